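# conflictburden

Burden-of-injury estimation (DALYs = YLLs + YLDs) for conflict-related
intentional injuries from record-level household-survey data, with

- a validated injury-record data model and a CSV *dialect* layer, so survey
  files with different headers/spellings load without code changes;
- a completeness filter that itemizes every exclusion (missing age/duration
  vs missing disability-weight information);
- remaining-life-expectancy lookup from a bundled standard (aspirational)
  life table, a flat `LE-at-birth − age` sensitivity table, or any
  user-supplied `age,remaining_le` CSV;
- a disability-weight registry with treated/untreated variants and
  per-weight beta-fitted draw vectors for uncertainty propagation;
- per-record burden computation across six injury patterns (death,
  short-term, long-term recovered treated/untreated, permanent
  treated/untreated), with both incidence-based and prevalence-based YLDs;
- bootstrap uncertainty intervals (resampling with replacement + DW draw
  variation), cause-specific decomposition, and extrapolation to a target
  population;
- a synthetic household-survey generator with a closed-form expected-burden
  oracle, so the entire pipeline is testable without any external data.

## CLI

Simulate a survey, then run the full pipeline:

```bash
burden simulate --seed 7 --out survey.csv            # + survey.csv.truth.csv ledger
burden run --records survey.csv \
    --life-table standard \
    --iterations 1000 --seed 7 \
    --n-persons 5148 --population 6900000 \
    --yld-mode both --study-end 2014.42 \
    --out results/
```

`--life-table` accepts `standard` (bundled), `flat:69.4` (country-specific
sensitivity mode), or a CSV path. Outputs under `--out`: `result.json`
(lossless, includes seed/iterations/life-table metadata), `result.csv`
(flat point/UI table), `exclusions.csv`, and `result_population.json` when
`--population` is given. Logs go to stderr; exit code 0 on success.

`burden simulate --config config.yaml` overrides any
`SyntheticSurveyConfig` field (household count, injury rate, case fatality,
mechanism mix, missingness, ...).

## Library sketch

```python
import conflictburden as cb

table = cb.load_standard_life_table()
registry = cb.generate_draws(cb.load_dw_registry(), n_draws=1000, seed=0)

read = cb.read_records("survey.csv")                 # records + completeness report
complete, excluded = cb.apply_completeness_filter(read.records, registry)

result = cb.bootstrap_burden(
    complete, registry, table,
    cb.BootstrapConfig(n_iterations=1000, seed=0),
    n_persons=5148,
)
by_cause = cb.cause_specific_burden(complete, registry, table)
city = cb.extrapolate(result, n_sampled_persons=5148, population=6_900_000)
cb.write_report(result, "result.json", "json")
```

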