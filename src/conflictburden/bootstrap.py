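"""Bootstrap uncertainty propagation, cause decomposition, and
population extrapolation.

Each bootstrap iteration resamples the complete records with replacement
and values the resample with one randomly selected draw from each
disability weight's draw distribution; iteration totals over YLL,
incidence YLD, and prevalence YLD give point estimates (means) and 95%
uncertainty intervals (2.5/97.5 percentiles).  Cause-specific estimates
resample but hold DWs at their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .burden import (
    DEFAULT_INJURY_TIME_OFFSET,
    DEFAULT_STUDY_END,
    InjuryPattern,
    PersonBurden,
    classify,
    compute_yld_incidence,
    compute_yld_prevalence,
    compute_yll,
    disability_span_years,
)
from .disability_weights import DWRegistry, generate_draws, match_dw
from .life_tables import LifeTable
from .records import InjuryRecord, Mechanism
from .results import BurdenResult, CauseBurden, Estimate

__all__ = [
    "BootstrapConfig",
    "bootstrap_burden",
    "cause_specific_burden",
    "compute_direct",
    "extrapolate",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Controls the uncertainty propagation.

    ``vary_dws`` selects a random DW draw per iteration (one shared draw
    index for all entries by default; ``per_record_draws`` switches to an
    independent index per resampled record).  ``resample`` toggles
    with-replacement resampling of the records.
    """

    n_iterations: int = 1000
    seed: int = 0
    vary_dws: bool = True
    resample: bool = True
    per_record_draws: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class _Prepared:
    """Vectorized view of a cohort: per-record fixed YLLs and DW-linear
    YLD multipliers, plus the per-record draw matrix."""

    records: list[InjuryRecord]
    patterns: list[InjuryPattern]
    yll: np.ndarray              # fixed YLL per record (0 for non-deaths)
    span_inc: np.ndarray         # incidence-YLD person-years per unit DW
    span_prev: np.ndarray        # within-window prevalence person-years per unit DW
    dw_mean: np.ndarray
    draws: np.ndarray            # (n_records, n_draws); zero rows for deaths
    prev_alloc: list[dict[int, float]]  # per-record year -> person-years


def _prepare(
    records: list[InjuryRecord],
    registry: DWRegistry,
    table: LifeTable,
    study_end: float | None,
    unknown_care_treated: bool,
    injury_time_offset: float,
) -> _Prepared:
    n = len(records)
    n_draws = registry.n_draws or 1
    yll = np.zeros(n)
    span_inc = np.zeros(n)
    span_prev = np.zeros(n)
    dw_mean = np.zeros(n)
    draws = np.zeros((n, n_draws))
    patterns: list[InjuryPattern] = []
    prev_alloc: list[dict[int, float]] = []

    for i, rec in enumerate(records):
        pattern = classify(rec, unknown_care_treated)
        patterns.append(pattern)
        if pattern is InjuryPattern.DEATH:
            yll[i] = compute_yll(rec, table)
            prev_alloc.append({})
            continue
        if not rec.disability_flag:  # zero-burden survivor
            prev_alloc.append({})
            continue
        entry = match_dw(rec, pattern, registry, unknown_care_treated)
        span = disability_span_years(rec, pattern, table)
        span_inc[i] = span
        dw_mean[i] = entry.mean
        draws[i, :] = entry.draws if entry.draws is not None else entry.mean
        alloc = compute_yld_prevalence(
            rec, pattern, 1.0, study_end, table, injury_time_offset
        )
        prev_alloc.append(alloc)
        span_prev[i] = sum(alloc.values())
    return _Prepared(records, patterns, yll, span_inc, span_prev, dw_mean, draws, prev_alloc)


def compute_direct(
    records: list[InjuryRecord],
    registry: DWRegistry,
    table: LifeTable,
    study_end: float | None = DEFAULT_STUDY_END,
    unknown_care_treated: bool = True,
    injury_time_offset: float = DEFAULT_INJURY_TIME_OFFSET,
) -> list[PersonBurden]:
    """Single-pass per-record burdens at mean disability weights.

    This is the plug-in computation the bootstrap collapses to when
    resampling and DW variation are switched off.
    """
    burdens = []
    for rec in records:
        pattern = classify(rec, unknown_care_treated)
        pb = PersonBurden(person_id=rec.person_id, pattern=pattern, cause=rec.mechanism)
        if pattern is InjuryPattern.DEATH:
            pb.yll = compute_yll(rec, table)
        elif rec.disability_flag:
            entry = match_dw(rec, pattern, registry, unknown_care_treated)
            pb.yld_incidence = compute_yld_incidence(rec, pattern, entry.mean, table)
            pb.yld_prevalence_by_year = compute_yld_prevalence(
                rec, pattern, entry.mean, study_end, table, injury_time_offset
            )
        burdens.append(pb)
    return burdens


def _iteration_totals(prep: _Prepared, config: BootstrapConfig) -> np.ndarray:
    """(n_iterations, 3) array of YLL / incidence-YLD / prevalence-YLD totals."""
    n = len(prep.records)
    n_draws = prep.draws.shape[1]
    rng = np.random.default_rng(config.seed)
    totals = np.empty((config.n_iterations, 3))
    base_idx = np.arange(n)
    for k in range(config.n_iterations):
        idx = rng.integers(0, n, size=n) if config.resample else base_idx
        if config.vary_dws:
            if config.per_record_draws:
                j = rng.integers(0, n_draws, size=n)
                dw = prep.draws[idx, j]
            else:
                j = rng.integers(0, n_draws)
                dw = prep.draws[idx, j]
        else:
            dw = prep.dw_mean[idx]
        totals[k, 0] = prep.yll[idx].sum()
        totals[k, 1] = (prep.span_inc[idx] * dw).sum()
        totals[k, 2] = (prep.span_prev[idx] * dw).sum()
    return totals


def _estimate(values: np.ndarray) -> Estimate:
    lo, hi = np.percentile(values, [2.5, 97.5])
    point = float(values.mean())
    return Estimate(point, min(float(lo), point), max(float(hi), point))


def bootstrap_burden(
    records: list[InjuryRecord],
    registry: DWRegistry,
    table: LifeTable,
    config: BootstrapConfig | None = None,
    *,
    study_end: float | None = DEFAULT_STUDY_END,
    n_persons: int | None = None,
    n_injuries: int | None = None,
    n_deaths: int | None = None,
    unknown_care_treated: bool = True,
    injury_time_offset: float = DEFAULT_INJURY_TIME_OFFSET,
    study_window: tuple[int, int] | None = None,
) -> BurdenResult:
    """Bootstrap the cohort's burden totals with DW-draw uncertainty.

    ``n_persons`` / ``n_injuries`` / ``n_deaths`` are the denominators for
    the per-person, per-injury, and per-death means; the latter two default
    to the complete-record and definitive-death counts of ``records``.
    Deterministic given ``config.seed``.
    """
    if not records:
        raise ValueError("cannot bootstrap an empty record list")
    config = config or BootstrapConfig()
    if config.vary_dws and registry.n_draws is None:
        registry = generate_draws(registry, seed=config.seed)

    prep = _prepare(
        records, registry, table, study_end, unknown_care_treated, injury_time_offset
    )
    totals = _iteration_totals(prep, config)
    yll_e = _estimate(totals[:, 0])
    inc_e = _estimate(totals[:, 1])
    prev_e = _estimate(totals[:, 2])
    daly_e = _estimate(totals[:, 0] + totals[:, 1])

    n_injuries = len(records) if n_injuries is None else n_injuries
    if n_deaths is None:
        n_deaths = sum(1 for p in prep.patterns if p is InjuryPattern.DEATH)

    def rates(denom: int | None) -> dict[str, Estimate]:
        if not denom:
            return {}
        f = 1.0 / denom
        return {
            "daly": daly_e.scaled(f),
            "yll": yll_e.scaled(f),
            "yld_incidence": inc_e.scaled(f),
        }

    # Year attribution at mean DWs, unresampled: YLLs and incidence YLDs to
    # the injury year; prevalence YLDs to the years actually lived.
    by_year: dict[int, dict[str, float]] = {}
    direct = compute_direct(
        records, registry, table, study_end, unknown_care_treated, injury_time_offset
    )
    for pb, rec in zip(direct, records):
        row = by_year.setdefault(
            rec.injury_year, {"yll": 0.0, "yld_incidence": 0.0, "yld_prevalence": 0.0, "daly": 0.0}
        )
        row["yll"] += pb.yll
        row["yld_incidence"] += pb.yld_incidence
        row["daly"] += pb.daly
        for year, val in pb.yld_prevalence_by_year.items():
            prow = by_year.setdefault(
                year, {"yll": 0.0, "yld_incidence": 0.0, "yld_prevalence": 0.0, "daly": 0.0}
            )
            prow["yld_prevalence"] += val

    meta = {
        "seed": config.seed,
        "n_iterations": config.n_iterations,
        "vary_dws": config.vary_dws,
        "resample": config.resample,
        "per_record_draws": config.per_record_draws,
        "life_table": table.name,
        "study_end": study_end,
        "n_dw_draws": registry.n_draws,
    }
    if study_window is not None:
        meta["study_window"] = list(study_window)

    return BurdenResult(
        total_yll=yll_e,
        total_yld_incidence=inc_e,
        total_yld_prevalence=prev_e,
        total_daly=daly_e,
        per_person=rates(n_persons),
        per_injury=rates(n_injuries),
        per_death=rates(n_deaths),
        by_year=by_year,
        n_records=len(records),
        n_persons=n_persons,
        n_injuries=n_injuries,
        n_deaths=n_deaths,
        meta=meta,
    )


def cause_specific_burden(
    records: list[InjuryRecord],
    registry: DWRegistry,
    table: LifeTable,
    config: BootstrapConfig | None = None,
    *,
    study_end: float | None = DEFAULT_STUDY_END,
    unknown_care_treated: bool = True,
    injury_time_offset: float = DEFAULT_INJURY_TIME_OFFSET,
) -> dict[str, CauseBurden]:
    """Per-mechanism DALY totals, shares of the grand total, and UIs.

    Resampling with replacement is performed per iteration but DWs stay at
    their means (varying them would not alter cause shares).  Point
    estimates and proportions come from the unresampled direct pass, so
    proportions sum to 1; causes with no records report zero with a
    degenerate UI.
    """
    if not records:
        raise ValueError("cannot decompose an empty record list")
    config = config or BootstrapConfig()
    direct = compute_direct(
        records, registry, table, study_end, unknown_care_treated, injury_time_offset
    )
    mechanisms = [m.value for m in Mechanism]
    mech_index = {m: i for i, m in enumerate(mechanisms)}
    daly = np.array([pb.daly for pb in direct])
    cause_idx = np.array([mech_index[pb.cause.value] for pb in direct])

    direct_totals = np.zeros(len(mechanisms))
    np.add.at(direct_totals, cause_idx, daly)
    grand = direct_totals.sum()

    n = len(records)
    rng = np.random.default_rng(config.seed)
    boot = np.empty((config.n_iterations, len(mechanisms)))
    for k in range(config.n_iterations):
        idx = rng.integers(0, n, size=n) if config.resample else np.arange(n)
        row = np.zeros(len(mechanisms))
        np.add.at(row, cause_idx[idx], daly[idx])
        boot[k] = row

    out: dict[str, CauseBurden] = {}
    counts = np.bincount(cause_idx, minlength=len(mechanisms))
    for m, i in mech_index.items():
        point = float(direct_totals[i])
        if counts[i] == 0:
            est = Estimate(0.0, 0.0, 0.0)
        else:
            lo, hi = np.percentile(boot[:, i], [2.5, 97.5])
            est = Estimate(point, min(float(lo), point), max(float(hi), point))
        out[m] = CauseBurden(
            daly=est,
            proportion=float(point / grand) if grand > 0 else 0.0,
            n_records=int(counts[i]),
        )
    return out


def extrapolate(
    result: BurdenResult, n_sampled_persons: int, population: int
) -> BurdenResult:
    """Scale sample totals to a target population via the per-person mean.

    Equivalent to (total / n_sampled_persons) x population applied to the
    point estimate and to each UI bound separately; exactly linear in
    ``population``.
    """
    if n_sampled_persons <= 0:
        raise ValueError("n_sampled_persons must be positive")
    if population <= 0:
        raise ValueError("population must be positive")
    f = population / n_sampled_persons
    return BurdenResult(
        total_yll=result.total_yll.scaled(f),
        total_yld_incidence=result.total_yld_incidence.scaled(f),
        total_yld_prevalence=result.total_yld_prevalence.scaled(f),
        total_daly=result.total_daly.scaled(f),
        per_person=dict(result.per_person),
        per_injury=dict(result.per_injury),
        per_death=dict(result.per_death),
        by_year={
            y: {k: v * f for k, v in row.items()} for y, row in result.by_year.items()
        },
        by_cause={
            m: CauseBurden(cb.daly.scaled(f), cb.proportion, cb.n_records)
            for m, cb in result.by_cause.items()
        },
        n_records=result.n_records,
        n_persons=result.n_persons,
        n_injuries=result.n_injuries,
        n_deaths=result.n_deaths,
        meta=dict(
            result.meta, extrapolated=True, population=population,
            n_sampled_persons=n_sampled_persons,
        ),
    )
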