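# Default CSV dialect: canonical column names and categorical spellings.
# Supply a modified copy of this file to ingest datasets with different
# headers or enum spellings; aliases map raw CSV tokens to canonical values.
columns:
  person_id: person_id
  age_at_injury: age_at_injury
  injury_year: injury_year
  mechanism: mechanism
  outcome: outcome
  age_at_death: age_at_death
  care: care
  disability: disability
  duration_value: duration_value
  duration_unit: duration_unit
  dw_code: dw_code
values:
  mechanism:
    gunshot: gunshot
    gun shot: gunshot
    gsw: gunshot
    shelling: shelling
    blast_explosion: blast_explosion
    blast: blast_explosion
    explosion: blast_explosion
    stabbing: stabbing
    stab: stabbing
    burn: burn
    burns: burn
    torture: torture
    other: other
  outcome:
    death_related: death_related
    death_possibly_related: death_possibly_related
    death_unrelated: death_unrelated
    survived: survived
  care:
    hospital: hospital
    clinic: clinic
    health clinic: clinic
    workplace: workplace
    place of employment: workplace
    none: none
    no care: none
    unknown: unknown
  duration_unit:
    years: years
    year: years
    months: months
    month: months
    weeks: weeks
    week: weeks
    days: days
    day: days
    continuing: continuing
    ongoing: continuing
  disability:
    "yes": "yes"
    "no": "no"
missing: ["", "NA", "N/A", "NaN", "."]
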