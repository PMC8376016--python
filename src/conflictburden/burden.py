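"""Per-record burden computations: injury-pattern classification, YLL, and
incidence/prevalence YLD.

Six patterns partition complete records: death; short-term disability
(< 1 year); long-term recovered disability (>= 1 year), treated or
untreated; and permanent ("continuing") disability, treated or untreated.
A record contributes to exactly one of YLL (definitive deaths) or YLD
(everything else); deaths judged only possibly related or unrelated to the
injury are routed to the YLD path for their documented duration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .disability_weights import is_treated
from .life_tables import LifeTable
from .records import DurationUnit, InjuryRecord, Mechanism, Outcome

#: Default end of the observation period, as a decimal year (~1 June 2014).
DEFAULT_STUDY_END = 2014.42

#: Default position of the injury within its calendar year (mid-year).
DEFAULT_INJURY_TIME_OFFSET = 0.5

_DIVISORS = {
    DurationUnit.YEARS: 1.0,
    DurationUnit.MONTHS: 12.0,
    DurationUnit.WEEKS: 52.0,
    DurationUnit.DAYS: 365.0,
}


class InjuryPattern(str, enum.Enum):
    DEATH = "death"
    SHORT_TERM = "short_term"
    LONG_TERM_RECOVERED_TREATED = "long_term_recovered_treated"
    LONG_TERM_RECOVERED_UNTREATED = "long_term_recovered_untreated"
    PERMANENT_TREATED = "permanent_treated"
    PERMANENT_UNTREATED = "permanent_untreated"

    @property
    def is_permanent(self) -> bool:
        return self in (InjuryPattern.PERMANENT_TREATED, InjuryPattern.PERMANENT_UNTREATED)


@dataclass
class PersonBurden:
    """One record's burden contributions (computed at mean DWs)."""

    person_id: str
    pattern: InjuryPattern
    cause: Mechanism
    yll: float = 0.0
    yld_incidence: float = 0.0
    yld_prevalence_by_year: dict[int, float] = field(default_factory=dict)

    @property
    def daly(self) -> float:
        return self.yll + self.yld_incidence


def parse_duration(value: float, unit: DurationUnit) -> float:
    """Convert a reported duration to fractional years (months / 12,
    weeks / 52, days / 365; years pass through)."""
    unit = DurationUnit(unit)
    if unit is DurationUnit.CONTINUING:
        raise ValueError("a 'continuing' disability has no finite duration")
    if value < 0:
        raise ValueError(f"duration must be nonnegative, got {value}")
    return float(value) / _DIVISORS[unit]


def record_duration_years(record: InjuryRecord) -> float:
    """Finite disability duration of a non-permanent record, in years.

    A survivor with no disability contributes zero duration.
    """
    if not record.disability_flag:
        return 0.0
    if record.is_permanent:
        raise ValueError(f"{record.person_id}: permanent disability has no finite duration")
    if record.duration_value is None or record.duration_unit is None:
        raise ValueError(f"{record.person_id}: missing duration")
    return parse_duration(record.duration_value, record.duration_unit)


def classify(record: InjuryRecord, unknown_care_treated: bool = True) -> InjuryPattern:
    """Assign the complete record to exactly one injury pattern."""
    if record.outcome is Outcome.DEATH_RELATED:
        return InjuryPattern.DEATH
    treated = is_treated(record.care, unknown_care_treated)
    if record.is_permanent:
        return InjuryPattern.PERMANENT_TREATED if treated else InjuryPattern.PERMANENT_UNTREATED
    duration = record_duration_years(record)
    if duration < 1.0:
        return InjuryPattern.SHORT_TERM
    return (
        InjuryPattern.LONG_TERM_RECOVERED_TREATED
        if treated
        else InjuryPattern.LONG_TERM_RECOVERED_UNTREATED
    )


def compute_yll(record: InjuryRecord, table: LifeTable) -> float:
    """Remaining standard life expectancy at age of death.

    Only definitive injury deaths yield YLLs; any other outcome is a
    contract violation.
    """
    if record.outcome is not Outcome.DEATH_RELATED:
        raise ValueError(
            f"{record.person_id}: YLL is defined only for outcome=death_related, "
            f"got {record.outcome.value}"
        )
    if record.age_at_death is None:
        raise ValueError(f"{record.person_id}: death record lacks age_at_death")
    return table.remaining_life_expectancy(record.age_at_death)


def disability_span_years(
    record: InjuryRecord, pattern: InjuryPattern, table: LifeTable | None
) -> float:
    """Years lived with the disability: reported duration for recovered
    patterns, remaining life expectancy at age of injury for permanent."""
    pattern = InjuryPattern(pattern)
    if pattern is InjuryPattern.DEATH:
        raise ValueError("death records have no disability span")
    if pattern.is_permanent:
        if record.age_at_injury is None:
            raise ValueError(f"{record.person_id}: permanent pattern needs age_at_injury")
        if table is None:
            raise ValueError("permanent pattern needs a life table")
        return table.remaining_life_expectancy(record.age_at_injury)
    return record_duration_years(record)


def compute_yld_incidence(
    record: InjuryRecord,
    pattern: InjuryPattern,
    dw_value: float,
    table: LifeTable | None = None,
) -> float:
    """Incidence YLD: disability weight x years lived with the disability,
    all attributed to the injury year."""
    if not 0.0 <= dw_value <= 1.0:
        raise ValueError(f"dw_value must be in [0, 1], got {dw_value}")
    return dw_value * disability_span_years(record, pattern, table)


def compute_yld_prevalence(
    record: InjuryRecord,
    pattern: InjuryPattern,
    dw_value: float,
    study_end: float | None = DEFAULT_STUDY_END,
    table: LifeTable | None = None,
    injury_time_offset: float = DEFAULT_INJURY_TIME_OFFSET,
) -> dict[int, float]:
    """Prevalence YLD: allocate ``dw_value`` per person-year of lived
    disability to each calendar year between the injury and
    ``min(recovery, study_end)``, fractional in the first and last years.

    ``study_end=None`` means an unbounded horizon, in which case the
    allocation sums exactly to the incidence YLD.  ``injury_time_offset``
    places the injury within its calendar year (default mid-year).
    """
    if not 0.0 <= dw_value <= 1.0:
        raise ValueError(f"dw_value must be in [0, 1], got {dw_value}")
    span = disability_span_years(record, pattern, table)
    start = record.injury_year + injury_time_offset
    end = start + span
    if study_end is not None:
        end = min(end, float(study_end))
    return allocate_person_years(start, end, dw_value)


def allocate_person_years(start: float, end: float, rate: float) -> dict[int, float]:
    """Spread ``rate`` per year over [start, end) by calendar-year overlap."""
    out: dict[int, float] = {}
    if end <= start or rate == 0.0:
        return out
    year = math.floor(start)
    while year < end:
        overlap = min(end, year + 1.0) - max(start, float(year))
        if overlap > 0:
            out[year] = rate * overlap
        year += 1
    return out
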