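"""Injury-record data model, survey-CSV reading, and completeness filtering.

The record layout mirrors a household-survey injury questionnaire: one row
per injured (or killed) person, carrying the year and mechanism of injury,
the outcome, where care was received, the reported duration of any
disability, and a disability-weight code used downstream for YLD
computation.  Column names and categorical spellings are decoupled from the
code through a *dialect* mapping (a small YAML/dict structure), so datasets
with different headers can be ingested without code changes.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

DEFAULT_STUDY_WINDOW: tuple[int, int] = (2003, 2014)

#: Reasons attached to excluded records / rejected rows.
REASON_MISSING_AGE_OR_DURATION = "missing age/duration"
REASON_MISSING_DW_INFO = "missing DW info"


class Mechanism(str, enum.Enum):
    """Mechanism of the intentional injury."""

    GUNSHOT = "gunshot"
    SHELLING = "shelling"
    BLAST_EXPLOSION = "blast_explosion"
    STABBING = "stabbing"
    BURN = "burn"
    TORTURE = "torture"
    OTHER = "other"


class Outcome(str, enum.Enum):
    """Vital outcome of the injured person as reported by the household."""

    DEATH_RELATED = "death_related"
    DEATH_POSSIBLY_RELATED = "death_possibly_related"
    DEATH_UNRELATED = "death_unrelated"
    SURVIVED = "survived"

    @property
    def is_death(self) -> bool:
        return self is not Outcome.SURVIVED


class Care(str, enum.Enum):
    """Highest level of post-injury care received."""

    HOSPITAL = "hospital"
    CLINIC = "clinic"
    WORKPLACE = "workplace"
    NONE = "none"
    UNKNOWN = "unknown"


class DurationUnit(str, enum.Enum):
    """Unit in which the respondent reported the duration of disability."""

    YEARS = "years"
    MONTHS = "months"
    WEEKS = "weeks"
    DAYS = "days"
    CONTINUING = "continuing"


@dataclass(frozen=True)
class InjuryRecord:
    """One surveyed person-injury.

    ``age_at_injury``, ``age_at_death``, ``duration_value`` and ``dw_code``
    may be absent (``None``); the completeness filter decides whether the
    record carries enough information for burden computation.
    """

    person_id: str
    injury_year: int
    mechanism: Mechanism
    outcome: Outcome
    age_at_injury: int | None = None
    age_at_death: int | None = None
    care: Care = Care.UNKNOWN
    disability_flag: bool = False
    duration_value: float | None = None
    duration_unit: DurationUnit | None = None
    dw_code: str | None = None

    def __post_init__(self) -> None:
        if self.age_at_injury is not None and self.age_at_injury < 0:
            raise ValueError(f"{self.person_id}: age_at_injury must be >= 0")
        if self.age_at_death is not None and self.age_at_death < 0:
            raise ValueError(f"{self.person_id}: age_at_death must be >= 0")
        if self.duration_value is not None and self.duration_value < 0:
            raise ValueError(f"{self.person_id}: duration_value must be >= 0")
        if self.duration_unit is DurationUnit.CONTINUING and self.duration_value is not None:
            raise ValueError(
                f"{self.person_id}: a 'continuing' disability cannot carry a duration value"
            )

    @property
    def is_permanent(self) -> bool:
        return self.duration_unit is DurationUnit.CONTINUING


@dataclass
class CompletenessReport:
    """Partition of validated records by usability for burden computation.

    Invariant: ``n_total == n_complete + n_missing_age_or_duration +
    n_missing_dw_info``.
    """

    n_total: int = 0
    n_complete: int = 0
    n_missing_age_or_duration: int = 0
    n_missing_dw_info: int = 0
    excluded_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_total != (
            self.n_complete + self.n_missing_age_or_duration + self.n_missing_dw_info
        ):
            raise ValueError("completeness counts do not partition n_total")


@dataclass(frozen=True)
class RowError:
    """A CSV row that could not be turned into a valid record."""

    row_index: int
    person_id: str | None
    reason: str


@dataclass
class ReadResult:
    records: list[InjuryRecord]
    report: CompletenessReport
    row_errors: list[RowError]

    def __iter__(self):  # allow ``records, report = read_records(...)`` style
        yield self.records
        yield self.report


# ---------------------------------------------------------------------------
# Dialect handling
# ---------------------------------------------------------------------------

_CANONICAL_COLUMNS = (
    "person_id",
    "age_at_injury",
    "injury_year",
    "mechanism",
    "outcome",
    "age_at_death",
    "care",
    "disability",
    "duration_value",
    "duration_unit",
    "dw_code",
)

_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n"}


def default_dialect() -> dict:
    """Identity dialect: canonical column names, canonical enum spellings."""
    from importlib.resources import files

    text = files("conflictburden.data").joinpath("default_dialect.yaml").read_text()
    return yaml.safe_load(text)


def load_dialect(path: str | Path) -> dict:
    with open(path) as fh:
        dialect = yaml.safe_load(fh)
    if "columns" not in dialect:
        raise ValueError(f"dialect file {path} lacks a 'columns' mapping")
    return dialect


def _remap(dialect: Mapping, fieldname: str, raw: str) -> str:
    aliases = dialect.get("values", {}).get(fieldname, {})
    return str(aliases.get(raw, raw))


def _is_missing(raw: str | None, dialect: Mapping) -> bool:
    if raw is None:
        return True
    tokens = dialect.get("missing", ["", "NA", "N/A", "NaN", "."])
    return raw.strip() in tokens


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_records(
    path: str | Path,
    dialect: Mapping | None = None,
    study_window: tuple[int, int] = DEFAULT_STUDY_WINDOW,
) -> ReadResult:
    """Read a survey CSV into validated :class:`InjuryRecord` objects.

    Every data row either becomes a record or an itemized :class:`RowError`;
    nothing is silently dropped.  Rows with an unknown categorical value or
    an injury year outside ``study_window`` are rejected per-row with a
    logged reason; a structurally unreadable file raises.

    Returns a :class:`ReadResult` whose ``report`` partitions the *valid*
    records by completeness (see :func:`apply_completeness_filter`).
    """
    dialect = dialect or default_dialect()
    cols = dialect["columns"]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[InjuryRecord] = []
    row_errors: list[RowError] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: no header row")
        missing_cols = [
            c for k, c in cols.items() if c is not None and c not in reader.fieldnames
        ]
        if missing_cols:
            raise ValueError(f"{path}: header lacks mapped columns {missing_cols}")
        for i, row in enumerate(reader):
            try:
                rec = _parse_row(row, dialect, study_window, i)
            except ValueError as exc:
                pid = row.get(cols.get("person_id", ""), None)
                row_errors.append(RowError(i, pid, str(exc)))
                logger.warning("row %d excluded: %s", i, exc)
                continue
            records.append(rec)

    report = build_completeness_report(records)
    return ReadResult(records=records, report=report, row_errors=row_errors)


def _parse_row(
    row: Mapping[str, str],
    dialect: Mapping,
    study_window: tuple[int, int],
    row_index: int,
) -> InjuryRecord:
    cols = dialect["columns"]

    def raw(fieldname: str) -> str | None:
        col = cols.get(fieldname)
        if col is None:
            return None
        value = row.get(col)
        if _is_missing(value, dialect):
            return None
        return value.strip()

    def parse_enum(fieldname: str, enum_cls):
        value = raw(fieldname)
        if value is None:
            return None
        mapped = _remap(dialect, fieldname, value)
        try:
            return enum_cls(mapped)
        except ValueError:
            raise ValueError(f"unknown {fieldname} value {value!r}") from None

    def parse_number(fieldname: str, cast):
        value = raw(fieldname)
        if value is None:
            return None
        try:
            return cast(float(value))
        except ValueError:
            raise ValueError(f"unparseable {fieldname} value {value!r}") from None

    person_id = raw("person_id") or f"row{row_index}"
    year = parse_number("injury_year", int)
    if year is None:
        raise ValueError("missing injury_year")
    lo, hi = study_window
    if not lo <= year <= hi:
        raise ValueError(f"injury_year {year} outside study window {lo}-{hi}")

    mechanism = parse_enum("mechanism", Mechanism)
    if mechanism is None:
        raise ValueError("missing mechanism")
    outcome = parse_enum("outcome", Outcome)
    if outcome is None:
        raise ValueError("missing outcome")
    care = parse_enum("care", Care) or Care.UNKNOWN
    duration_unit = parse_enum("duration_unit", DurationUnit)

    disability_raw = raw("disability")
    if disability_raw is None:
        disability = duration_unit is not None
    else:
        token = _remap(dialect, "disability", disability_raw).lower()
        if token in _TRUE_TOKENS:
            disability = True
        elif token in _FALSE_TOKENS:
            disability = False
        else:
            raise ValueError(f"unknown disability value {disability_raw!r}")

    return InjuryRecord(
        person_id=person_id,
        injury_year=year,
        mechanism=mechanism,
        outcome=outcome,
        age_at_injury=parse_number("age_at_injury", int),
        age_at_death=parse_number("age_at_death", int),
        care=care,
        disability_flag=disability,
        duration_value=parse_number("duration_value", float),
        duration_unit=duration_unit,
        dw_code=raw("dw_code"),
    )


# ---------------------------------------------------------------------------
# Completeness filter
# ---------------------------------------------------------------------------

def completeness_status(record: InjuryRecord, registry=None) -> str | None:
    """Return ``None`` if the record is usable, else an exclusion reason.

    Rules: a definitive death needs its age at death (for YLL).  A
    non-death record on the YLD path needs age at injury for a permanent
    ("continuing") disability, or a duration for a recovered one, plus a
    resolvable disability-weight code.  A survivor with no disability at
    all is complete with zero burden.
    """
    if record.outcome is Outcome.DEATH_RELATED:
        return None if record.age_at_death is not None else REASON_MISSING_AGE_OR_DURATION

    # YLD path: survivors plus deaths not definitively attributed to the injury.
    if not record.disability_flag:
        return None  # zero-burden record
    if record.is_permanent:
        if record.age_at_injury is None:
            return REASON_MISSING_AGE_OR_DURATION
    else:
        if record.duration_value is None or record.duration_unit is None:
            return REASON_MISSING_AGE_OR_DURATION
    if record.dw_code is None:
        return REASON_MISSING_DW_INFO
    if registry is not None and not registry.can_match(record):
        return REASON_MISSING_DW_INFO
    return None


def apply_completeness_filter(
    records: Iterable[InjuryRecord], registry=None
) -> tuple[list[InjuryRecord], list[tuple[InjuryRecord, str]]]:
    """Partition records into (complete, excluded-with-reason)."""
    complete: list[InjuryRecord] = []
    excluded: list[tuple[InjuryRecord, str]] = []
    for rec in records:
        reason = completeness_status(rec, registry)
        if reason is None:
            complete.append(rec)
        else:
            excluded.append((rec, reason))
    return complete, excluded


def build_completeness_report(
    records: Sequence[InjuryRecord], registry=None
) -> CompletenessReport:
    report = CompletenessReport(n_total=len(records))
    for rec in records:
        reason = completeness_status(rec, registry)
        if reason is None:
            report.n_complete += 1
        elif reason == REASON_MISSING_AGE_OR_DURATION:
            report.n_missing_age_or_duration += 1
            report.excluded_ids.append(rec.person_id)
        else:
            report.n_missing_dw_info += 1
            report.excluded_ids.append(rec.person_id)
    report.validate()
    return report


# ---------------------------------------------------------------------------
# Writing survey CSVs (used by the synthetic generator and round-trip tests)
# ---------------------------------------------------------------------------

def write_survey_csv(
    records: Iterable[InjuryRecord],
    path: str | Path,
    dialect: Mapping | None = None,
) -> None:
    """Emit records in the same CSV dialect :func:`read_records` consumes."""
    dialect = dialect or default_dialect()
    cols = dialect["columns"]
    header = [cols[c] for c in _CANONICAL_COLUMNS if cols.get(c) is not None]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            values = {
                "person_id": rec.person_id,
                "age_at_injury": rec.age_at_injury,
                "injury_year": rec.injury_year,
                "mechanism": rec.mechanism.value,
                "outcome": rec.outcome.value,
                "age_at_death": rec.age_at_death,
                "care": rec.care.value,
                "disability": "yes" if rec.disability_flag else "no",
                "duration_value": rec.duration_value,
                "duration_unit": rec.duration_unit.value if rec.duration_unit else None,
                "dw_code": rec.dw_code,
            }
            writer.writerow(
                ["" if values[c] is None else values[c] for c in _CANONICAL_COLUMNS if cols.get(c) is not None]
            )
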