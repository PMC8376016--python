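"""Burden-result container and report serialization (JSON / CSV)."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

_TOL = 1e-9


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional 95% uncertainty interval."""

    point: float
    ui_lower: float | None = None
    ui_upper: float | None = None

    def __post_init__(self) -> None:
        if self.ui_lower is not None and self.ui_upper is not None:
            if not (self.ui_lower - _TOL <= self.point <= self.ui_upper + _TOL):
                raise ValueError(
                    f"point {self.point} outside UI ({self.ui_lower}, {self.ui_upper})"
                )

    def scaled(self, factor: float) -> "Estimate":
        return Estimate(
            self.point * factor,
            None if self.ui_lower is None else self.ui_lower * factor,
            None if self.ui_upper is None else self.ui_upper * factor,
        )

    def to_dict(self) -> dict:
        return {"point": self.point, "ui_lower": self.ui_lower, "ui_upper": self.ui_upper}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Estimate":
        return cls(d["point"], d.get("ui_lower"), d.get("ui_upper"))

    @classmethod
    def zero(cls) -> "Estimate":
        return cls(0.0, None, None)


@dataclass(frozen=True)
class CauseBurden:
    daly: Estimate
    proportion: float
    n_records: int

    def to_dict(self) -> dict:
        return {
            "daly": self.daly.to_dict(),
            "proportion": self.proportion,
            "n_records": self.n_records,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CauseBurden":
        return cls(Estimate.from_dict(d["daly"]), d["proportion"], d["n_records"])


@dataclass(frozen=True)
class BurdenResult:
    """Totals, rates, and decompositions from a burden computation.

    Point estimates are bootstrap means (or direct sums for a degenerate
    bootstrap); UIs are 2.5/97.5 percentiles of the iteration totals.
    ``per_person`` divides by the surveyed population, ``per_injury`` by
    the number of injuries, ``per_death`` by the number of deaths.
    """

    total_yll: Estimate
    total_yld_incidence: Estimate
    total_yld_prevalence: Estimate
    total_daly: Estimate
    per_person: dict[str, Estimate] = field(default_factory=dict)
    per_injury: dict[str, Estimate] = field(default_factory=dict)
    per_death: dict[str, Estimate] = field(default_factory=dict)
    by_year: dict[int, dict[str, float]] = field(default_factory=dict)
    by_cause: dict[str, CauseBurden] = field(default_factory=dict)
    n_records: int = 0
    n_persons: int | None = None
    n_injuries: int | None = None
    n_deaths: int | None = None
    meta: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, meta: dict | None = None) -> "BurdenResult":
        """Degenerate result for an empty cohort: zero totals, flagged UIs."""
        zero = Estimate.zero()
        return cls(zero, zero, zero, zero, meta=dict(meta or {}, empty_cohort=True))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "totals": {
                "yll": self.total_yll.to_dict(),
                "yld_incidence": self.total_yld_incidence.to_dict(),
                "yld_prevalence": self.total_yld_prevalence.to_dict(),
                "daly": self.total_daly.to_dict(),
            },
            "per_person": {k: v.to_dict() for k, v in self.per_person.items()},
            "per_injury": {k: v.to_dict() for k, v in self.per_injury.items()},
            "per_death": {k: v.to_dict() for k, v in self.per_death.items()},
            "by_year": {str(y): dict(v) for y, v in sorted(self.by_year.items())},
            "by_cause": {k: v.to_dict() for k, v in self.by_cause.items()},
            "n_records": self.n_records,
            "n_persons": self.n_persons,
            "n_injuries": self.n_injuries,
            "n_deaths": self.n_deaths,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BurdenResult":
        totals = d["totals"]
        return cls(
            total_yll=Estimate.from_dict(totals["yll"]),
            total_yld_incidence=Estimate.from_dict(totals["yld_incidence"]),
            total_yld_prevalence=Estimate.from_dict(totals["yld_prevalence"]),
            total_daly=Estimate.from_dict(totals["daly"]),
            per_person={k: Estimate.from_dict(v) for k, v in d.get("per_person", {}).items()},
            per_injury={k: Estimate.from_dict(v) for k, v in d.get("per_injury", {}).items()},
            per_death={k: Estimate.from_dict(v) for k, v in d.get("per_death", {}).items()},
            by_year={int(y): dict(v) for y, v in d.get("by_year", {}).items()},
            by_cause={k: CauseBurden.from_dict(v) for k, v in d.get("by_cause", {}).items()},
            n_records=d.get("n_records", 0),
            n_persons=d.get("n_persons"),
            n_injuries=d.get("n_injuries"),
            n_deaths=d.get("n_deaths"),
            meta=dict(d.get("meta", {})),
        )

    def point_estimates(self) -> dict[str, float]:
        """Flat quantity -> point mapping (shared by JSON and CSV views)."""
        out = {
            "total_yll": self.total_yll.point,
            "total_yld_incidence": self.total_yld_incidence.point,
            "total_yld_prevalence": self.total_yld_prevalence.point,
            "total_daly": self.total_daly.point,
        }
        for prefix, mapping in (
            ("per_person", self.per_person),
            ("per_injury", self.per_injury),
            ("per_death", self.per_death),
        ):
            for k, v in mapping.items():
                out[f"{prefix}_{k}"] = v.point
        for cause, cb in self.by_cause.items():
            out[f"cause_{cause}_daly"] = cb.daly.point
        for year, vals in self.by_year.items():
            for k, v in vals.items():
                out[f"year_{year}_{k}"] = v
        return out


def write_report(result: BurdenResult, path: str | Path, format: str = "json") -> None:
    """Write a result report.  JSON round-trips losslessly (including
    metadata: seed, iterations, life table, study window); CSV is a flat
    quantity/point/UI table for spreadsheet use."""
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        _write_csv(result, path)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> BurdenResult:
    with open(path) as fh:
        return BurdenResult.from_dict(json.load(fh))


def _write_csv(result: BurdenResult, path: Path) -> None:
    def ui(e: Estimate) -> tuple:
        return (e.ui_lower, e.ui_upper)

    rows: list[tuple] = []
    for name, est in (
        ("total_yll", result.total_yll),
        ("total_yld_incidence", result.total_yld_incidence),
        ("total_yld_prevalence", result.total_yld_prevalence),
        ("total_daly", result.total_daly),
    ):
        rows.append((name, est.point, *ui(est)))
    for prefix, mapping in (
        ("per_person", result.per_person),
        ("per_injury", result.per_injury),
        ("per_death", result.per_death),
    ):
        for k, est in mapping.items():
            rows.append((f"{prefix}_{k}", est.point, *ui(est)))
    for cause, cb in result.by_cause.items():
        rows.append((f"cause_{cause}_daly", cb.daly.point, *ui(cb.daly)))
    for year, vals in sorted(result.by_year.items()):
        for k, v in sorted(vals.items()):
            rows.append((f"year_{year}_{k}", v, None, None))
    for k, v in sorted(result.meta.items()):
        rows.append((f"meta_{k}", v, None, None))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["quantity", "point", "ui_lower", "ui_upper"])
        for row in rows:
            writer.writerow(["" if v is None else v for v in row])
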