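"""Remaining life expectancy lookup.

Deaths are valued against an *aspirational* standard life table — a
remaining-life-expectancy schedule built from the lowest observed
age-specific death rates among large countries — so that every death is
counted identically regardless of where it occurred.  A country-specific
(or any user-supplied) table can be substituted for sensitivity analysis;
a flat ``le_at_birth - age`` table is provided as the simplest such
alternative.

Tables are piecewise-linear: values at tabulated ages are exact, values
between knots are linearly interpolated, and ages beyond the last knot
return the final entry (floored at zero).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "LifeTable",
    "load_standard_life_table",
    "load_life_table",
    "make_flat_life_table",
    "remaining_life_expectancy",
]


@dataclass(frozen=True)
class LifeTable:
    """Mapping from age to remaining life expectancy (both in years).

    Invariants enforced on construction:

    * ages strictly increasing, starting at 0;
    * remaining life expectancy nonnegative everywhere (no monotonicity
      assumption — real tables have infant-mortality artifacts);
    * ``age + remaining_le`` non-decreasing in age (total-longevity
      consistency of a coherent table).
    """

    name: str
    ages: np.ndarray = field(repr=False)
    remaining: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        remaining = np.asarray(self.remaining, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "remaining", remaining)
        if ages.ndim != 1 or ages.shape != remaining.shape or ages.size == 0:
            raise ValueError("life table needs matching 1-D age/LE arrays")
        if ages[0] != 0:
            raise ValueError("life table must start at age 0")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("life-table ages must be strictly increasing")
        if np.any(remaining < 0):
            raise ValueError("remaining life expectancy must be nonnegative")
        if np.any(np.diff(ages + remaining) < -1e-9):
            raise ValueError("age + remaining LE must be non-decreasing")

    @property
    def entries(self) -> list[tuple[float, float]]:
        return list(zip(self.ages.tolist(), self.remaining.tolist()))

    def remaining_life_expectancy(self, age: float) -> float:
        """Linear interpolation; beyond the last knot, the final value."""
        if age < 0:
            raise ValueError(f"age must be nonnegative, got {age}")
        return float(np.interp(age, self.ages, self.remaining))


def remaining_life_expectancy(age: float, table: LifeTable) -> float:
    return table.remaining_life_expectancy(age)


def load_standard_life_table() -> LifeTable:
    """Load the bundled standard (aspirational) reference life table.

    The packaged schedule is validated at import against its anchor value:
    remaining life expectancy at age 20 of roughly 67 years.
    """
    from importlib.resources import files

    text = files("conflictburden.data").joinpath("standard_life_table.csv").read_text()
    table = _parse_life_table_csv(io.StringIO(text), name="standard")
    anchor = table.remaining_life_expectancy(20.0)
    if abs(anchor - 67.0) > 1.5:  # corrupt resource guard
        raise RuntimeError(f"bundled standard life table fails age-20 anchor: {anchor}")
    return table


def load_life_table(path: str | Path, name: str | None = None) -> LifeTable:
    """Read a two-column (age, remaining_le) CSV with a header row."""
    path = Path(path)
    with open(path) as fh:
        return _parse_life_table_csv(fh, name=name or path.stem)


def _parse_life_table_csv(fh, name: str) -> LifeTable:
    import csv

    reader = csv.reader(fh)
    header = next(reader, None)
    if header is None or len(header) < 2:
        raise ValueError(f"life table {name!r}: expected header 'age,remaining_le'")
    ages, remaining = [], []
    for row in reader:
        if not row or not row[0].strip():
            continue
        ages.append(float(row[0]))
        remaining.append(float(row[1]))
    return LifeTable(name=name, ages=np.array(ages), remaining=np.array(remaining))


def make_flat_life_table(le_at_birth: float, name: str | None = None) -> LifeTable:
    """Table with ``remaining_le(a) = max(0, le_at_birth - a)``.

    Used for the country-specific sensitivity mode when only life
    expectancy at birth is known.
    """
    if le_at_birth <= 0:
        raise ValueError(f"le_at_birth must be positive, got {le_at_birth}")
    return LifeTable(
        name=name or f"flat:{le_at_birth}",
        ages=np.array([0.0, float(le_at_birth)]),
        remaining=np.array([float(le_at_birth), 0.0]),
    )
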