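"""Disability-weight registry with treated/untreated variants and draw-level
uncertainty.

Each registry entry carries a mean weight in [0, 1] plus a 95% uncertainty
interval.  For uncertainty propagation, a beta distribution is fitted to
every entry — the mean is matched exactly and the concentration is chosen
to minimize the squared error of the 2.5/97.5 percentiles against the
published bounds — and a reproducible draw vector is sampled from it.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
from scipy import optimize, stats

if TYPE_CHECKING:  # pragma: no cover
    from .burden import InjuryPattern
    from .records import InjuryRecord

DEFAULT_N_DRAWS = 1000


class Variant(str, enum.Enum):
    TREATED = "treated"
    UNTREATED = "untreated"
    SINGLE = "single"


class DWMatchError(KeyError):
    """A record's disability-weight code cannot be resolved in the registry."""


@dataclass(frozen=True)
class DisabilityWeightEntry:
    code: str
    description: str
    variant: Variant
    mean: float
    ui_lower: float
    ui_upper: float
    draws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.ui_lower <= self.mean <= self.ui_upper <= 1.0:
            raise ValueError(
                f"DW {self.code}/{self.variant.value}: need "
                f"0 <= lower <= mean <= upper <= 1, got "
                f"({self.ui_lower}, {self.mean}, {self.ui_upper})"
            )
        if self.draws is not None:
            draws = np.asarray(self.draws, dtype=float)
            if draws.min() < 0 or draws.max() > 1:
                raise ValueError(f"DW {self.code}: draws outside [0, 1]")
            object.__setattr__(self, "draws", draws)

    @property
    def is_degenerate(self) -> bool:
        return self.ui_lower == self.mean == self.ui_upper


class DWRegistry:
    """Entries keyed by ``(code, variant)``."""

    def __init__(self, entries: Iterable[DisabilityWeightEntry]):
        self._entries: dict[tuple[str, Variant], DisabilityWeightEntry] = {}
        for entry in entries:
            key = (entry.code, entry.variant)
            if key in self._entries:
                raise ValueError(f"duplicate DW entry {key}")
            self._entries[key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, code: str, variant: Variant) -> DisabilityWeightEntry:
        try:
            return self._entries[(code, Variant(variant))]
        except KeyError:
            raise DWMatchError(f"no DW entry for ({code!r}, {Variant(variant).value})") from None

    def has(self, code: str, variant: Variant) -> bool:
        return (code, Variant(variant)) in self._entries

    @property
    def codes(self) -> set[str]:
        return {code for code, _ in self._entries}

    @property
    def n_draws(self) -> int | None:
        for entry in self._entries.values():
            if entry.draws is not None:
                return len(entry.draws)
        return None

    def long_term_codes(self) -> set[str]:
        """Codes that carry a treated or untreated variant."""
        return {
            code
            for code, variant in self._entries
            if variant in (Variant.TREATED, Variant.UNTREATED)
        }

    def can_match(self, record: "InjuryRecord") -> bool:
        """Whether *some* entry can be resolved for this record's code.

        Used by the completeness filter; the care-dependent variant choice
        is handled by :func:`match_dw`.
        """
        if record.dw_code is None:
            return False
        code = record.dw_code
        return any(self.has(code, v) for v in Variant)

    def with_draws(self, n_draws: int = DEFAULT_N_DRAWS, seed: int = 0) -> "DWRegistry":
        return generate_draws(self, n_draws=n_draws, seed=seed)


def load_dw_registry(path: str | Path | None = None) -> DWRegistry:
    """Load a registry CSV (columns: code, description, variant, mean,
    ui_lower, ui_upper).  With no path, loads the bundled starter set."""
    if path is None:
        from importlib.resources import files

        text = files("conflictburden.data").joinpath("dw_registry.csv").read_text()
        fh = io.StringIO(text)
        return _parse_registry(fh, source="<bundled>")
    with open(path, newline="") as fh:
        return _parse_registry(fh, source=str(path))


def _parse_registry(fh, source: str) -> DWRegistry:
    reader = csv.DictReader(fh)
    required = {"code", "variant", "mean", "ui_lower", "ui_upper"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(f"DW registry {source}: header must include {sorted(required)}")
    entries = []
    for row in reader:
        try:
            entries.append(
                DisabilityWeightEntry(
                    code=row["code"].strip(),
                    description=(row.get("description") or "").strip(),
                    variant=Variant(row["variant"].strip()),
                    mean=float(row["mean"]),
                    ui_lower=float(row["ui_lower"]),
                    ui_upper=float(row["ui_upper"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"DW registry {source}, code {row.get('code')!r}: {exc}") from exc
    return DWRegistry(entries)


# ---------------------------------------------------------------------------
# Beta fitting and draw generation
# ---------------------------------------------------------------------------

def fit_beta(mean: float, ui_lower: float, ui_upper: float) -> tuple[float, float] | None:
    """Fit beta parameters (alpha, beta) matching ``mean`` exactly and
    minimizing squared error of the 2.5/97.5 percentiles.

    Returns ``None`` for a degenerate entry (point mass).  The analytic
    mean of the returned distribution equals ``mean`` by construction.
    """
    if ui_lower == mean == ui_upper:
        return None
    if not 0.0 < mean < 1.0:
        # Mean pinned to a boundary with a nonzero interval cannot be a beta.
        raise ValueError(f"cannot fit beta with boundary mean {mean} and nonzero UI")

    def objective(log10_conc: float) -> float:
        conc = 10.0**log10_conc
        a, b = mean * conc, (1.0 - mean) * conc
        lo, hi = stats.beta.ppf([0.025, 0.975], a, b)
        return (lo - ui_lower) ** 2 + (hi - ui_upper) ** 2

    res = optimize.minimize_scalar(objective, bounds=(-2.0, 8.0), method="bounded")
    conc = 10.0**res.x
    return mean * conc, (1.0 - mean) * conc


def generate_draws(
    registry: DWRegistry, n_draws: int = DEFAULT_N_DRAWS, seed: int = 0
) -> DWRegistry:
    """Return a registry copy with a reproducible draw vector per entry.

    Each entry gets an independent substream derived from ``seed`` and its
    position in (code, variant) sort order, so draws are deterministic and
    insensitive to registry insertion order.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    entries = sorted(registry, key=lambda e: (e.code, e.variant.value))
    out = []
    for idx, entry in enumerate(entries):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), idx]))
        params = fit_beta(entry.mean, entry.ui_lower, entry.ui_upper)
        if params is None:
            draws = np.full(n_draws, entry.mean)
        else:
            a, b = params
            draws = rng.beta(a, b, size=n_draws)
        out.append(replace(entry, draws=draws))
    return DWRegistry(out)


# ---------------------------------------------------------------------------
# Matching records to entries
# ---------------------------------------------------------------------------

def is_treated(care, unknown_care_treated: bool = True) -> bool:
    """All levels of post-injury care collapse to 'treated'; only 'none' is
    untreated; 'unknown' defaults to treated (configurable)."""
    from .records import Care

    care = Care(care)
    if care is Care.NONE:
        return False
    if care is Care.UNKNOWN:
        return unknown_care_treated
    return True


def match_dw(
    record: "InjuryRecord",
    pattern: "InjuryPattern",
    registry: DWRegistry,
    unknown_care_treated: bool = True,
) -> DisabilityWeightEntry:
    """Resolve the disability-weight entry for a complete non-death record.

    Long-term and permanent patterns resolve ``(code, treated|untreated)``
    by care status; short-term patterns prefer the ``single`` variant and
    fall back to the care-dependent one.
    """
    from .burden import InjuryPattern

    pattern = InjuryPattern(pattern)
    if pattern is InjuryPattern.DEATH:
        raise ValueError("death records carry no disability weight")
    code = record.dw_code
    if code is None:
        raise DWMatchError(f"record {record.person_id} has no dw_code")

    care_variant = (
        Variant.TREATED
        if is_treated(record.care, unknown_care_treated)
        else Variant.UNTREATED
    )
    if pattern is InjuryPattern.SHORT_TERM:
        order = (Variant.SINGLE, care_variant)
    else:
        order = (care_variant, Variant.SINGLE)
    for variant in order:
        if registry.has(code, variant):
            return registry.get(code, variant)
    raise DWMatchError(
        f"record {record.person_id}: no resolvable DW for code {code!r} "
        f"(tried {[v.value for v in order]})"
    )
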