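"""Herdbook record containers: per-cow longitudinal events for one farm.

Dates are year-month only (the model is monthly); ``pandas.Period`` with
monthly frequency is used throughout.  Validation mirrors what a clean
herdbook export must satisfy: strictly increasing calvings at least
MIN_CALVING_INTERVAL months apart, test days inside the cow's productive
window, and culling reasons restricted to the 12-category vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

#: The 12-category culling-reason vocabulary.
REASONS: tuple[str, ...] = (
    "calving_issues",
    "others",
    "respiratory",
    "udder_health",
    "fertility",
    "claw",
    "slow_milking",
    "sold_alive",
    "metabolic",
    "accident",
    "inadequate_performance",
    "somatic_cell_count",
)

REASON_INDEX = {r: i for i, r in enumerate(REASONS)}

#: Reasons whose terminal income is carcass value (all but live sales).
CARCASS_REASONS = tuple(r for r in REASONS if r != "sold_alive")

#: Human-readable labels used in reports, keyed by reason code.
REASON_LABELS = {
    "calving_issues": "Calving issues",
    "others": "Others",
    "respiratory": "Respiratory disease",
    "udder_health": "Udder health",
    "fertility": "Fertility",
    "claw": "Claw issues",
    "slow_milking": "Slow milking",
    "sold_alive": "Sold alive",
    "metabolic": "Metabolic disease",
    "accident": "Accidents/injuries",
    "inadequate_performance": "Inadequate performance",
    "somatic_cell_count": "Somatic cell count",
}

# Accepted spellings (lower-cased, punctuation collapsed) -> reason code.
_REASON_ALIASES = {
    "calving issues": "calving_issues",
    "calving": "calving_issues",
    "others": "others",
    "other": "others",
    "respiratory disease": "respiratory",
    "respiratory": "respiratory",
    "udder health": "udder_health",
    "udder": "udder_health",
    "mastitis": "udder_health",
    "fertility": "fertility",
    "fertility issues": "fertility",
    "claw issues": "claw",
    "claw": "claw",
    "slow milking": "slow_milking",
    "sold alive": "sold_alive",
    "metabolic disease": "metabolic",
    "metabolic": "metabolic",
    "accidents injuries": "accident",
    "accident": "accident",
    "accidents": "accident",
    "injuries": "accident",
    "inadequate performance": "inadequate_performance",
    "performance": "inadequate_performance",
    "somatic cell count": "somatic_cell_count",
    "scc": "somatic_cell_count",
}
for _r in REASONS:
    _REASON_ALIASES.setdefault(_r, _r)
    _REASON_ALIASES.setdefault(_r.replace("_", " "), _r)

MIN_CALVING_INTERVAL = 10  # months

KNOWN_BREEDS = ("BV", "HO", "OB", "SF", "MO")


class RecordError(ValueError):
    """A herdbook record violating a container invariant."""


def normalize_reason(raw: str) -> tuple[str, bool]:
    """Map a raw culling-reason string onto the 12-category vocabulary.

    Matching is case-insensitive and ignores punctuation.  Returns
    ``(code, recognized)``; unrecognized strings map to ``"others"`` with
    ``recognized=False`` so callers can warn without dropping the event.
    """
    key = re.sub(r"[^a-z0-9 ]+", " ", str(raw).strip().lower())
    key = re.sub(r"\s+", " ", key).strip()
    code = _REASON_ALIASES.get(key)
    if code is None:
        return "others", False
    return code, True


def as_period(value) -> pd.Period:
    """Parse a year-month; day-of-month in inputs is truncated."""
    p = pd.Period(value, freq="M")
    if p is pd.NaT:
        raise ValueError(f"unparseable year-month: {value!r}")
    return p


@dataclass(frozen=True)
class TestDay:
    """One monthly milk-recording measurement."""

    month: pd.Period
    milk_kg: float
    fat_pct: float
    protein_pct: float

    def __post_init__(self):
        if self.milk_kg < 0:
            raise RecordError(f"milk_kg must be >= 0, got {self.milk_kg}")
        for name in ("fat_pct", "protein_pct"):
            v = getattr(self, name)
            if not (0 < v < 10):
                raise RecordError(f"{name} must lie in (0, 10), got {v}")


@dataclass(frozen=True)
class CullingEvent:
    """Removal of a cow from the herd, with its coded reason."""

    month: pd.Period
    reason: str

    def __post_init__(self):
        if self.reason not in REASONS:
            raise RecordError(f"unknown culling reason code {self.reason!r}")


@dataclass
class CowRecord:
    """Longitudinal event record for one cow.

    Invariants: calvings strictly increasing and at least
    ``MIN_CALVING_INTERVAL`` months apart; test-day months between the first
    calving and the culling month (if any).
    """

    cow_id: str
    breed: str = "BV"
    calvings: list[pd.Period] = field(default_factory=list)
    testdays: list[TestDay] = field(default_factory=list)
    inseminations: list[pd.Period] = field(default_factory=list)
    culling: CullingEvent | None = None

    def validate(self) -> None:
        for a, b in zip(self.calvings, self.calvings[1:]):
            gap = (b - a).n
            if gap < MIN_CALVING_INTERVAL:
                raise RecordError(
                    f"cow {self.cow_id}: calvings {a} and {b} only {gap} months "
                    f"apart (minimum {MIN_CALVING_INTERVAL})"
                )
        if self.calvings:
            first = self.calvings[0]
            last = self.culling.month if self.culling else None
            for td in self.testdays:
                if td.month < first:
                    raise RecordError(
                        f"cow {self.cow_id}: test day {td.month} before first calving {first}"
                    )
                if last is not None and td.month > last:
                    raise RecordError(
                        f"cow {self.cow_id}: test day {td.month} after culling {last}"
                    )
        elif self.testdays:
            raise RecordError(f"cow {self.cow_id}: test days but no calving record")

    def event_months(self) -> list[pd.Period]:
        months = list(self.calvings) + [td.month for td in self.testdays]
        months += list(self.inseminations)
        if self.culling is not None:
            months.append(self.culling.month)
        return months


@dataclass
class Herdbook:
    """Per-cow longitudinal event records for one farm over one period."""

    farm_id: str
    cows: list[CowRecord]
    period: tuple[pd.Period, pd.Period]

    def validate(self) -> None:
        start, end = self.period
        if end < start:
            raise RecordError(f"farm {self.farm_id}: period end {end} before start {start}")
        seen: set[str] = set()
        for cow in self.cows:
            if cow.cow_id in seen:
                raise RecordError(f"farm {self.farm_id}: duplicate cow id {cow.cow_id}")
            seen.add(cow.cow_id)
            cow.validate()
            for month in cow.event_months():
                if not (start <= month <= end):
                    raise RecordError(
                        f"farm {self.farm_id}, cow {cow.cow_id}: event {month} "
                        f"outside period {start}..{end}"
                    )

    def cow(self, cow_id: str) -> CowRecord:
        for c in self.cows:
            if c.cow_id == cow_id:
                return c
        raise KeyError(cow_id)

    @property
    def n_months(self) -> int:
        return (self.period[1] - self.period[0]).n + 1

    def herd_size_by_month(self) -> pd.Series:
        """Number of cows present (first calving .. removal) each month."""
        start, end = self.period
        idx = pd.period_range(start, end, freq="M")
        counts = pd.Series(0, index=idx)
        for cow in self.cows:
            if not cow.calvings:
                continue
            entry = cow.calvings[0]
            exit_ = cow.culling.month if cow.culling else end
            counts.loc[entry:exit_] += 1
        return counts

    def culling_events(self) -> list[tuple[str, CullingEvent, int]]:
        """All culling events as (cow_id, event, parity at removal)."""
        out = []
        for cow in self.cows:
            if cow.culling is None:
                continue
            parity = sum(1 for c in cow.calvings if c <= cow.culling.month)
            out.append((cow.cow_id, cow.culling, parity))
        return out
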