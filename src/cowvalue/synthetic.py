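"""Synthetic herdbook generator with known ground truth.

Simulates each cow month by month from a ground-truth transition kernel
(conception probabilities, cause-specific culling hazards) and emits the
same record types a herdbook export contains: calvings, monthly test days
(Wood-curve yields with lognormal noise), inseminations and culling events.
Culled cows are replaced by first-parity heifers in the following month so
the herd size stays constant, and the full study period starts from a
startup herd of fresh first-parity cows.  Identical (truth, n_months,
seed) inputs reproduce byte-identical herdbooks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (REASONS, KNOWN_BREEDS, CowRecord, CullingEvent,
                      Herdbook, TestDay)
from .states import CowState, StateSpace, build_state_space, parity_class
from .transitions import TransitionModel

#: Default cause mix of culling hazards (shares of total hazard), shaped
#: like the removal-reason profile of Swiss field herds: fertility and
#: udder health dominate, followed by voluntary live sales and performance.
DEFAULT_REASON_MIX = np.array([
    0.031,  # calving_issues
    0.071,  # others
    0.005,  # respiratory
    0.226,  # udder_health
    0.264,  # fertility
    0.074,  # claw
    0.005,  # slow_milking
    0.137,  # sold_alive
    0.020,  # metabolic
    0.061,  # accident
    0.098,  # inadequate_performance
    0.007,  # somatic_cell_count
])
DEFAULT_REASON_MIX = DEFAULT_REASON_MIX / DEFAULT_REASON_MIX.sum()

#: Monthly all-cause culling hazard by parity class {1, 2, 3+}; rises with
#: parity and yields an annual replacement rate in the low twenties.
DEFAULT_HAZARD_BY_CLASS = (0.012, 0.020, 0.032)

#: Monthly conception probability for eligible open cows by parity class.
DEFAULT_CONCEPTION_BY_CLASS = (0.40, 0.35, 0.31)

#: Wood parameters (a kg/month, b, c /month) by parity class: first-parity
#: cows peak lower and flatter, mature cows higher and steeper.
DEFAULT_WOOD_BY_CLASS = ((620.0, 0.18, 0.035),
                         (700.0, 0.22, 0.045),
                         (750.0, 0.25, 0.050))


class GroundTruthError(ValueError):
    """Invalid ground-truth configuration (e.g. exit probabilities > 1)."""


@dataclass
class GroundTruth:
    """Generator parameters: the known truth behind a synthetic farm.

    ``conception_prob[k, m]`` is the monthly conception probability of an
    eligible open cow of parity class k+1 at month in milk m;
    ``cull_hazard[k, r]`` the monthly probability of removal for reason r.
    """

    conception_prob: np.ndarray = None      # (3, m_max + 1)
    cull_hazard: np.ndarray = None          # (3, 12)
    wood_params: np.ndarray = None          # (3, 3): a, b, c per class
    fat_mean: float = 4.1
    protein_mean: float = 3.35
    fat_sd: float = 0.25
    protein_sd: float = 0.12
    milk_sigma: float = 0.1                 # lognormal test-day noise (log sd)
    cow_effect_sigma: float = 0.1           # lognormal between-cow effect
    herd_size: int = 80
    p_max: int = 12
    m_max: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.conception_prob is None:
            cp = np.zeros((3, self.m_max + 1))
            for k, base in enumerate(DEFAULT_CONCEPTION_BY_CLASS):
                cp[k, 2:] = base
            self.conception_prob = cp
        if self.cull_hazard is None:
            self.cull_hazard = (np.array(DEFAULT_HAZARD_BY_CLASS)[:, None]
                                * DEFAULT_REASON_MIX[None, :])
        if self.wood_params is None:
            self.wood_params = np.array(DEFAULT_WOOD_BY_CLASS)
        self.conception_prob = np.asarray(self.conception_prob, dtype=float)
        self.cull_hazard = np.asarray(self.cull_hazard, dtype=float)
        self.wood_params = np.asarray(self.wood_params, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.herd_size < 1:
            raise GroundTruthError("herd_size must be >= 1")
        if np.any(self.conception_prob < 0) or np.any(self.conception_prob > 1):
            raise GroundTruthError("conception probabilities must lie in [0, 1]")
        if np.any(self.cull_hazard < 0):
            raise GroundTruthError("hazards must be >= 0")
        total = self.cull_hazard.sum(axis=1)
        if np.any(total > 1):
            raise GroundTruthError(
                f"total monthly culling hazard exceeds 1 (max {total.max():.3f})")

    # -- model views -------------------------------------------------------

    def space(self) -> StateSpace:
        return build_state_space(self.p_max, self.m_max)

    def transition_model(self, space: StateSpace | None = None) -> TransitionModel:
        """The exact kernel implied by this ground truth."""
        space = space or self.space()
        K = space.n_transient
        p_cull = np.zeros(K)
        p_conceive = np.zeros(K)
        split = np.zeros((K, len(REASONS)))
        totals = self.cull_hazard.sum(axis=1)
        for i, s in enumerate(space.states):
            k = parity_class(s.parity) - 1
            p_cull[i] = totals[k]
            split[i] = self.cull_hazard[k]
            if space.conception_eligible(s):
                p_conceive[i] = self.conception_prob[k, s.month_in_milk]
        return TransitionModel(space, p_cull, split, p_conceive)

    def expected_yield(self, cls: int, mim: int) -> float:
        a, b, c = self.wood_params[cls - 1]
        return float(a * mim ** b * np.exp(-c * mim))


@dataclass
class TruthSampler:
    """Distribution over per-farm ground truths for a multi-farm study.

    Farms differ in herd size and in multiplicative farm effects on
    hazards, conception and milk scale, emulating between-herd variation.
    """

    herd_size_range: tuple[int, int] = (20, 100)
    hazard_log_sd: float = 0.20
    conception_log_sd: float = 0.10
    milk_log_sd: float = 0.08

    def draw(self, rng: np.random.Generator) -> GroundTruth:
        base = GroundTruth()
        hz = float(np.exp(rng.normal(0.0, self.hazard_log_sd)))
        cz = float(np.exp(rng.normal(0.0, self.conception_log_sd)))
        mz = float(np.exp(rng.normal(0.0, self.milk_log_sd)))
        wood = base.wood_params.copy()
        wood[:, 0] *= mz
        return GroundTruth(
            conception_prob=np.clip(base.conception_prob * cz, 0.0, 0.95),
            cull_hazard=np.clip(base.cull_hazard * hz, 0.0, 1.0),
            wood_params=wood,
            herd_size=int(rng.integers(self.herd_size_range[0],
                                       self.herd_size_range[1] + 1)),
        )


@dataclass
class _SimCow:
    cow_id: str
    breed: str
    effect: float
    state_idx: int
    record: CowRecord


def generate_farm(truth: GroundTruth, n_months: int = 60, seed: int = 0,
                  farm_id: str = "farm-01",
                  start: str | pd.Period = "2018-01") -> Herdbook:
    """Simulate one farm month by month from the ground-truth kernel.

    All initial cows calve for the first time in the first simulated month
    (a startup herd); culled cows are replaced the following month so the
    herd size is constant from month 2 on.  Milk is recorded to 0.01 kg so
    a write/read round trip is exact.
    """
    if n_months < 12:
        raise ValueError("n_months must be >= 12")
    truth.validate()
    space = truth.space()
    model = truth.transition_model(space)
    rng = np.random.default_rng(seed)
    start = pd.Period(start, freq="M")
    period = (start, start + n_months - 1)

    cows: list[CowRecord] = []
    herd: list[_SimCow] = []
    counter = 0

    def new_cow(month: pd.Period) -> _SimCow:
        nonlocal counter
        counter += 1
        cow_id = f"{farm_id}-C{counter:04d}"
        breed = str(rng.choice(KNOWN_BREEDS, p=[0.45, 0.30, 0.08, 0.12, 0.05]))
        effect = float(np.exp(rng.normal(0.0, truth.cow_effect_sigma)))
        record = CowRecord(cow_id=cow_id, breed=breed, calvings=[month])
        cows.append(record)
        return _SimCow(cow_id, breed, effect,
                       space.index(CowState(1, 1, 0)), record)

    for _ in range(truth.herd_size):
        herd.append(new_cow(start))

    dry_from = space.gestation - 2  # no test day in the last 2 gestation months

    for t in range(n_months):
        month = start + t
        entrants: list[_SimCow] = []
        for cow in herd:
            s = space.state(cow.state_idx)
            # monthly records
            if s.month_in_pregnancy <= dry_from:
                cls = parity_class(s.parity)
                milk = (truth.expected_yield(cls, s.month_in_milk) * cow.effect
                        * float(np.exp(rng.normal(0.0, truth.milk_sigma))))
                fat = float(np.clip(rng.normal(truth.fat_mean, truth.fat_sd),
                                    1.0, 9.0))
                protein = float(np.clip(
                    rng.normal(truth.protein_mean, truth.protein_sd), 1.0, 9.0))
                cow.record.testdays.append(TestDay(
                    month=month, milk_kg=round(milk, 2), fat_pct=round(fat, 2),
                    protein_pct=round(protein, 2)))
            if space.conception_eligible(s):
                cow.record.inseminations.append(month)
            # transition
            i = cow.state_idx
            u = rng.random()
            if u < model.p_cull[i]:
                reason = REASONS[int(rng.choice(len(REASONS),
                                                p=model.cull_split[i]))]
                cow.record.culling = CullingEvent(month=month, reason=reason)
                cow.state_idx = -1
                if t + 1 < n_months:
                    entrants.append(new_cow(month + 1))
            else:
                u2 = (u - model.p_cull[i]) / (1.0 - model.p_cull[i])
                if model.next_conceive[i] >= 0 and u2 < model.p_conceive[i]:
                    cow.state_idx = int(model.next_conceive[i])
                else:
                    nxt = int(model.next_continue[i])
                    if model.is_calving[i]:
                        cow.record.calvings.append(month + 1)
                    cow.state_idx = nxt
        herd = [c for c in herd if c.state_idx >= 0] + entrants
        # replacements calve in their entry month (handled by new_cow date)

    # calvings scheduled beyond the period end must not appear in records
    for record in cows:
        record.calvings = [c for c in record.calvings if c <= period[1]]

    hb = Herdbook(farm_id=farm_id, cows=cows, period=period)
    hb.validate()
    return hb


def generate_study(n_farms: int = 29, truth_sampler: TruthSampler | None = None,
                   seed: int = 0, n_months: int = 60,
                   start: str | pd.Period = "2018-01"
                   ) -> list[tuple[Herdbook, GroundTruth]]:
    """Generate a multi-farm study with per-farm ground truths.

    Deterministic under ``seed``; per-farm generation seeds are drawn from
    one master generator so farms are independent but reproducible.
    """
    if n_farms < 1:
        raise ValueError("n_farms must be >= 1")
    sampler = truth_sampler or TruthSampler()
    master = np.random.default_rng(seed)
    out = []
    for f in range(1, n_farms + 1):
        truth = sampler.draw(master)
        farm_seed = int(master.integers(0, 2**31 - 1))
        truth.seed = farm_seed
        hb = generate_farm(truth, n_months=n_months, seed=farm_seed,
                           farm_id=f"farm-{f:02d}", start=start)
        out.append((hb, truth))
    return out


def ground_truth_to_config(truth: GroundTruth) -> dict:
    """Flat key-value serialisation of a ground truth (for test harnesses)."""
    return {
        "herd_size": truth.herd_size,
        "p_max": truth.p_max,
        "m_max": truth.m_max,
        "seed": truth.seed,
        "fat_mean": truth.fat_mean,
        "protein_mean": truth.protein_mean,
        "milk_sigma": truth.milk_sigma,
        "cow_effect_sigma": truth.cow_effect_sigma,
        "conception_prob": truth.conception_prob.tolist(),
        "cull_hazard": truth.cull_hazard.tolist(),
        "wood_params": truth.wood_params.tolist(),
    }


def ground_truth_from_config(cfg: dict) -> GroundTruth:
    kwargs = dict(cfg)
    for key in ("conception_prob", "cull_hazard", "wood_params"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = np.asarray(kwargs[key], dtype=float)
    return GroundTruth(**kwargs)
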