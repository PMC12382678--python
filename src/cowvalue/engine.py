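"""Cow-value engine: expected lifetime economics of an absorbing Markov cow.

Starting from a cow's current state the chain is iterated until absorption
(culling).  Expected quantities are computed exactly from the fundamental
matrix of the absorbing chain: with transient kernel Q, the expected
remaining months N, expected future calvings P and expected total cash T
solve ``(I - Q) x = rhs`` for the appropriate per-state right-hand side.
The average monthly contribution margin is the expected total cash divided
by the expected number of productive months, and

    cow_value = avg_mcm(cow) - avg_mcm(replacement heifer)

where the replacement starts at (parity 1, month 1, open), performs at the
herd-average lactation curve, and is charged the heifer acquisition cost in
her first month.  A vectorised Monte-Carlo path simulator provides an
independent oracle for every analytic expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import economics as econmod
from .economics import EconomicParams
from .lactation import WoodFit, wood_yield
from .records import REASON_INDEX
from .states import CowState, parity_class
from .transitions import TransitionModel

RESIDUAL_TOL = 1e-9


class TruncationWarning(UserWarning):
    """Horizon reached with non-negligible unabsorbed probability mass."""


@dataclass(frozen=True)
class CowValueResult:
    """Cow-versus-replacement comparison for one start state."""

    avg_mcm_cow: float
    avg_mcm_replacement: float
    expected_remaining_months: float
    expected_remaining_parities: float

    @property
    def cow_value(self) -> float:
        return self.avg_mcm_cow - self.avg_mcm_replacement


@dataclass(frozen=True)
class ScenarioSpec:
    """What-if variant of the cow stream.

    ``yield_multiplier`` scales the cow's expected milk yields (never the
    replacement's); ``one_time_cost`` is charged at month offset +1,
    weighted by the probability of surviving to that month;
    ``pregnancy_override`` re-seeds the start state's month in pregnancy.
    """

    yield_multiplier: float = 1.0
    one_time_cost: float = 0.0
    pregnancy_override: int | None = None

    def __post_init__(self):
        if self.yield_multiplier <= 0:
            raise ValueError("yield_multiplier must be > 0")
        if self.one_time_cost < 0:
            raise ValueError("one_time_cost must be >= 0")


# ---------------------------------------------------------------------------
# low-level primitives on a raw transient kernel Q (used by toy-chain tests
# as well as by the full engine)
# ---------------------------------------------------------------------------

def occupancy_trajectory(Q, start: int, horizon: int, absorb_split=None,
                         tol: float = RESIDUAL_TOL):
    """Iterate state occupancy month by month from a start state.

    Parameters
    ----------
    Q : (K, K) array or sparse matrix
        Substochastic transient kernel; row deficits are absorption.
    start : int
        Start state index (occupancy 1 in month 1).
    horizon : int
        Maximum number of months to iterate.
    absorb_split : (K, R) array, optional
        Per-state distribution of absorption over causes; when given the
        per-month absorbed mass is split accordingly.

    Returns
    -------
    occupancy : (T, K) ndarray
        ``occupancy[t-1, s]`` is the probability of being alive in state s
        in month t.
    absorbed : (T,) or (T, R) ndarray
        Probability of being absorbed between months t and t+1.

    Iteration stops early once unabsorbed mass falls below ``tol``; a
    :class:`TruncationWarning` is emitted if the horizon is hit with
    residual mass >= 1e-6.
    """
    Q = sp.csr_matrix(Q)
    K = Q.shape[0]
    v = np.zeros(K)
    v[start] = 1.0
    row_absorb = 1.0 - np.asarray(Q.sum(axis=1)).ravel()
    occ, absorbed = [], []
    for _ in range(horizon):
        occ.append(v.copy())
        a = v * row_absorb
        absorbed.append(absorb_split.T @ a if absorb_split is not None else a.sum())
        v = Q.T @ v
        if v.sum() < tol:
            break
    else:
        if v.sum() >= 1e-6:
            warnings.warn(
                f"horizon {horizon} reached with unabsorbed mass {v.sum():.3e}",
                TruncationWarning, stacklevel=2)
    return np.array(occ), np.array(absorbed)


def _solve_fundamental(Q, rhs):
    ImQ = sp.eye(Q.shape[0], format="csc") - sp.csc_matrix(Q)
    return spla.spsolve(ImQ, rhs)


def expected_remaining_months(Q, start: int | None = None):
    """Expected months until absorption: row sums of the fundamental matrix.

    Returns the full per-state vector, or a scalar when ``start`` is given.
    """
    n = _solve_fundamental(Q, np.ones(sp.csr_matrix(Q).shape[0]))
    return float(n[start]) if start is not None else n


def expected_event_count(Q, event_prob, start: int | None = None):
    """Expected number of future events before absorption.

    ``event_prob[s]`` is the probability that the transition out of state s
    is the event of interest (e.g. a calving).
    """
    x = _solve_fundamental(Q, np.asarray(event_prob, dtype=float))
    return float(x[start]) if start is not None else x


def expected_total_cash(Q, cash, start: int | None = None):
    """Expected total cash before absorption; ``cash[s]`` is the expected
    cash flow of one month spent in state s (terminal income folded in as
    ``p_absorb * income``)."""
    x = _solve_fundamental(Q, np.asarray(cash, dtype=float))
    return float(x[start]) if start is not None else x


# ---------------------------------------------------------------------------
# full engine over the cow state space
# ---------------------------------------------------------------------------

class CowValueEngine:
    """Bundles a transition model, economics and herd lactation curves.

    The (I - Q) factorisation is computed once and reused for every cow on
    a farm, so per-cow valuations are a sparse triangular solve each.
    """

    def __init__(self, model: TransitionModel, econ: EconomicParams,
                 herd_curves: dict[int, WoodFit], fat_pct: float = None,
                 protein_pct: float = None,
                 replacement_state: CowState = CowState(1, 1, 0)):
        self.model = model
        self.space = model.space
        self.econ = econ
        self.herd_curves = herd_curves
        self.fat_pct = econ.fat_reference if fat_pct is None else fat_pct
        self.protein_pct = econ.protein_reference if protein_pct is None else protein_pct
        self.replacement_state = replacement_state

        space = self.space
        K = space.n_transient
        self._parity = np.array([s.parity for s in space.states])
        self._mim = np.array([s.month_in_milk for s in space.states])
        self._preg = np.array([s.month_in_pregnancy for s in space.states])
        self._dry = self._preg > space.gestation - econ.dry_months
        self._calving_month = self._mim == 1
        self._insem_due = (self._preg == 0) & (self._mim >= 3)

        # herd-average yield per state (0 when dry)
        base = np.zeros(K)
        for cls in (1, 2, 3):
            mask = np.array([parity_class(p) == cls for p in self._parity])
            base[mask] = wood_yield(herd_curves[cls].curve, self._mim[mask])
        base[self._dry] = 0.0
        self._base_yield = base

        Q = model.Q()
        self._ImQ_factor = spla.splu(sp.csc_matrix(sp.eye(K) - Q))
        self._Q = Q
        self._months = self._ImQ_factor.solve(np.ones(K))
        calve_prob = (1.0 - model.p_cull) * model.is_calving
        self._parities = self._ImQ_factor.solve(calve_prob)
        self._cull_income = model.expected_cull_income(
            econmod.carcass_income(econ), econ.live_sale_value)
        self._cash_cache: dict[float, np.ndarray] = {}

    # -- per-state cash flows ----------------------------------------------

    def state_cash(self, yield_multiplier: float = 1.0) -> np.ndarray:
        """Expected cash flow of one month in each state (CHF), including
        probability-weighted terminal cull income, for a cow whose yields
        are the herd curve times ``yield_multiplier``."""
        key = round(float(yield_multiplier), 12)
        if key not in self._cash_cache:
            e = self.econ
            y = self._base_yield * yield_multiplier
            milk = econmod.milk_income(y, self.fat_pct, self.protein_pct, e)
            feed = econmod.feed_cost(y, self.fat_pct, self.protein_pct,
                                     e.live_weight, self._preg, e)
            vet = e.vet_cost_yearly / 12.0
            insem = np.where(self._insem_due, e.insemination_cost, 0.0)
            calf = np.where(self._calving_month,
                            e.calf_sale_weight * e.calf_price, 0.0)
            cash = (milk + calf - feed - vet - insem
                    + self.model.p_cull * self._cull_income)
            self._cash_cache[key] = cash
        return self._cash_cache[key]

    # -- expectations -------------------------------------------------------

    def expected_remaining_months(self, state: CowState) -> float:
        return float(self._months[self.space.index(state)])

    def expected_remaining_parities(self, state: CowState) -> float:
        return float(self._parities[self.space.index(state)])

    def average_mcm(self, state: CowState, *, yield_multiplier: float = 1.0,
                    charge_heifer: bool = False,
                    one_time_cost: float = 0.0) -> float:
        """Average monthly contribution margin over the remaining lifetime:
        expected total cash divided by expected remaining months."""
        i = self.space.index(state)
        total = float(self._ImQ_factor.solve(self.state_cash(yield_multiplier))[i])
        if charge_heifer:
            total -= self.econ.heifer_cost
        if one_time_cost:
            survive_next = 1.0 - self.model.p_cull[i]
            total -= one_time_cost * survive_next
        return total / float(self._months[i])

    def replacement_average_mcm(self) -> float:
        return self.average_mcm(self.replacement_state, charge_heifer=True)

    def cow_value(self, state: CowState, cow_effect: float = 1.0,
                  scenario: ScenarioSpec | None = None) -> CowValueResult:
        """Cow value of a cow in ``state`` whose yields are the herd curve
        times ``cow_effect``, optionally under a what-if scenario."""
        spec = scenario or ScenarioSpec()
        if spec.pregnancy_override is not None:
            state = CowState(state.parity, state.month_in_milk,
                             spec.pregnancy_override)
        i = self.space.index(state)
        if i >= self.space.n_transient:
            raise ValueError("start state is absorbed")
        avg_cow = self.average_mcm(
            state, yield_multiplier=cow_effect * spec.yield_multiplier,
            one_time_cost=spec.one_time_cost)
        return CowValueResult(
            avg_mcm_cow=avg_cow,
            avg_mcm_replacement=self.replacement_average_mcm(),
            expected_remaining_months=self.expected_remaining_months(state),
            expected_remaining_parities=self.expected_remaining_parities(state),
        )

    def occupancy(self, state: CowState, horizon: int | None = None,
                  tol: float = RESIDUAL_TOL):
        """Monthly occupancy probabilities plus per-month culling mass
        split by reason (see :func:`occupancy_trajectory`)."""
        horizon = horizon or self.space.p_max * self.space.m_max
        split = self.model.cull_split
        return occupancy_trajectory(self._Q, self.space.index(state), horizon,
                                    absorb_split=split, tol=tol)

    def scenario_grid(self, states, scenarios: dict[str, ScenarioSpec]):
        """Cow values for a grid of states under several scenarios.

        Returns a DataFrame with one row per state and one value column per
        scenario (plus the baseline ``cow_value`` column).
        """
        import pandas as pd
        rows = []
        for s in states:
            row = {"parity": s.parity, "month_in_milk": s.month_in_milk,
                   "month_in_pregnancy": s.month_in_pregnancy,
                   "cow_value": self.cow_value(s).cow_value}
            for name, spec in scenarios.items():
                row[name] = self.cow_value(s, scenario=spec).cow_value
            rows.append(row)
        return pd.DataFrame(rows)


def apply_scenario(engine: CowValueEngine, state: CowState,
                   spec: ScenarioSpec, cow_effect: float = 1.0) -> CowValueResult:
    """Evaluate a what-if scenario (see :class:`ScenarioSpec`)."""
    return engine.cow_value(state, cow_effect=cow_effect, scenario=spec)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonteCarloSummary:
    """Path-simulation estimates with standard errors."""

    n_paths: int
    mean_months: float
    se_months: float
    mean_parities: float
    se_parities: float
    mean_total_cash: float
    se_total_cash: float
    avg_mcm: float
    se_avg_mcm: float


def simulate_paths(p_cull, p_conceive, next_continue, next_conceive,
                   is_calving, base_cash, cull_income_carcass,
                   p_sold_alive, live_sale_value, start: int, n_paths: int,
                   rng: np.random.Generator, horizon: int,
                   heifer_cost: float = 0.0, one_time_cost: float = 0.0):
    """Vectorised lifetime path sampler over a compact successor structure.

    Returns per-path (months, calvings, total_cash) arrays.  ``base_cash``
    must exclude the expected terminal-income term: terminal income is
    sampled (carcass or live sale) and credited to the final month alive.
    """
    state = np.full(n_paths, start, dtype=np.int64)
    alive = np.ones(n_paths, dtype=bool)
    months = np.zeros(n_paths, dtype=np.int64)
    calvings = np.zeros(n_paths, dtype=np.int64)
    cash = np.zeros(n_paths)
    cash -= heifer_cost
    for t in range(1, horizon + 1):
        if not alive.any():
            break
        idx = np.where(alive)[0]
        s = state[idx]
        months[idx] += 1
        cash[idx] += base_cash[s]
        if one_time_cost and t == 2:
            cash[idx] -= one_time_cost
        u = rng.random(idx.size)
        culled = u < p_cull[s]
        cull_idx = idx[culled]
        if cull_idx.size:
            sold = rng.random(cull_idx.size) < p_sold_alive[state[cull_idx]]
            cash[cull_idx] += np.where(sold, live_sale_value, cull_income_carcass)
            alive[cull_idx] = False
        live = idx[~culled]
        if live.size:
            s_live = state[live]
            u2 = (u[~culled] - p_cull[s_live]) / np.maximum(1e-300,
                                                            1.0 - p_cull[s_live])
            conceive = (u2 < p_conceive[s_live]) & (next_conceive[s_live] >= 0)
            nxt = np.where(conceive, next_conceive[s_live],
                           next_continue[s_live])
            calvings[live] += (~conceive) & is_calving[s_live]
            state[live] = nxt
    return months, calvings, cash


def monte_carlo_oracle(engine: CowValueEngine, state: CowState,
                       n_paths: int = 100_000, seed: int = 0, *,
                       yield_multiplier: float = 1.0,
                       charge_heifer: bool = False,
                       one_time_cost: float = 0.0) -> MonteCarloSummary:
    """Simulate lifetime paths from the kernel and summarise the ledgers.

    Deterministic under ``seed``.  ``avg_mcm`` is the ratio estimator
    (total cash across paths over total months across paths), matching the
    engine's expected-total / expected-months definition; its standard
    error comes from the delta method.
    """
    rng = np.random.default_rng(seed)
    model = engine.model
    cash_no_terminal = (engine.state_cash(yield_multiplier)
                        - model.p_cull * engine._cull_income)
    p_sold = model.cull_split[:, REASON_INDEX["sold_alive"]]
    horizon = engine.space.p_max * engine.space.m_max + 1
    months, calvings, cash = simulate_paths(
        model.p_cull, model.p_conceive, model.next_continue,
        model.next_conceive, model.is_calving, cash_no_terminal,
        econmod.carcass_income(engine.econ), p_sold,
        engine.econ.live_sale_value, engine.space.index(state), n_paths, rng,
        horizon, heifer_cost=engine.econ.heifer_cost if charge_heifer else 0.0,
        one_time_cost=one_time_cost)
    mean_m, mean_c = months.mean(), cash.mean()
    se = lambda x: float(x.std(ddof=1) / np.sqrt(n_paths))
    avg = mean_c / mean_m
    resid = cash - avg * months
    se_avg = float(resid.std(ddof=1) / (mean_m * np.sqrt(n_paths)))
    return MonteCarloSummary(
        n_paths=n_paths,
        mean_months=float(mean_m), se_months=se(months),
        mean_parities=float(calvings.mean()), se_parities=se(calvings),
        mean_total_cash=float(mean_c), se_total_cash=se(cash),
        avg_mcm=float(avg), se_avg_mcm=se_avg)
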