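"""Monthly transition kernel over the cow state space.

Each live state has at most three successor events: culling (absorbing,
split over the 12 reasons), conception (open, eligible states only), and
the deterministic "continue" move — open cows age one month in milk,
pregnant cows advance gestation, and cows at 9 months of pregnancy calve
into (parity + 1, month 1, open).  Boundary rules make the chain absorbing:
open cows at the month-in-milk ceiling are culled, as are cows whose next
calving would exceed the parity ceiling.

``estimate_transition_model`` computes maximum-likelihood cell frequencies
from herdbook records with a back-off hierarchy for sparse cells:
state -> pooled over parity -> pooled over month in milk -> global.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .records import REASONS, REASON_INDEX, Herdbook
from .states import CowState, StateSpace

N_MIN_DEFAULT = 20

#: Reason assigned to structurally forced culls (open cow at the month
#: ceiling: reproductive failure; would-be calving beyond the parity
#: ceiling: unspecified voluntary removal).
FORCED_OPEN_REASON = "fertility"
FORCED_PARITY_REASON = "others"


class EstimationError(ValueError):
    """Raised when no transitions are observed."""


def _structure_arrays(space: StateSpace):
    """Deterministic successor structure for every live state.

    Returns (next_continue, next_conceive, is_calving) integer/bool arrays;
    -1 marks "no successor", i.e. a structurally forced cull.
    """
    K = space.n_transient
    next_continue = np.full(K, -1, dtype=np.int64)
    next_conceive = np.full(K, -1, dtype=np.int64)
    is_calving = np.zeros(K, dtype=bool)
    g_max = space.gestation
    for i, s in enumerate(space.states):
        p, m, g = s.parity, s.month_in_milk, s.month_in_pregnancy
        if g == g_max:
            if p < space.p_max:
                next_continue[i] = space.index(CowState(p + 1, 1, 0))
                is_calving[i] = True
        elif g > 0:
            if m < space.m_max:
                next_continue[i] = space.index(CowState(p, m + 1, g + 1))
        else:  # open
            if m < space.m_max:
                next_continue[i] = space.index(CowState(p, m + 1, 0))
            if space.conception_eligible(s):
                next_conceive[i] = space.index(CowState(p, m + 1, 1))
    return next_continue, next_conceive, is_calving


class TransitionModel:
    """Row-stochastic monthly kernel with cause-split culling hazards.

    Parameters
    ----------
    space : StateSpace
    p_cull : (K,) array
        Total monthly culling probability per live state (forced to 1 on
        structurally terminal states).
    cull_split : (K, 12) array
        Distribution over culling reasons given a cull; rows are
        normalised, with a structural default where no information exists.
    p_conceive : (K,) array
        Monthly conception probability given survival; nonzero only for
        open, conception-eligible states.
    """

    def __init__(self, space: StateSpace, p_cull, cull_split, p_conceive):
        self.space = space
        K = space.n_transient
        p_cull = np.asarray(p_cull, dtype=float).copy()
        cull_split = np.asarray(cull_split, dtype=float).copy()
        p_conceive = np.asarray(p_conceive, dtype=float).copy()
        if p_cull.shape != (K,) or p_conceive.shape != (K,) or \
                cull_split.shape != (K, len(REASONS)):
            raise ValueError("probability array shapes do not match the state space")
        if np.any(p_cull < 0) or np.any(p_cull > 1) or \
                np.any(p_conceive < 0) or np.any(p_conceive > 1) or \
                np.any(cull_split < 0):
            raise ValueError("probabilities must lie in [0, 1]")

        nc, ncv, calving = _structure_arrays(space)
        self.next_continue = nc
        self.next_conceive = ncv
        self.is_calving = calving

        # structural rules
        eligible = ncv >= 0
        p_conceive[~eligible] = 0.0
        forced = nc < 0
        p_cull[forced] = 1.0

        # reason split: normalise; default reasons where a row is empty
        row_sums = cull_split.sum(axis=1)
        open_state = np.array([s.month_in_pregnancy == 0 for s in space.states])
        for i in np.where(row_sums <= 0)[0]:
            reason = FORCED_OPEN_REASON if open_state[i] else FORCED_PARITY_REASON
            cull_split[i, REASON_INDEX[reason]] = 1.0
        cull_split /= cull_split.sum(axis=1, keepdims=True)

        self.p_cull = p_cull
        self.cull_split = cull_split
        self.p_conceive = p_conceive

    # -- matrix views ------------------------------------------------------

    def matrix(self) -> sp.csr_matrix:
        """Full (K+1) x (K+1) row-stochastic matrix, CULLED last."""
        K = self.space.n_transient
        rows, cols, vals = [], [], []
        surv = 1.0 - self.p_cull
        for i in range(K):
            rows.append(i)
            cols.append(self.space.culled_index)
            vals.append(self.p_cull[i])
            if surv[i] > 0:
                if self.next_conceive[i] >= 0 and self.p_conceive[i] > 0:
                    rows.append(i)
                    cols.append(self.next_conceive[i])
                    vals.append(surv[i] * self.p_conceive[i])
                stay = surv[i] * (1.0 - self.p_conceive[i])
                if stay > 0:
                    rows.append(i)
                    cols.append(self.next_continue[i])
                    vals.append(stay)
        rows.append(self.space.culled_index)
        cols.append(self.space.culled_index)
        vals.append(1.0)
        mat = sp.csr_matrix((vals, (rows, cols)),
                            shape=(self.space.n_states, self.space.n_states))
        resid = np.abs(np.asarray(mat.sum(axis=1)).ravel() - 1.0).max()
        if resid > 1e-12:
            raise ValueError(f"row sums deviate from 1 by {resid:.2e}")
        return mat

    def Q(self) -> sp.csr_matrix:
        """Transient-to-transient block of the kernel."""
        full = self.matrix()
        K = self.space.n_transient
        return full[:K, :K].tocsr()

    def expected_cull_income(self, carcass_value: float, live_sale_value: float):
        """Per-state expected terminal income given a cull in that state."""
        p_sold = self.cull_split[:, REASON_INDEX["sold_alive"]]
        return carcass_value * (1.0 - p_sold) + live_sale_value * p_sold

    def to_edge_frame(self) -> pd.DataFrame:
        """Serializable edge list (from, to, probability, reason)."""
        rows = []
        surv = 1.0 - self.p_cull
        for i, s in enumerate(self.space.states):
            for r, share in zip(REASONS, self.cull_split[i]):
                pr = self.p_cull[i] * share
                if pr > 0:
                    rows.append((str(s), "CULLED", pr, r))
            if surv[i] > 0:
                if self.next_conceive[i] >= 0 and self.p_conceive[i] > 0:
                    rows.append((str(s), str(self.space.state(self.next_conceive[i])),
                                 surv[i] * self.p_conceive[i], ""))
                stay = surv[i] * (1.0 - self.p_conceive[i])
                if stay > 0:
                    rows.append((str(s), str(self.space.state(self.next_continue[i])),
                                 stay, ""))
        return pd.DataFrame(rows, columns=["from_state", "to_state",
                                           "probability", "reason"])


def transition_matrix(model: TransitionModel) -> sp.csr_matrix:
    """Row-stochastic matrix over the model's state indexing."""
    return model.matrix()


# -- estimation from herdbook records -------------------------------------

def extract_transitions(herdbook: Herdbook, space: StateSpace):
    """Yield observed monthly (state, outcome, reason) triples for one farm.

    Outcomes are ``"cull"`` (with reason), ``"conceive"`` and ``"continue"``.
    Pregnancy inside completed lactations is backdated exactly from the
    next calving (a calving at month t implies conception at t - 10 and
    pregnancy months t-9 .. t-1).  In the final lactation — right-censored
    by culling or by the period end — no later calving exists, so
    conception is inferred from the insemination non-return rule: the cow
    is presumed to have conceived at her last recorded service if no
    return to service follows within the observed window.  Without this,
    every cull would be attributed to an open state and open-state hazards
    would be badly inflated.
    """
    start, end = herdbook.period
    g_max = space.gestation
    for cow in herdbook.cows:
        if not cow.calvings:
            continue
        calvings = sorted(cow.calvings)
        inseminations = sorted(cow.inseminations)
        cull = cow.culling
        last = cull.month if cull is not None else end
        # presumed conception month of the censored final lactation
        final_ins = [i for i in inseminations if calvings[-1] <= i <= last]
        conceived_at = (final_ins[-1]
                        if final_ins and final_ins[-1] < last else None)
        t = calvings[0]
        while t <= last:
            prior = [c for c in calvings if c <= t]
            parity = len(prior)
            mim = (t - prior[-1]).n + 1
            nxt = [c for c in calvings if c > t]
            preg = 0
            conceive_month = False
            if nxt:
                lead = (nxt[0] - t).n
                if lead <= g_max:
                    preg = g_max + 1 - lead  # months since conception month
                conceive_month = lead == g_max + 1
            elif conceived_at is not None:
                since = (t - conceived_at).n
                if 1 <= since <= g_max:
                    preg = since
                conceive_month = since == 0
            if parity > space.p_max or mim > space.m_max:
                t += 1
                continue
            state = CowState(parity, mim, preg)
            if cull is not None and t == last:
                yield state, "cull", cull.reason
            elif t < last:
                if conceive_month and space.conception_eligible(state):
                    yield state, "conceive", None
                else:
                    yield state, "continue", None
            t += 1


@dataclass
class _Counts:
    n: float = 0.0            # hazard denominator (observed at-risk months)
    n_cull: float = 0.0
    n_open: float = 0.0       # conception denominator
    n_conceive: float = 0.0
    reasons: np.ndarray = None

    def __post_init__(self):
        if self.reasons is None:
            self.reasons = np.zeros(len(REASONS))


def estimate_transition_model(herdbooks, space: StateSpace,
                              n_min: int = N_MIN_DEFAULT) -> TransitionModel:
    """Maximum-likelihood transition estimates with hierarchical back-off.

    Cells (states) with fewer than ``n_min`` observations back off to
    estimates pooled over parity, then additionally over month in milk,
    then to the global pool.  Structural zeros and forced-cull boundaries
    are enforced by :class:`TransitionModel`.
    """
    if isinstance(herdbooks, Herdbook):
        herdbooks = [herdbooks]
    K = space.n_transient
    by_state = [_Counts() for _ in range(K)]
    by_mg: dict[tuple[int, int], _Counts] = {}
    by_g: dict[int, _Counts] = {}
    glob = _Counts()

    n_obs = 0
    for hb in herdbooks:
        for state, outcome, reason in extract_transitions(hb, space):
            n_obs += 1
            i = space.index(state)
            keys = [by_state[i],
                    by_mg.setdefault((state.month_in_milk, state.month_in_pregnancy),
                                     _Counts()),
                    by_g.setdefault(state.month_in_pregnancy, _Counts()),
                    glob]
            for c in keys:
                c.n += 1
                if outcome == "cull":
                    c.n_cull += 1
                    c.reasons[REASON_INDEX[reason]] += 1
                elif outcome == "conceive":
                    c.n_open += 1
                    c.n_conceive += 1
                elif outcome == "continue" and space.conception_eligible(state):
                    c.n_open += 1
    if n_obs == 0:
        raise EstimationError("no month-to-month transitions observed")

    p_cull = np.zeros(K)
    p_conceive = np.zeros(K)
    split = np.zeros((K, len(REASONS)))
    for i, s in enumerate(space.states):
        chain = [by_state[i],
                 by_mg.get((s.month_in_milk, s.month_in_pregnancy), _Counts()),
                 by_g.get(s.month_in_pregnancy, _Counts()),
                 glob]
        cell = next((c for c in chain if c.n >= n_min), glob)
        p_cull[i] = cell.n_cull / cell.n if cell.n > 0 else 0.0
        if space.conception_eligible(s):
            ccell = next((c for c in chain if c.n_open >= n_min), glob)
            p_conceive[i] = (ccell.n_conceive / ccell.n_open
                             if ccell.n_open > 0 else 0.0)
        rcell = next((c for c in chain if c.reasons.sum() > 0), glob)
        split[i] = rcell.reasons
    return TransitionModel(space, p_cull, split, p_conceive)


def estimation_counts(herdbooks, space: StateSpace) -> pd.DataFrame:
    """Per-state raw counts, for diagnostics and recovery tests."""
    if isinstance(herdbooks, Herdbook):
        herdbooks = [herdbooks]
    K = space.n_transient
    by_state = [_Counts() for _ in range(K)]
    for hb in herdbooks:
        for state, outcome, reason in extract_transitions(hb, space):
            c = by_state[space.index(state)]
            c.n += 1
            if outcome == "cull":
                c.n_cull += 1
                c.reasons[REASON_INDEX[reason]] += 1
            elif outcome == "conceive":
                c.n_open += 1
                c.n_conceive += 1
            elif outcome == "continue" and space.conception_eligible(state):
                c.n_open += 1
    rows = []
    for i, s in enumerate(space.states):
        c = by_state[i]
        rows.append((s.parity, s.month_in_milk, s.month_in_pregnancy,
                     c.n, c.n_cull, c.n_open, c.n_conceive))
    return pd.DataFrame(rows, columns=["parity", "month_in_milk",
                                       "month_in_pregnancy", "n", "n_cull",
                                       "n_open", "n_conceive"])
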