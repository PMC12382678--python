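"""Audit of farmer culling decisions against the economic optimum.

For every cow the engine computes the cow value at her last observed point
in time; comparing the sign of that value with whether the farmer actually
removed her places each cow in one of four quadrants:

=================  =======================  =====================
                   culled                   retained
=================  =======================  =====================
cow value > 0      replaced_too_soon        retained_ok
cow value < 0      correctly_culled         retained_too_long
=================  =======================  =====================

A cow value of exactly zero is treated as retain-optimal.  Farm-level
losses accumulate the cow values destroyed by suboptimal decisions:
``replaced_loss`` sums (negated) positive values of prematurely culled
cows, ``not_replaced_loss`` sums negative values of cows kept too long;
both are reported as numbers <= 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .engine import CowValueEngine
from .lactation import cow_effects
from .records import REASONS, REASON_LABELS, CowRecord, Herdbook
from .states import CowState, StateSpace

QUADRANTS = ("replaced_too_soon", "correctly_culled", "retained_ok",
             "retained_too_long")

#: Months since the last insemination before a cow with no return to
#: service is presumed pregnant (roughly a 35-day non-return window).
PREG_CONFIRM_MONTHS = 1


@dataclass(frozen=True)
class DecisionRecord:
    """One cow's final state, cow value and decision classification."""

    cow_id: str
    farm_id: str
    final_state: CowState
    cow_value: float
    expected_remaining_parities: float
    culled: bool
    reason: str | None
    quadrant: str


@dataclass(frozen=True)
class FarmAudit:
    """Farm-level aggregation of decision records."""

    farm_id: str
    replaced_loss: float        # <= 0: value destroyed by premature culls
    not_replaced_loss: float    # <= 0: value destroyed by late replacement
    n_cows: int
    replacement_rate: float     # % of the (average) herd removed per year
    loss_per_farm_month: float
    loss_per_cow_month: float
    n_months: int


def classify_decision(cow_value: float, culled: bool) -> str:
    """Map (sign of cow value, culled flag) to its decision quadrant."""
    if not math.isfinite(cow_value):
        raise ValueError(f"cow value must be finite, got {cow_value}")
    if cow_value >= 0:
        return "replaced_too_soon" if culled else "retained_ok"
    return "correctly_culled" if culled else "retained_too_long"


def final_state(cow: CowRecord, end: pd.Period, space: StateSpace,
                preg_confirm_months: int = PREG_CONFIRM_MONTHS
                ) -> tuple[CowState | None, pd.Period | None]:
    """Reconstruct a cow's state at her last observed point in time.

    The last observed month is the latest month carrying any record for
    the cow (capped at the period end).  Parity counts calvings up to that
    month; month in milk runs from the last calving; pregnancy is inferred
    from the insemination history: the cow is presumed pregnant iff her
    last insemination lies at least ``preg_confirm_months`` before the
    last observation, was not followed by a return to service, and the
    implied conception is biologically consistent with the state grid.

    Returns ``(None, None)`` for cows without a calving record (heifers
    not yet in milk).
    """
    if not cow.calvings:
        return None, None
    last_obs = min(max(cow.event_months()), end)
    calvings = [c for c in sorted(cow.calvings) if c <= last_obs]
    if not calvings:
        return None, None
    parity = min(len(calvings), space.p_max)
    mim = min((last_obs - calvings[-1]).n + 1, space.m_max)
    preg = 0
    inseminations = [i for i in sorted(cow.inseminations) if i <= last_obs]
    if inseminations and inseminations[-1] >= calvings[-1]:
        gap = (last_obs - inseminations[-1]).n
        candidate = gap  # months since the (presumed) conception month
        conception_mim = mim - candidate
        if (gap >= preg_confirm_months and 1 <= candidate <= space.gestation
                and 2 <= conception_mim <= space.m_max - space.gestation):
            preg = candidate
    state = CowState(parity, mim, preg)
    if state not in space:
        state = CowState(parity, mim, 0)
    return state, last_obs


def audit_farm(herdbook: Herdbook, engine: CowValueEngine,
               effects: dict[str, float] | None = None,
               preg_confirm_months: int = PREG_CONFIRM_MONTHS
               ) -> tuple[FarmAudit, list[DecisionRecord]]:
    """Audit every cow of one farm against the engine's recommendation.

    ``effects`` maps cow ids to multiplicative yield effects; when omitted
    they are estimated from the herd's test days.  Cows with no calving
    record are excluded with a warning.
    """
    space = engine.space
    if effects is None:
        effects = cow_effects(herdbook, engine.herd_curves)
    records: list[DecisionRecord] = []
    replaced_loss = 0.0
    not_replaced_loss = 0.0
    for cow in herdbook.cows:
        state, last_obs = final_state(cow, herdbook.period[1], space,
                                      preg_confirm_months)
        if state is None:
            warnings.warn(f"cow {cow.cow_id}: no calving record, excluded "
                          "from audit", stacklevel=2)
            continue
        result = engine.cow_value(state, cow_effect=effects.get(cow.cow_id, 1.0))
        culled = cow.culling is not None
        quadrant = classify_decision(result.cow_value, culled)
        if quadrant == "replaced_too_soon":
            replaced_loss -= result.cow_value
        elif quadrant == "retained_too_long":
            not_replaced_loss += result.cow_value
        records.append(DecisionRecord(
            cow_id=cow.cow_id, farm_id=herdbook.farm_id, final_state=state,
            cow_value=result.cow_value,
            expected_remaining_parities=result.expected_remaining_parities,
            culled=culled, reason=cow.culling.reason if culled else None,
            quadrant=quadrant))
    n_months = herdbook.n_months
    years = n_months / 12.0
    herd_size = herdbook.herd_size_by_month()
    avg_herd = float(herd_size.mean()) if len(herd_size) else 0.0
    n_culled = sum(1 for r in records if r.culled)
    rate = 100.0 * n_culled / avg_herd / years if avg_herd > 0 else 0.0
    total_loss = replaced_loss + not_replaced_loss
    audit = FarmAudit(
        farm_id=herdbook.farm_id,
        replaced_loss=replaced_loss,
        not_replaced_loss=not_replaced_loss,
        n_cows=len(records),
        replacement_rate=rate,
        loss_per_farm_month=total_loss / n_months if n_months else 0.0,
        loss_per_cow_month=(total_loss / n_months / avg_herd
                            if n_months and avg_herd > 0 else 0.0),
        n_months=n_months)
    return audit, records


def reason_by_parity(cullings, p_max: int = 12, labels: bool = True
                     ) -> pd.DataFrame:
    """Reason x parity count grid with row/column totals and shares.

    ``cullings`` is an iterable of ``(reason, parity)`` pairs.  Shares are
    percent of the grand total, rounded to one decimal.
    """
    counts = pd.DataFrame(0, index=list(REASONS),
                          columns=list(range(1, p_max + 1)))
    for reason, parity in cullings:
        if reason not in REASONS:
            raise ValueError(f"unknown reason {reason!r}")
        counts.loc[reason, min(int(parity), p_max)] += 1
    grid = counts.copy()
    grid["Total"] = counts.sum(axis=1)
    grand = int(counts.values.sum())
    grid["Share"] = (100.0 * grid["Total"] / grand).round(1) if grand else 0.0
    total_row = counts.sum(axis=0)
    share_row = (100.0 * total_row / grand).round(1) if grand else total_row * 0.0
    grid.loc["Total replaced"] = list(total_row) + [grand, 100.0 if grand else 0.0]
    grid.loc["Share of total (%)"] = list(share_row) + [100.0 if grand else 0.0,
                                                        float("nan")]
    if labels:
        grid = grid.rename(index=REASON_LABELS)
    return grid


def study_summary(audits) -> pd.Series:
    """Study-level aggregation over farm audits.

    Column sums of the losses and cow counts, plus means and standard
    deviations of the per-farm rates.  Accepts a list of
    :class:`FarmAudit` or an equivalent DataFrame.
    """
    frame = audits if isinstance(audits, pd.DataFrame) else farm_audit_frame(audits)
    if len(frame) == 0:
        raise ValueError("study_summary needs at least one farm audit")
    out = {
        "n_farms": len(frame),
        "replaced_loss_total": float(frame["replaced_loss"].sum()),
        "not_replaced_loss_total": float(frame["not_replaced_loss"].sum()),
        "n_cows_total": int(frame["n_cows"].sum()),
        "mean_cows_per_farm": float(frame["n_cows"].mean()),
        "replacement_rate_mean": float(frame["replacement_rate"].mean()),
        "replacement_rate_sd": float(frame["replacement_rate"].std(ddof=1))
        if len(frame) > 1 else 0.0,
    }
    for col in ("loss_per_farm_month", "loss_per_cow_month"):
        if col in frame.columns:
            out[f"{col}_mean"] = float(frame[col].mean())
            out[f"{col}_sd"] = (float(frame[col].std(ddof=1))
                                if len(frame) > 1 else 0.0)
    return pd.Series(out)


def farm_audit_frame(audits) -> pd.DataFrame:
    """Farm audits as a DataFrame sorted by farm id (report layout)."""
    cols = ["farm_id", "replaced_loss", "not_replaced_loss", "n_cows",
            "replacement_rate", "loss_per_farm_month", "loss_per_cow_month",
            "n_months"]
    if isinstance(audits, pd.DataFrame):
        return audits
    rows = [{c: getattr(a, c) for c in cols} for a in audits]
    frame = pd.DataFrame(rows, columns=cols)
    return frame.sort_values("farm_id").reset_index(drop=True)


def decision_frame(records) -> pd.DataFrame:
    """Decision records as a DataFrame sorted by farm and cow id."""
    rows = [{
        "farm_id": r.farm_id, "cow_id": r.cow_id,
        "parity": r.final_state.parity,
        "month_in_milk": r.final_state.month_in_milk,
        "month_in_pregnancy": r.final_state.month_in_pregnancy,
        "cow_value": r.cow_value,
        "expected_remaining_parities": r.expected_remaining_parities,
        "culled": r.culled, "reason": r.reason or "",
        "quadrant": r.quadrant,
    } for r in records]
    cols = ["farm_id", "cow_id", "parity", "month_in_milk",
            "month_in_pregnancy", "cow_value", "expected_remaining_parities",
            "culled", "reason", "quadrant"]
    frame = pd.DataFrame(rows, columns=cols)
    return frame.sort_values(["farm_id", "cow_id"]).reset_index(drop=True)


def study_reason_grid(herdbooks, p_max: int = 12) -> pd.DataFrame:
    """Reason x parity grid pooled over a collection of herdbooks."""
    events = []
    for hb in herdbooks:
        for _, ev, parity in hb.culling_events():
            events.append((ev.reason, parity))
    return reason_by_parity(events, p_max=p_max)
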