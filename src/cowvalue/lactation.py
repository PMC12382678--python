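"""Wood lactation curves: y(m) = a * m^b * exp(-c * m).

Curves are fitted per parity class {1, 2, 3+} by least squares on the
log-linearised model ``log y = log a + b log m - c m`` (deterministic, no
initialisation).  A cow's expected yield is the herd curve of her parity
class scaled by a multiplicative cow effect (her mean test-day ratio to the
herd curve), which keeps per-cow predictions stable on few test days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import Herdbook
from .states import parity_class

MIN_TESTDAYS = 6
MIN_DISTINCT_MONTHS = 4


class InsufficientDataError(ValueError):
    """Too few test days to fit a lactation curve; caller should fall back
    to a herd or default curve."""


@dataclass(frozen=True)
class LactationCurve:
    """Wood-function parameters for one parity class.

    ``a`` is the scale in kg/month, ``b`` the dimensionless rise exponent,
    ``c`` the per-month decay rate.  For b, c > 0 the curve peaks at
    month b / c.
    """

    a: float
    b: float
    c: float
    parity_class: int = 1

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"Wood scale a must be > 0, got {self.a}")

    def peak_month(self) -> float:
        return self.b / self.c if self.c > 0 else math.inf


def wood_yield(curve: LactationCurve, m):
    """Evaluate the Wood curve at month(s) in milk ``m`` (kg/month)."""
    m_arr = np.asarray(m, dtype=float)
    if np.any(m_arr < 1):
        raise ValueError("month in milk must be >= 1")
    return curve.a * m_arr ** curve.b * np.exp(-curve.c * m_arr)


@dataclass(frozen=True)
class WoodFit:
    """A fitted curve with residual standard deviation (log scale) and the
    standard errors of (log a, b, c)."""

    curve: LactationCurve
    resid_sd: float
    se_log_a: float
    se_b: float
    se_c: float
    n_obs: int


def fit_wood(months, yields, parity_cls: int = 1, groups=None) -> WoodFit:
    """Least-squares Wood fit on test days with positive yield.

    Parameters
    ----------
    months, yields : array-like
        Months in milk (>= 1) and milk yields (kg/month).
    groups : array-like, optional
        Cow identifiers; when given, parameter standard errors are
        cluster-robust by cow (test days of one cow share a cow effect).

    Raises
    ------
    InsufficientDataError
        Fewer than 6 usable test days or fewer than 4 distinct months.
    """
    m = np.asarray(months, dtype=float)
    y = np.asarray(yields, dtype=float)
    keep = y > 0
    m, y = m[keep], y[keep]
    if groups is not None:
        groups = np.asarray(groups)[keep]
    if len(y) < MIN_TESTDAYS or len(np.unique(m)) < MIN_DISTINCT_MONTHS:
        raise InsufficientDataError(
            f"need >= {MIN_TESTDAYS} test days over >= {MIN_DISTINCT_MONTHS} "
            f"distinct months, got {len(y)} over {len(np.unique(m))}"
        )
    X = np.column_stack([np.ones_like(m), np.log(m), -m])
    model = sm.OLS(np.log(y), X)
    if groups is not None:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        res = model.fit()
    log_a, b, c = res.params
    se = res.bse
    curve = LactationCurve(a=float(np.exp(log_a)), b=float(b), c=float(c),
                           parity_class=parity_cls)
    resid_sd = float(np.sqrt(res.scale))
    return WoodFit(curve=curve, resid_sd=resid_sd, se_log_a=float(se[0]),
                   se_b=float(se[1]), se_c=float(se[2]), n_obs=len(y))


def _testday_frame(herdbook: Herdbook) -> pd.DataFrame:
    """All test days of a herd with cow id, parity class and month in milk."""
    rows = []
    for cow in herdbook.cows:
        if not cow.calvings:
            continue
        calvings = sorted(cow.calvings)
        for td in cow.testdays:
            # lactation containing this test day
            prior = [c for c in calvings if c <= td.month]
            if not prior:
                continue
            parity = len(prior)
            mim = (td.month - prior[-1]).n + 1
            rows.append((cow.cow_id, parity_class(parity), mim, td.milk_kg,
                         td.fat_pct, td.protein_pct))
    return pd.DataFrame(rows, columns=["cow_id", "parity_class", "mim",
                                       "milk_kg", "fat_pct", "protein_pct"])


def herd_average_curve(herdbook: Herdbook) -> dict[int, WoodFit]:
    """Pool all cows' test days per parity class and fit one curve each.

    Classes without enough data inherit the all-class pooled fit.  Used for
    the replacement heifer benchmark and for cows lacking individual data.

    Raises
    ------
    InsufficientDataError
        If not even the pooled test days support a fit.
    """
    frame = _testday_frame(herdbook)
    if frame.empty:
        raise InsufficientDataError(f"farm {herdbook.farm_id}: no fittable test days")
    pooled = fit_wood(frame["mim"], frame["milk_kg"], parity_cls=0,
                      groups=frame["cow_id"])
    fits: dict[int, WoodFit] = {}
    for cls in (1, 2, 3):
        sub = frame[frame["parity_class"] == cls]
        try:
            fits[cls] = fit_wood(sub["mim"], sub["milk_kg"], parity_cls=cls,
                                 groups=sub["cow_id"])
        except InsufficientDataError:
            fits[cls] = WoodFit(
                curve=LactationCurve(pooled.curve.a, pooled.curve.b,
                                     pooled.curve.c, parity_class=cls),
                resid_sd=pooled.resid_sd, se_log_a=pooled.se_log_a,
                se_b=pooled.se_b, se_c=pooled.se_c, n_obs=pooled.n_obs)
    return fits


def herd_composition(herdbook: Herdbook) -> tuple[float, float]:
    """Herd-mean fat % and protein % over all test days."""
    frame = _testday_frame(herdbook)
    if frame.empty:
        raise InsufficientDataError(f"farm {herdbook.farm_id}: no test days")
    return float(frame["fat_pct"].mean()), float(frame["protein_pct"].mean())


def cow_effect(cow_testdays, curves: dict[int, WoodFit]) -> float:
    """Multiplicative cow effect: mean ratio of the cow's test-day yields to
    the herd curve at the same (parity class, month in milk).

    ``cow_testdays`` is an iterable of (parity_class, month_in_milk, milk_kg)
    triples.  Returns 1.0 when no usable test day exists.
    """
    ratios = []
    for cls, mim, milk in cow_testdays:
        if milk <= 0 or mim < 1:
            continue
        expected = float(wood_yield(curves[parity_class(cls)].curve, mim))
        if expected > 0:
            ratios.append(milk / expected)
    return float(np.mean(ratios)) if ratios else 1.0


def cow_effects(herdbook: Herdbook, curves: dict[int, WoodFit]) -> dict[str, float]:
    """Cow effects for every cow in the herd with test-day data."""
    frame = _testday_frame(herdbook)
    out: dict[str, float] = {}
    for cow_id, sub in frame.groupby("cow_id"):
        out[str(cow_id)] = cow_effect(
            sub[["parity_class", "mim", "milk_kg"]].itertuples(index=False),
            curves)
    return out
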