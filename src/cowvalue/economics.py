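"""Monthly contribution margin (MCM) of a dairy cow.

The MCM of one cow-month is revenue minus variable cost::

    MCM_t = (milk + calf + cull income) - (feed + vet + insemination + replacement)

Milk income is component-priced (linear fat/protein surcharges around
reference contents).  Feed cost follows a piecewise-linear net-energy
model: a maintenance requirement per kg metabolic weight, a production
requirement per kg energy-corrected milk (ECM), and a late-gestation
surcharge; the requirement is covered by roughage up to a maximum dry-matter
intake and by concentrate beyond it.  Veterinary cost is a flat monthly
average; insemination is charged to open cows from the third month in milk;
the replacement heifer's acquisition cost is charged to the replacement
stream's first month, and a culled cow's terminal month is credited carcass
(or live-sale) income.

All functions accept scalars or numpy arrays and are exact in the sense
that ``MCMBreakdown.net`` always equals the signed component sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .states import CowState, GESTATION_MONTHS


class EconomicParams(BaseModel):
    """Farm economic parameters (CHF), with Swiss dataset averages as defaults.

    Prices are per unit stated in each field name; feed-model constants are
    net-energy-lactation (NEL) values in MJ.
    """

    milk_price: float = Field(default=0.797, ge=0, description="CHF/kg milk")
    vet_cost_yearly: float = Field(default=977.20, ge=0, description="CHF/cow/year")
    insemination_cost: float = Field(default=66.80, ge=0, description="CHF/service")
    heifer_cost: float = Field(default=3123.33, ge=0, description="CHF per replacement heifer")
    roughage_price: float = Field(default=0.409, ge=0, description="CHF/kg DM")
    concentrate_price: float = Field(default=0.88, ge=0, description="CHF/kg DM")
    slaughter_price: float = Field(default=3.69, ge=0, description="CHF/kg carcass")
    calf_price: float = Field(default=7.33, ge=0, description="CHF/kg live weight")
    live_weight: float = Field(default=650.0, gt=0, description="kg, mature cow")
    dressing_fraction: float = Field(default=0.54, gt=0, lt=1)
    calf_sale_weight: float = Field(default=75.0, ge=0, description="kg live weight at sale")
    live_sale_value: float = Field(default=1800.0, ge=0,
                                   description="CHF terminal income for cows sold alive")
    fat_reference: float = Field(default=4.0, gt=0, lt=10, description="% fat at base price")
    protein_reference: float = Field(default=3.3, gt=0, lt=10, description="% protein at base price")
    fat_adjust: float = Field(default=0.03, description="price fraction per % point fat")
    protein_adjust: float = Field(default=0.05, description="price fraction per % point protein")
    # feed model constants
    maintenance_mj_per_kg_mw_day: float = Field(default=0.293, ge=0,
                                                description="MJ NEL per kg LW^0.75 per day")
    mj_per_kg_ecm: float = Field(default=3.14, ge=0, description="MJ NEL per kg ECM")
    gestation_surcharge_mj_day: tuple[float, float, float] = Field(
        default=(13.0, 18.0, 26.0),
        description="extra MJ NEL/day in pregnancy months 7, 8, 9")
    max_roughage_dm_day: float = Field(default=16.0, gt=0, description="kg DM/day")
    roughage_mj_per_kg: float = Field(default=5.5, gt=0, description="MJ NEL per kg DM")
    concentrate_mj_per_kg: float = Field(default=7.0, gt=0, description="MJ NEL per kg DM")
    days_per_month: float = Field(default=30.4375, gt=0)
    dry_months: int = Field(default=2, ge=0,
                            description="dry (zero-milk) months before an expected calving")

    @model_validator(mode="after")
    def _check_surcharge(self):
        if any(v < 0 for v in self.gestation_surcharge_mj_day):
            raise ValueError("gestation surcharges must be >= 0")
        return self


#: ECM coefficients: ECM = milk * (a*fat% + b*protein% + c) / mj_per_kg_ecm
ECM_FAT_COEF = 0.383
ECM_PROTEIN_COEF = 0.242
ECM_OFFSET = 0.7832


@dataclass(frozen=True)
class MCMBreakdown:
    """One cow-month's revenue and cost components and their net (CHF)."""

    milk_income: float
    calf_income: float
    cull_income: float
    feed_cost: float
    vet_cost: float
    insemination_cost: float
    replacement_cost: float

    @property
    def net(self) -> float:
        return ((self.milk_income + self.calf_income + self.cull_income)
                - (self.feed_cost + self.vet_cost + self.insemination_cost
                   + self.replacement_cost))


def ecm(yield_kg, fat_pct, protein_pct, params: EconomicParams | None = None):
    """Energy-corrected milk (kg) for a given yield and composition."""
    p = params or EconomicParams()
    return yield_kg * (ECM_FAT_COEF * fat_pct + ECM_PROTEIN_COEF * protein_pct
                       + ECM_OFFSET) / p.mj_per_kg_ecm


def milk_income(yield_kg, fat_pct, protein_pct, params: EconomicParams):
    """Milk revenue: yield x price x composition adjustment (floored at 0)."""
    adjust = (1.0
              + params.fat_adjust * (fat_pct - params.fat_reference)
              + params.protein_adjust * (protein_pct - params.protein_reference))
    return yield_kg * params.milk_price * np.maximum(adjust, 0.0)


def _gestation_surcharge(pregnancy_month, params: EconomicParams):
    pm = np.asarray(pregnancy_month)
    surcharge = np.zeros(pm.shape, dtype=float)
    for offset, mj in enumerate(params.gestation_surcharge_mj_day):
        surcharge = np.where(pm == GESTATION_MONTHS - 2 + offset, mj, surcharge)
    return surcharge


def feed_energy_mj(yield_kg, fat_pct, protein_pct, live_weight, pregnancy_month,
                   params: EconomicParams):
    """Monthly NEL requirement (MJ): maintenance + production + gestation."""
    maint_day = params.maintenance_mj_per_kg_mw_day * live_weight ** 0.75
    prod_month = params.mj_per_kg_ecm * ecm(yield_kg, fat_pct, protein_pct, params)
    surcharge_day = _gestation_surcharge(pregnancy_month, params)
    return (maint_day + surcharge_day) * params.days_per_month + prod_month


def feed_cost(yield_kg, fat_pct, protein_pct, live_weight, pregnancy_month,
              params: EconomicParams):
    """Monthly feed cost (CHF): roughage-first ration, concentrate on top.

    The energy requirement is met by roughage up to ``max_roughage_dm_day``;
    any remainder is met by concentrate, so within the concentrate regime
    the marginal cost of yield is the concentrate cost of the added ECM
    energy (piecewise-linear in yield).
    """
    energy = feed_energy_mj(yield_kg, fat_pct, protein_pct, live_weight,
                            pregnancy_month, params)
    energy_day = energy / params.days_per_month
    roughage_day = np.minimum(params.max_roughage_dm_day,
                              energy_day / params.roughage_mj_per_kg)
    concentrate_day = np.maximum(
        0.0, energy_day - roughage_day * params.roughage_mj_per_kg
    ) / params.concentrate_mj_per_kg
    cost_day = (roughage_day * params.roughage_price
                + concentrate_day * params.concentrate_price)
    return cost_day * params.days_per_month


def is_dry(state: CowState, params: EconomicParams) -> bool:
    """Dry period: no milk in the ``dry_months`` months before expected calving."""
    return state.month_in_pregnancy > GESTATION_MONTHS - params.dry_months


def insemination_due(state: CowState) -> bool:
    """Insemination cost is charged to open cows from month in milk 3."""
    return state.open and state.month_in_milk >= 3


def monthly_mcm(state: CowState, yield_kg: float, fat_pct: float,
                protein_pct: float, params: EconomicParams, *,
                is_calving_month: bool = False, is_cull_month: bool = False,
                cull_is_carcass: bool = True,
                charge_heifer: bool = False) -> MCMBreakdown:
    """Full MCM breakdown for one cow-month.

    Parameters
    ----------
    state : CowState
        The cow's state in this month.
    yield_kg : float
        Expected milk yield (kg/month) before the dry-period rule; set to 0
        automatically when the state is dry.
    is_calving_month, is_cull_month, cull_is_carcass, charge_heifer :
        Event flags: calf income in calving months, terminal cull income
        (carcass or live sale) in the culling month, and the heifer
        acquisition cost in a replacement stream's first month.
    """
    if state.month_in_milk < 1 or state.parity < 1:
        raise ValueError(f"invalid state {state}")
    y = 0.0 if is_dry(state, params) else float(yield_kg)
    mi = float(milk_income(y, fat_pct, protein_pct, params))
    fc = float(feed_cost(y, fat_pct, protein_pct, params.live_weight,
                         state.month_in_pregnancy, params))
    vet = params.vet_cost_yearly / 12.0
    insem = params.insemination_cost if insemination_due(state) else 0.0
    calf = params.calf_sale_weight * params.calf_price if is_calving_month else 0.0
    cull = 0.0
    if is_cull_month:
        cull = (params.live_weight * params.dressing_fraction * params.slaughter_price
                if cull_is_carcass else params.live_sale_value)
    repl = params.heifer_cost if charge_heifer else 0.0
    return MCMBreakdown(milk_income=mi, calf_income=calf, cull_income=cull,
                        feed_cost=fc, vet_cost=vet, insemination_cost=insem,
                        replacement_cost=repl)


def carcass_income(params: EconomicParams) -> float:
    return params.live_weight * params.dressing_fraction * params.slaughter_price
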