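"""Shared fixtures: default model objects and synthetic study data.

Heavy objects (synthetic farms, engines) are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import pandas as pd
import pytest

from cowvalue import (CowRecord, CowValueEngine, CullingEvent,
                      EconomicParams, Herdbook, TestDay, generate_farm)
from cowvalue.lactation import LactationCurve, WoodFit
from cowvalue.synthetic import GroundTruth


def wood_fits_from_params(params) -> dict[int, WoodFit]:
    """Exact WoodFit objects (zero uncertainty) from (a, b, c) rows."""
    return {cls: WoodFit(curve=LactationCurve(*params[cls - 1], parity_class=cls),
                         resid_sd=0.0, se_log_a=0.0, se_b=0.0, se_c=0.0, n_obs=0)
            for cls in (1, 2, 3)}


@pytest.fixture(scope="session")
def default_truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture(scope="session")
def space(default_truth):
    return default_truth.space()


@pytest.fixture(scope="session")
def truth_model(default_truth, space):
    return default_truth.transition_model(space)


@pytest.fixture(scope="session")
def truth_curves(default_truth):
    return wood_fits_from_params(default_truth.wood_params)


@pytest.fixture(scope="session")
def econ() -> EconomicParams:
    return EconomicParams()


@pytest.fixture(scope="session")
def default_engine(truth_model, econ, truth_curves, default_truth):
    """Engine on the exact default-truth kernel and curves."""
    return CowValueEngine(truth_model, econ, truth_curves,
                          default_truth.fat_mean, default_truth.protein_mean)


@pytest.fixture(scope="session")
def study_farms(default_truth):
    """Two 120-cow farms over 5 years (~14,000 cow-months) simulated from
    the shared default ground truth."""
    truth = GroundTruth(herd_size=120)
    farms = [generate_farm(truth, n_months=60, seed=s, farm_id=f"farm-{s:02d}")
             for s in (1, 2)]
    return truth, farms


@pytest.fixture(scope="session")
def small_farm():
    """One 60-cow farm over 4 years, for cheaper unit tests."""
    truth = GroundTruth(herd_size=60)
    return truth, generate_farm(truth, n_months=48, seed=11, farm_id="farm-s")


def make_toy_herdbook() -> Herdbook:
    """Three hand-written cows (two culled) spanning 2018-01 .. 2020-12."""
    period = (pd.Period("2018-01"), pd.Period("2020-12"))

    def td(month, milk):
        return TestDay(month=pd.Period(month), milk_kg=milk, fat_pct=4.0,
                       protein_pct=3.3)

    cow1 = CowRecord(
        cow_id="A1", breed="BV",
        calvings=[pd.Period("2018-02"), pd.Period("2019-01")],
        testdays=[td("2018-03", 620.0), td("2018-04", 640.0),
                  td("2019-02", 700.0), td("2019-03", 710.0)],
        inseminations=[pd.Period("2018-04"), pd.Period("2019-03")],
        culling=CullingEvent(month=pd.Period("2019-08"), reason="fertility"),
    )
    cow2 = CowRecord(
        cow_id="A2", breed="HO",
        calvings=[pd.Period("2018-05")],
        testdays=[td("2018-06", 580.0), td("2018-07", 600.0),
                  td("2018-08", 590.0), td("2018-09", 560.0)],
        inseminations=[pd.Period("2018-07")],
        culling=CullingEvent(month=pd.Period("2018-11"), reason="udder_health"),
    )
    cow3 = CowRecord(
        cow_id="A3", breed="BV",
        calvings=[pd.Period("2019-03"), pd.Period("2020-02")],
        testdays=[td("2019-04", 660.0), td("2019-05", 655.0),
                  td("2020-03", 680.0)],
        inseminations=[pd.Period("2019-05")],
        culling=None,
    )
    hb = Herdbook(farm_id="toy", cows=[cow1, cow2, cow3], period=period)
    hb.validate()
    return hb


@pytest.fixture()
def toy_herdbook() -> Herdbook:
    return make_toy_herdbook()
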