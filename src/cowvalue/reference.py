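"""Bundled reference tables from a five-year field audit of 29 Swiss
dairy herds.

Three small tables ship with the package and serve as in-package inputs
for the audit-arithmetic operations:

* ``farm_summary`` — per-farm cumulative losses from suboptimal decisions,
  cow counts and replacement rates (values as published, including one
  farm whose "replaced" entry is positive);
* ``culling_reasons_by_parity`` — counts of all 553 culling events by
  removal reason and parity;
* ``scenario_cow_values`` — cow values (CHF) on a parity-1 state grid
  under baseline, 10%-lower-yield and 800-CHF-health-event scenarios.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("cowvalue.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_farm_summary() -> pd.DataFrame:
    """Per-farm audit summary (29 farms): losses, cow counts, rates."""
    frame = _read("farm_summary.csv")
    frame["farm_id"] = frame["farm_id"].astype(str)
    return frame


def load_culling_reasons() -> pd.DataFrame:
    """Reason x parity culling counts, indexed by reason code."""
    return _read("culling_reasons_by_parity.csv").set_index("reason")


def culling_events_from_grid(grid: pd.DataFrame | None = None
                             ) -> list[tuple[str, int]]:
    """Expand a reason x parity count grid into (reason, parity) events."""
    grid = load_culling_reasons() if grid is None else grid
    events: list[tuple[str, int]] = []
    for reason, row in grid.iterrows():
        for col, n in row.items():
            parity = int(str(col).lstrip("p"))
            events.extend([(str(reason), parity)] * int(n))
    return events


def load_scenario_grid() -> pd.DataFrame:
    """Reference cow values on the parity-1 scenario grid (CHF)."""
    return _read("scenario_cow_values.csv")
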