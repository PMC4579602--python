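"""Socio-economic cost surface for reserve selection.

The cost of including a planning unit proxies the conflict a new no-take
area would create: foregone artisanal fishing profit where coral reef is
present, and the number of prospective local users (population density)
where mangrove is present.  Each component is min–max rescaled to [0, 1]
over the cells where its habitat occurs and the two are added, plus a small
uniform baseline so habitat-free cells are never free to select.  Only the
ordering matters downstream — all else being equal, expensive places are
avoided — so any strictly monotone combination would serve; the additive one
is the documented default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

BASELINE_COST = 0.01


def _rescale(values: np.ndarray, mask: np.ndarray, label: str) -> np.ndarray:
    """Min–max rescale over masked cells; constant components collapse to 0."""
    if not mask.any():
        return np.zeros_like(values, dtype=float)
    sub = values[mask]
    lo, hi = float(sub.min()), float(sub.max())
    if hi <= lo:
        warnings.warn(
            f"{label} is constant over its habitat cells; component rescaled to 0",
            stacklevel=3,
        )
        return np.zeros_like(values, dtype=float)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def build_cost(
    fishing_profit: pd.Series,
    population_density: pd.Series,
    habitat_amounts: pd.DataFrame,
    baseline: float = BASELINE_COST,
    reef_column: str = "coral_reef",
    mangrove_column: str = "mangrove",
) -> pd.Series:
    """Per-planning-unit cost index.

    ``cost = rescaled_profit * [reef present] + rescaled_density *
    [mangrove present] + baseline``; non-negative everywhere and equal to the
    baseline where neither habitat occurs.
    """
    index = habitat_amounts.index
    profit = fishing_profit.loc[index].to_numpy(float)
    density = population_density.loc[index].to_numpy(float)
    if (profit < 0).any() or (density < 0).any():
        raise ValueError("cost components must be non-negative")
    reef = (
        habitat_amounts[reef_column].to_numpy() > 0
        if reef_column in habitat_amounts
        else np.zeros(len(index), dtype=bool)
    )
    mangrove = (
        habitat_amounts[mangrove_column].to_numpy() > 0
        if mangrove_column in habitat_amounts
        else np.zeros(len(index), dtype=bool)
    )
    cost = (
        _rescale(profit, reef, "fishing profit") * reef
        + _rescale(density, mangrove, "population density") * mangrove
        + baseline
    )
    return pd.Series(cost, index=index, name="cost")
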