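"""Assembly of the six objective-specific reserve-selection scenarios.

Every scenario shares the base representation targets (20% of each of the
habitat classes, 10% of each bioregion) and adds its own ingredients:

==============  ==============================================================
representation  base targets only
fsa             + every fish-spawning-aggregation site (target 100%) and its
                20-km catchment (target 50%)
turtle          + nesting and foraging layers at 50% and an accumulated
                turtle-track connectivity matrix
trout           + directed larval-dispersal connectivity (long-dispersing)
cucumber        + directed larval-dispersal connectivity (short-dispersing)
climate         base targets on 2030 reef amounts degraded by modelled rates
==============  ==============================================================

Targets are expressed as fractions of each feature's total amount in the
scenario's own feature table; penalty weights (SPF) default high enough that
shortfalls dominate cost, so targets behave as constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from . import cost as cost_mod
from . import lockin as lockin_mod
from .climate import degrade_habitat
from .connectivity import ConnMatrix, accumulate_tracks, upscale_dispersal
from .seascape import REEF, Seascape

OBJECTIVES = ("representation", "fsa", "turtle", "trout", "cucumber", "climate")
CONNECTIVITY_OBJECTIVES = ("turtle", "trout", "cucumber")

HABITAT_TARGET = 0.20
BIOREGION_TARGET = 0.10
FSA_SITE_TARGET = 1.0
FSA_CATCHMENT_TARGET = 0.5
TURTLE_LAYER_TARGET = 0.5
CATCHMENT_RADIUS_KM = 20.0


class ScenarioError(ValueError):
    """Raised when a scenario's required layers are missing or degenerate."""


@dataclass
class Scenario:
    """One solvable reserve-selection problem.

    ``features`` has one row per conservation feature with columns
    ``feature_id`` (1-based int), ``name``, ``feature_class``,
    ``target_fraction``, ``total_amount``, ``target_amount``, ``spf``.
    ``amounts`` is a (n_features, n_units) sparse matrix of feature amounts
    per planning unit.  Connectivity is present exactly for the turtle and
    larval objectives.
    """

    name: str
    features: pd.DataFrame
    amounts: sparse.csr_matrix
    pu_ids: np.ndarray
    costs: np.ndarray
    locked: np.ndarray  # bool mask over units
    conn: ConnMatrix | None = None
    conn_weight: float = 0.0
    n_runs: int = 100
    seed: int = 0
    iterations: int | None = None
    init_fraction: float = 0.3

    @property
    def n_units(self) -> int:
        return self.pu_ids.size

    @property
    def n_features(self) -> int:
        return len(self.features)

    def validate(self) -> None:
        if self.amounts.shape != (self.n_features, self.n_units):
            raise ScenarioError("amounts matrix shape mismatch")
        if (self.features["target_fraction"] <= 0).any() or (
            self.features["target_fraction"] > 1
        ).any():
            raise ScenarioError("target fractions must lie in (0, 1]")
        if (self.features["total_amount"] <= 0).any():
            bad = self.features.loc[
                self.features["total_amount"] <= 0, "name"
            ].tolist()
            raise ScenarioError(f"features with zero total amount: {bad}")
        if self.conn is not None and self.name not in CONNECTIVITY_OBJECTIVES:
            raise ScenarioError(
                f"objective {self.name!r} must not carry a connectivity matrix"
            )
        if self.conn is None and self.name in ("trout", "cucumber"):
            raise ScenarioError(f"objective {self.name!r} requires connectivity")


def _feature_rows(
    entries: list[tuple[str, str, float, pd.Series]],
    n_units: int,
    spf: float | None,
    total_cost: float,
) -> tuple[pd.DataFrame, sparse.csr_matrix]:
    """Build the features table and amounts matrix from (name, class,
    target, per-unit amounts) entries; SPF defaults to
    ``10 * total_cost / n_features`` shared by all features."""
    rows, mats = [], []
    for name, fclass, target, amounts in entries:
        total = float(amounts.sum())
        if total <= 0:
            raise ScenarioError(f"feature {name!r} ({fclass}) has zero total amount")
        rows.append(
            {
                "name": name,
                "feature_class": fclass,
                "target_fraction": target,
                "total_amount": total,
                "target_amount": target * total,
            }
        )
        mats.append(sparse.csr_matrix(amounts.to_numpy()[None, :]))
    features = pd.DataFrame(rows)
    features.insert(0, "feature_id", np.arange(1, len(features) + 1))
    spf_value = spf if spf is not None else 10.0 * total_cost / len(features)
    features["spf"] = spf_value
    return features, sparse.csr_matrix(sparse.vstack(mats))


def _base_entries(scape: Seascape, habitat_amounts: pd.DataFrame | None = None):
    amounts = habitat_amounts if habitat_amounts is not None else scape.habitat_amounts
    entries = []
    for name in amounts.columns:
        entries.append((name, "habitat", HABITAT_TARGET, amounts[name]))
    cell_area = scape.config.cell_area
    bior = scape.planning_units["bioregion"]
    for b in sorted(bior.unique()):
        layer = pd.Series(
            np.where(bior.to_numpy() == b, cell_area, 0.0), index=amounts.index
        )
        entries.append((f"bioregion_{b}", "bioregion", BIOREGION_TARGET, layer))
    return entries


def _prepare(
    scape: Seascape,
    locked: set[int] | None,
    costs: pd.Series | None,
    lock_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    if locked is None:
        locked = lockin_mod.locked_union(scape.mpas, scape.habitat_amounts, lock_seed)
    if costs is None:
        pu = scape.planning_units
        costs = cost_mod.build_cost(
            pu["fishing_profit"], pu["population_density"], scape.habitat_amounts
        )
    locked_mask = scape.habitat_amounts.index.isin(sorted(locked))
    return locked_mask, costs.loc[scape.habitat_amounts.index].to_numpy(float)


def _make_scenario(
    scape: Seascape,
    name: str,
    entries,
    *,
    locked,
    costs,
    conn=None,
    conn_weight_scale: float = 0.1,
    spf: float | None = None,
    n_runs: int = 100,
    seed: int = 0,
    lock_seed: int = 0,
    **kwargs,
) -> Scenario:
    locked_mask, cost_arr = _prepare(scape, locked, costs, lock_seed)
    features, amounts = _feature_rows(
        entries, scape.n_units, spf, float(cost_arr.sum())
    )
    b = 0.0
    if conn is not None:
        mass = float(conn.matrix.sum())
        b = conn_weight_scale * float(cost_arr.sum()) / mass if mass > 0 else 0.0
    scenario = Scenario(
        name=name,
        features=features,
        amounts=amounts,
        pu_ids=scape.habitat_amounts.index.to_numpy(int),
        costs=cost_arr,
        locked=locked_mask,
        conn=conn,
        conn_weight=b,
        n_runs=n_runs,
        seed=seed,
        **kwargs,
    )
    scenario.validate()
    return scenario


def build_representation(
    scape: Seascape,
    *,
    locked: set[int] | None = None,
    costs: pd.Series | None = None,
    **kwargs,
) -> Scenario:
    """Base scenario: 20% of every habitat, 10% of every bioregion."""
    return _make_scenario(
        scape, "representation", _base_entries(scape), locked=locked, costs=costs, **kwargs
    )


def catchment_cells(
    scape: Seascape, site_pu: int, radius_km: float = CATCHMENT_RADIUS_KM
) -> np.ndarray:
    """Planning units whose centroids lie within ``radius_km`` of a site's."""
    pu = scape.planning_units
    sx, sy = pu.loc[site_pu, ["x_km", "y_km"]]
    d = np.hypot(pu["x_km"] - sx, pu["y_km"] - sy)
    return pu.index[d <= radius_km + 1e-9].to_numpy(int)


def build_fsa(
    scape: Seascape,
    *,
    locked: set[int] | None = None,
    costs: pd.Series | None = None,
    catchment_radius_km: float = CATCHMENT_RADIUS_KM,
    **kwargs,
) -> Scenario:
    """Representation plus 100% of FSA sites and 50% of their catchments."""
    entries = _base_entries(scape)
    index = scape.habitat_amounts.index
    cell_area = scape.config.cell_area
    for _, site in scape.fsa_sites.iterrows():
        pu_id = int(site["pu_id"])
        if pu_id not in index:
            raise ScenarioError(f"FSA site {site['site_id']} is off-grid")
        point = pd.Series(np.where(index == pu_id, 1.0, 0.0), index=index)
        entries.append((f"{site['site_id']}_site", "fsa_site", FSA_SITE_TARGET, point))
        members = catchment_cells(scape, pu_id, catchment_radius_km)
        layer = pd.Series(
            np.where(index.isin(members), cell_area, 0.0), index=index
        )
        entries.append(
            (f"{site['site_id']}_catchment", "fsa_catchment", FSA_CATCHMENT_TARGET, layer)
        )
    return _make_scenario(scape, "fsa", entries, locked=locked, costs=costs, **kwargs)


def build_turtle(
    scape: Seascape,
    *,
    locked: set[int] | None = None,
    costs: pd.Series | None = None,
    **kwargs,
) -> Scenario:
    """Representation plus 50% nesting/foraging layers and track connectivity.

    Nesting and foraging amounts are the per-cell counts of track start and
    end points.  With no usable tracks the connectivity term is dropped with
    a warning and the scenario degenerates to representation structure.
    """
    entries = _base_entries(scape)
    index = scape.habitat_amounts.index
    w = scape.config.grid_width
    nest = np.zeros(index.size)
    forage = np.zeros(index.size)
    for track in scape.turtle_tracks:
        first = track.path[0][0] * w + track.path[0][1]
        last = track.path[-1][0] * w + track.path[-1][1]
        nest[first] += 1.0
        forage[last] += 1.0
    conn = None
    if scape.turtle_tracks:
        entries.append(
            (
                "turtle_nesting",
                "turtle_nesting",
                TURTLE_LAYER_TARGET,
                pd.Series(nest, index=index),
            )
        )
        entries.append(
            (
                "turtle_foraging",
                "turtle_foraging",
                TURTLE_LAYER_TARGET,
                pd.Series(forage, index=index),
            )
        )
        conn = accumulate_tracks(scape.turtle_tracks, scape.grid_shape)
    else:
        warnings.warn(
            "no turtle tracks: connectivity term absent from turtle scenario",
            stacklevel=2,
        )
    return _make_scenario(
        scape, "turtle", entries, locked=locked, costs=costs, conn=conn, **kwargs
    )


def build_larval(
    scape: Seascape,
    species: str,
    *,
    locked: set[int] | None = None,
    costs: pd.Series | None = None,
    **kwargs,
) -> Scenario:
    """Representation features plus directed larval-dispersal connectivity."""
    if species not in ("trout", "cucumber"):
        raise ScenarioError(f"unknown larval species {species!r}")
    membership = scape.planning_units["reef_complex"].to_numpy()
    conn = upscale_dispersal(
        scape.dispersal[species], membership, scape.habitat_amounts[REEF].to_numpy()
    )
    return _make_scenario(
        scape,
        species,
        _base_entries(scape),
        locked=locked,
        costs=costs,
        conn=conn,
        **kwargs,
    )


def build_climate(
    scape: Seascape,
    degradation: pd.Series,
    *,
    locked: set[int] | None = None,
    costs: pd.Series | None = None,
    **kwargs,
) -> Scenario:
    """Representation targets applied to climate-degraded 2030 reef amounts."""
    if degradation is None:
        raise ScenarioError("climate scenario requires degradation rates")
    degraded = degrade_habitat(scape.habitat_amounts, degradation, REEF)
    return _make_scenario(
        scape,
        "climate",
        _base_entries(scape, habitat_amounts=degraded),
        locked=locked,
        costs=costs,
        **kwargs,
    )


def build_scenario(
    scape: Seascape,
    objective: str,
    degradation: pd.Series | None = None,
    **kwargs,
) -> Scenario:
    """Dispatch one Table-style objective name to its builder."""
    if objective == "representation":
        return build_representation(scape, **kwargs)
    if objective == "fsa":
        return build_fsa(scape, **kwargs)
    if objective == "turtle":
        return build_turtle(scape, **kwargs)
    if objective in ("trout", "cucumber"):
        return build_larval(scape, objective, **kwargs)
    if objective == "climate":
        if degradation is None:
            raise ScenarioError("climate scenario requires degradation rates")
        return build_climate(scape, degradation, **kwargs)
    raise ScenarioError(f"unknown objective {objective!r}")
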