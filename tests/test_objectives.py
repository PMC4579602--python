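"""Scenario assembly: targets, feature sets, catchments and dispatch."""

import numpy as np
import pandas as pd
import pytest

from reefplan.objectives import (
    ScenarioError,
    build_climate,
    build_fsa,
    build_larval,
    build_representation,
    build_scenario,
    build_turtle,
    catchment_cells,
)
from reefplan.prioritizer import objective_score


def test_representation_feature_counts_and_targets(small_scape):
    sc = build_representation(small_scape)
    assert sc.n_features == 5 + 4  # habitats + bioregions
    habitats = sc.features[sc.features["feature_class"] == "habitat"]
    bioregions = sc.features[sc.features["feature_class"] == "bioregion"]
    assert (habitats["target_fraction"] == 0.20).all()
    assert (bioregions["target_fraction"] == 0.10).all()
    assert sc.conn is None


def test_empty_habitat_class_is_named_error(small_scape):
    import copy

    broken = copy.copy(small_scape)
    broken.habitat_amounts = small_scape.habitat_amounts.copy()
    broken.habitat_amounts["seagrass"] = 0.0
    with pytest.raises(ScenarioError, match="seagrass"):
        build_representation(broken, locked=set())


def test_fsa_targets(small_scape):
    sc = build_fsa(small_scape)
    sites = sc.features[sc.features["feature_class"] == "fsa_site"]
    catchments = sc.features[sc.features["feature_class"] == "fsa_catchment"]
    assert len(sites) == len(small_scape.fsa_sites)
    assert (sites["target_fraction"] == 1.0).all()
    assert (catchments["target_fraction"] == 0.5).all()


def test_catchment_is_twenty_km_centroid_disc(small_scape):
    """On a 10-km grid the 20-km catchment is the cells within 2 cell widths."""
    site = int(small_scape.fsa_sites["pu_id"].iloc[0])
    members = set(catchment_cells(small_scape, site, 20.0))
    pu = small_scape.planning_units
    r0, c0 = pu.loc[site, "row"], pu.loc[site, "col"]
    expected = {
        int(p)
        for p, r, c in zip(pu.index, pu["row"], pu["col"])
        if (r - r0) ** 2 + (c - c0) ** 2 <= 4
    }
    assert members == expected
    assert site in members


def test_fsa_without_sites_reduces_to_representation(small_scape):
    import copy

    no_sites = copy.copy(small_scape)
    no_sites.fsa_sites = small_scape.fsa_sites.iloc[0:0]
    sc = build_fsa(no_sites)
    rep = build_representation(small_scape)
    assert sc.features["name"].tolist() == rep.features["name"].tolist()


def test_turtle_layers_and_connectivity(small_scape):
    sc = build_turtle(small_scape)
    layers = sc.features[
        sc.features["feature_class"].isin(["turtle_nesting", "turtle_foraging"])
    ]
    assert len(layers) == 2
    assert (layers["target_fraction"] == 0.5).all()
    assert sc.conn is not None and not sc.conn.directed
    assert sc.conn_weight > 0
    # layer amounts count track endpoints
    nesting_total = layers[layers["feature_class"] == "turtle_nesting"][
        "total_amount"
    ].iloc[0]
    assert nesting_total == len(small_scape.turtle_tracks)


def test_turtle_zero_weight_reduces_to_cost_plus_shortfall(small_scape):
    sc = build_turtle(small_scape)
    sc.conn_weight = 0.0
    rng = np.random.default_rng(0)
    sel = rng.random(sc.n_units) < 0.4
    bd = objective_score(sel, sc)
    assert bd.connectivity == 0.0
    assert bd.total == pytest.approx(bd.cost + bd.shortfall_total)


def test_larval_scenarios_use_species_matrices(small_scape):
    trout = build_larval(small_scape, "trout")
    cuke = build_larval(small_scape, "cucumber")
    rep = build_representation(small_scape)
    assert trout.features["name"].tolist() == rep.features["name"].tolist()
    assert cuke.features["name"].tolist() == rep.features["name"].tolist()
    assert trout.conn.directed and cuke.conn.directed
    # contrasting dispersal: the long-disperser exports more flow off-diagonal
    t = trout.conn.matrix.toarray()
    c = cuke.conn.matrix.toarray()
    assert 1 - np.trace(t) / t.sum() > 1 - np.trace(c) / c.sum()
    with pytest.raises(ScenarioError):
        build_larval(small_scape, "shark")


def test_climate_scenario_degrades_reef_only(small_scape):
    idx = small_scape.habitat_amounts.index
    rep = build_representation(small_scape)
    zero = build_climate(small_scape, pd.Series(0.0, index=idx))
    assert np.allclose(
        zero.amounts.toarray(), rep.amounts.toarray()
    )  # d=0 -> identical to representation


def test_climate_scenario_toy_arithmetic(small_scape):
    idx = small_scape.habitat_amounts.index
    d = pd.Series(0.0, index=idx)
    target_pu = small_scape.habitat_amounts["coral_reef"].idxmax()
    d.loc[target_pu] = 0.25
    sc = build_climate(small_scape, d)
    reef_idx = sc.features.index[sc.features["name"] == "coral_reef"][0]
    col = list(idx).index(target_pu)
    original = small_scape.habitat_amounts.loc[target_pu, "coral_reef"]
    assert sc.amounts[reef_idx, col] == pytest.approx(0.75 * original)


def test_climate_full_degradation_empties_reef_feature(small_scape):
    idx = small_scape.habitat_amounts.index
    with pytest.raises(ScenarioError, match="coral_reef"):
        build_climate(small_scape, pd.Series(1.0, index=idx))


def test_dispatch_and_missing_rates(small_scape):
    sc = build_scenario(small_scape, "representation")
    assert sc.name == "representation"
    with pytest.raises(ScenarioError):
        build_scenario(small_scape, "climate")
    with pytest.raises(ScenarioError):
        build_scenario(small_scape, "unknown")


def test_spf_default_scales_with_cost(small_scape):
    sc = build_representation(small_scape)
    expected = 10.0 * sc.costs.sum() / sc.n_features
    assert sc.features["spf"].iloc[0] == pytest.approx(expected)
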