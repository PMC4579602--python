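"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from reefplan.climate import ClimateForcing
from reefplan.objectives import Scenario
from reefplan.seascape import SeascapeConfig, generate_seascape

SMALL_CONFIG = SeascapeConfig(
    grid_width=12,
    grid_height=12,
    n_provinces=4,
    n_countries=2,
    n_habitats=5,
    n_bioregions=4,
    n_small_mpas=4,
    n_large_mpas=2,
    n_fsa_sites=4,
    n_turtle_tracks=6,
    n_reef_complexes=4,
    seed=5,
)


@pytest.fixture(scope="session")
def small_scape():
    return generate_seascape(SMALL_CONFIG)


def make_forcing(
    sst: np.ndarray,
    years: np.ndarray,
    aragonite: np.ndarray | None = None,
    ar_years: np.ndarray | None = None,
    centres: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> ClimateForcing:
    """Hand-built forcing for climate unit tests."""
    n_coarse = sst.shape[0]
    if aragonite is None:
        ar_years = years
        aragonite = np.full((n_coarse, years.size), 3.8)
    if ar_years is None:
        ar_years = years
    if centres is None:
        centres = np.column_stack(
            [np.arange(n_coarse, dtype=float), np.zeros(n_coarse)]
        )
    if valid is None:
        valid = np.ones(n_coarse, dtype=bool)
    return ClimateForcing(
        sst=sst,
        years=years,
        aragonite=aragonite,
        ar_years=ar_years,
        coarse_shape=(1, n_coarse),
        factor=1,
        centres=centres,
        valid=valid,
        cell_to_coarse=np.arange(n_coarse),
    )


def make_scenario(
    costs,
    feature_amounts,
    targets,
    spf,
    locked=None,
    conn=None,
    conn_weight=0.0,
    name="representation",
    seed=0,
    n_runs=1,
    iterations=None,
) -> Scenario:
    """Assemble a Scenario directly from arrays (bypassing the seascape)."""
    costs = np.asarray(costs, dtype=float)
    amounts = sparse.csr_matrix(np.atleast_2d(np.asarray(feature_amounts, float)))
    nf, n = amounts.shape
    totals = np.asarray(amounts.sum(axis=1)).ravel()
    targets = np.asarray(targets, dtype=float)
    features = pd.DataFrame(
        {
            "feature_id": np.arange(1, nf + 1),
            "name": [f"f{k}" for k in range(nf)],
            "feature_class": "habitat",
            "target_fraction": targets,
            "total_amount": totals,
            "target_amount": targets * totals,
            "spf": spf,
        }
    )
    locked_mask = np.zeros(n, dtype=bool)
    if locked:
        locked_mask[list(locked)] = True
    if conn is not None:
        name = "turtle"
    scenario = Scenario(
        name=name,
        features=features,
        amounts=amounts,
        pu_ids=np.arange(1, n + 1),
        costs=costs,
        locked=locked_mask,
        conn=conn,
        conn_weight=conn_weight,
        n_runs=n_runs,
        seed=seed,
        iterations=iterations,
    )
    scenario.validate()
    return scenario


def exhaustive_optimum(scenario: Scenario) -> float:
    """Brute-force optimum objective over all subsets (independent oracle)."""
    n = scenario.n_units
    assert n <= 16, "enumeration oracle limited to small instances"
    masks = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
    if scenario.locked.any():
        masks = masks[(masks[:, scenario.locked]).all(axis=1)]
    cost = masks @ scenario.costs
    amounts = np.asarray(scenario.amounts.todense())
    captured = masks @ amounts.T
    targets = scenario.features["target_amount"].to_numpy()
    spf = scenario.features["spf"].to_numpy()
    penalty = (spf * np.clip((targets - captured) / targets, 0.0, None)).sum(axis=1)
    conn_pen = np.zeros(len(masks))
    if scenario.conn is not None and scenario.conn_weight > 0:
        M = np.asarray(scenario.conn.matrix.todense())
        inflow = masks.astype(float) @ M  # sum_i s_i * CV_ij per j
        conn_pen = scenario.conn_weight * (inflow * (~masks)).sum(axis=1)
    return float((cost + penalty + conn_pen).min())


def random_instance(rng: np.random.Generator, with_conn: bool = False) -> Scenario:
    """Random small reserve-selection instance for oracle comparisons."""
    from reefplan.connectivity import ConnMatrix

    n = int(rng.integers(8, 13))
    nf = int(rng.integers(2, 5))
    costs = rng.uniform(0.2, 2.0, n)
    amounts = rng.uniform(0, 1, (nf, n)) * (rng.random((nf, n)) < 0.6)
    amounts[amounts.sum(axis=1) == 0, 0] = 1.0  # no empty features
    targets = rng.uniform(0.3, 0.6, nf)
    spf = 5.0 * costs.sum() / nf
    locked = {int(rng.integers(n))} if rng.random() < 0.3 else None
    conn = None
    weight = 0.0
    if with_conn:
        M = rng.uniform(0, 0.2, (n, n)) * (rng.random((n, n)) < 0.3)
        conn = ConnMatrix(sparse.csr_matrix(M), directed=True)
        weight = float(rng.uniform(0.1, 0.5))
    return make_scenario(
        costs, amounts, targets, spf, locked=locked, conn=conn, conn_weight=weight
    )
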