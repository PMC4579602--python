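"""Simulated-annealing reserve selection and selection frequencies.

Each scenario is solved by minimizing

``total = sum_{i in R} cost_i
        + sum_f spf_f * max(0, (T_f - A_f(R)) / T_f)
        + b * sum_{i in R, j not in R} CV_ij``

over subsets R of planning units that always contain the locked-in MPAs:
reserve cost, proportional target-shortfall penalties weighted by the
species penalty factor, and the connectivity penalty for flow leaving the
reserve set.  A run starts from the locked units plus a random 30% of the
rest, proposes single-unit flips (never of locked units) under a geometric
cooling schedule, and finishes with greedy improvement passes until no
single flip helps, so every returned solution is 1-flip locally optimal.

Repeating the anneal (100 runs by default, seeds derived as
``scenario_seed + run_index``) gives per-unit selection frequencies — the
fraction of runs in which a unit is selected — used downstream as the
conservation-priority proxy.

The inner loop is JIT-compiled with numba; amounts and connectivity are
passed as flat CSR/CSC index arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

from .connectivity import connectivity_penalty
from .objectives import Scenario

MAX_ITERATIONS = 1_000_000
ITERATIONS_PER_UNIT = 10_000


@dataclass
class ScoreBreakdown:
    """Objective decomposition; the three terms sum exactly to ``total``."""

    cost: float
    shortfall: np.ndarray  # per-feature penalty
    connectivity: float

    @property
    def shortfall_total(self) -> float:
        return float(self.shortfall.sum())

    @property
    def total(self) -> float:
        return self.cost + self.shortfall_total + self.connectivity


@dataclass
class Solution:
    """A reserve set with its objective breakdown."""

    selected: np.ndarray  # bool mask over units
    breakdown: ScoreBreakdown

    @property
    def total(self) -> float:
        return self.breakdown.total

    def selected_ids(self, pu_ids: np.ndarray) -> np.ndarray:
        return pu_ids[self.selected]


@dataclass
class RunEnsemble:
    """Solutions and selection frequencies over repeated anneals."""

    scenario_name: str
    solutions: list[Solution]
    selection_frequency: pd.Series  # indexed by pu_id, in [0, 1]
    best: Solution

    @property
    def n_runs(self) -> int:
        return len(self.solutions)


def objective_score(selected: np.ndarray, scenario: Scenario) -> ScoreBreakdown:
    """Score a candidate reserve set (reference implementation).

    ``T_f = target_fraction * total_amount`` and ``A_f(R)`` is the captured
    amount; the shortfall penalty is proportional, so an unmet feature costs
    at most its SPF.
    """
    sel = np.asarray(selected, dtype=bool)
    if sel.size != scenario.n_units:
        raise ValueError("selection mask does not match scenario size")
    cost = float(scenario.costs[sel].sum())
    captured = np.asarray(scenario.amounts @ sel.astype(float))
    targets = scenario.features["target_amount"].to_numpy(float)
    spf = scenario.features["spf"].to_numpy(float)
    shortfall = spf * np.clip((targets - captured) / targets, 0.0, None)
    conn_pen = 0.0
    if scenario.conn is not None and scenario.conn_weight > 0:
        conn_pen = connectivity_penalty(sel, scenario.conn, scenario.conn_weight)
    return ScoreBreakdown(cost=cost, shortfall=shortfall, connectivity=conn_pen)


@njit(cache=True)
def _flip_delta(
    u, sel, captured, costs,
    amt_indptr, amt_feat, amt_val,
    targets, spf,
    out_indptr, out_idx, out_val,
    in_indptr, in_idx, in_val,
    b,
):
    adding = not sel[u]
    delta = costs[u] if adding else -costs[u]
    for k in range(amt_indptr[u], amt_indptr[u + 1]):
        f = amt_feat[k]
        a = amt_val[k]
        old = captured[f]
        new = old + a if adding else old - a
        t = targets[f]
        old_pen = spf[f] * max(0.0, (t - old) / t)
        new_pen = spf[f] * max(0.0, (t - new) / t)
        delta += new_pen - old_pen
    if b > 0.0:
        s = 0.0
        for k in range(out_indptr[u], out_indptr[u + 1]):
            j = out_idx[k]
            if j != u and not sel[j]:
                s += out_val[k]
        for k in range(in_indptr[u], in_indptr[u + 1]):
            i = in_idx[k]
            if i != u and sel[i]:
                s -= in_val[k]
        delta += b * s if adding else -b * s
    return delta


@njit(cache=True)
def _apply_flip(u, sel, captured, amt_indptr, amt_feat, amt_val):
    adding = not sel[u]
    for k in range(amt_indptr[u], amt_indptr[u + 1]):
        f = amt_feat[k]
        if adding:
            captured[f] += amt_val[k]
        else:
            captured[f] -= amt_val[k]
    sel[u] = not sel[u]


@njit(cache=True)
def _anneal_kernel(
    costs, locked,
    amt_indptr, amt_feat, amt_val,
    targets, spf,
    out_indptr, out_idx, out_val,
    in_indptr, in_idx, in_val,
    b, n_iter, init_fraction, seed,
):
    n = costs.size
    nf = targets.size
    np.random.seed(seed)
    sel = np.zeros(n, dtype=np.bool_)
    avail = np.empty(n, dtype=np.int64)
    n_avail = 0
    for u in range(n):
        if locked[u]:
            sel[u] = True
        else:
            avail[n_avail] = u
            n_avail += 1
            if np.random.random() < init_fraction:
                sel[u] = True
    captured = np.zeros(nf)
    for u in range(n):
        if sel[u]:
            for k in range(amt_indptr[u], amt_indptr[u + 1]):
                captured[amt_feat[k]] += amt_val[k]
    if n_avail == 0:
        return sel

    # calibrate the schedule from sampled uphill move sizes:
    # start at ~80% uphill acceptance, end below 0.1%
    pos_sum = 0.0
    pos_cnt = 0
    for _ in range(256):
        u = avail[np.random.randint(n_avail)]
        d = _flip_delta(
            u, sel, captured, costs, amt_indptr, amt_feat, amt_val,
            targets, spf, out_indptr, out_idx, out_val,
            in_indptr, in_idx, in_val, b,
        )
        if d > 0.0:
            pos_sum += d
            pos_cnt += 1
    mean_up = pos_sum / pos_cnt if pos_cnt > 0 else 1.0
    t0 = mean_up / 0.2231435513  # -ln(0.8)
    tf = mean_up / 6.9077552790  # -ln(0.001)
    cool = (tf / t0) ** (1.0 / max(n_iter, 1))

    temp = t0
    for _ in range(n_iter):
        u = avail[np.random.randint(n_avail)]
        d = _flip_delta(
            u, sel, captured, costs, amt_indptr, amt_feat, amt_val,
            targets, spf, out_indptr, out_idx, out_val,
            in_indptr, in_idx, in_val, b,
        )
        if d <= 0.0 or np.random.random() < np.exp(-d / temp):
            _apply_flip(u, sel, captured, amt_indptr, amt_feat, amt_val)
        temp *= cool

    improved = True
    while improved:  # greedy polish: 1-flip local optimality
        improved = False
        for k in range(n_avail):
            u = avail[k]
            d = _flip_delta(
                u, sel, captured, costs, amt_indptr, amt_feat, amt_val,
                targets, spf, out_indptr, out_idx, out_val,
                in_indptr, in_idx, in_val, b,
            )
            if d < -1e-12:
                _apply_flip(u, sel, captured, amt_indptr, amt_feat, amt_val)
                improved = True
    return sel


def _scenario_arrays(scenario: Scenario) -> dict:
    cached = getattr(scenario, "_kernel_arrays", None)
    if cached is not None:
        return cached
    csc = sparse.csc_matrix(scenario.amounts)
    empty_i = np.zeros(scenario.n_units + 1, dtype=np.int64)
    empty_v = np.zeros(0)
    empty_x = np.zeros(0, dtype=np.int64)
    arrays = {
        "costs": scenario.costs.astype(float),
        "locked": scenario.locked.astype(bool),
        "amt_indptr": csc.indptr.astype(np.int64),
        "amt_feat": csc.indices.astype(np.int64),
        "amt_val": csc.data.astype(float),
        "targets": scenario.features["target_amount"].to_numpy(float),
        "spf": scenario.features["spf"].to_numpy(float),
        "out_indptr": empty_i,
        "out_idx": empty_x,
        "out_val": empty_v,
        "in_indptr": empty_i,
        "in_idx": empty_x,
        "in_val": empty_v,
        "b": 0.0,
    }
    if scenario.conn is not None and scenario.conn_weight > 0:
        csr = scenario.conn.matrix
        ccsc = scenario.conn.csc
        arrays.update(
            out_indptr=csr.indptr.astype(np.int64),
            out_idx=csr.indices.astype(np.int64),
            out_val=csr.data.astype(float),
            in_indptr=ccsc.indptr.astype(np.int64),
            in_idx=ccsc.indices.astype(np.int64),
            in_val=ccsc.data.astype(float),
            b=float(scenario.conn_weight),
        )
    scenario._kernel_arrays = arrays
    return arrays


def default_iterations(n_units: int) -> int:
    return min(ITERATIONS_PER_UNIT * n_units, MAX_ITERATIONS)


def anneal(scenario: Scenario, seed: int) -> Solution:
    """One simulated-annealing run; deterministic in (scenario, seed)."""
    a = _scenario_arrays(scenario)
    n_iter = (
        scenario.iterations
        if scenario.iterations is not None
        else default_iterations(scenario.n_units)
    )
    sel = _anneal_kernel(
        a["costs"], a["locked"],
        a["amt_indptr"], a["amt_feat"], a["amt_val"],
        a["targets"], a["spf"],
        a["out_indptr"], a["out_idx"], a["out_val"],
        a["in_indptr"], a["in_idx"], a["in_val"],
        a["b"], int(n_iter), float(scenario.init_fraction),
        int(seed) % (2**32),
    )
    sel = np.asarray(sel, dtype=bool)
    return Solution(selected=sel, breakdown=objective_score(sel, scenario))


def run_scenario(scenario: Scenario) -> RunEnsemble:
    """Ensemble of independent anneals with derived per-run seeds."""
    if scenario.n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    solutions = [
        anneal(scenario, (scenario.seed + run) % (2**31))
        for run in range(scenario.n_runs)
    ]
    counts = np.sum([s.selected for s in solutions], axis=0)
    freq = pd.Series(
        counts / scenario.n_runs, index=scenario.pu_ids, name="selection_frequency"
    )
    best = min(solutions, key=lambda s: s.total)
    return RunEnsemble(
        scenario_name=scenario.name,
        solutions=solutions,
        selection_frequency=freq,
        best=best,
    )


def captured_fractions(solution: Solution, scenario: Scenario) -> pd.Series:
    """Fraction of each feature's total amount captured by a solution."""
    captured = np.asarray(scenario.amounts @ solution.selected.astype(float))
    totals = scenario.features["total_amount"].to_numpy(float)
    return pd.Series(
        captured / totals, index=scenario.features["name"], name="captured_fraction"
    )
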