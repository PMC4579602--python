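"""Province-level conservation benefits, hotspots and complementarity.

The conservation benefit of a province for one objective is the proportion
of its eligible planning units selected in at least half of the annealing
runs.  Provinces at or above the upper-quartile benefit for *every*
objective are multi-objective hotspots; provinces at or above the 90th
percentile for a single objective are that objective's top-decile
(complementary) priorities.  Complementarity structure is summarized by
average-linkage hierarchical clustering of provinces on Euclidean distances
between their benefit profiles, each objective column first scaled by its
maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .prioritizer import RunEnsemble

BENEFIT_THRESHOLD = 0.5  # "selected at least half the time"
HOTSPOT_PERCENTILE = 75.0
TOP_DECILE_PERCENTILE = 90.0


@dataclass
class HotspotResult:
    """Per-province count of objectives at/above the upper-quartile benefit."""

    counts: pd.Series  # objectives at/above threshold, 0..n_objectives
    hotspot: pd.Series  # bool, count == n_objectives
    thresholds: pd.Series  # per-objective 75th percentile


@dataclass
class ComplementarityResult:
    """Top-decile sets, pairwise dissimilarities and the dendrogram."""

    top_decile: dict[str, set]
    distances: pd.DataFrame  # square symmetric, zero diagonal
    linkage_matrix: np.ndarray
    labels: pd.Series  # cluster label per province
    cluster_objectives: dict[int, set]  # objectives with a top-decile member
    newick: str


def eligible_units(scenario) -> np.ndarray:
    """Mask of planning units carrying at least one conservation feature."""
    return np.asarray(scenario.amounts.sum(axis=0)).ravel() > 0


def province_benefit(
    ensemble: RunEnsemble,
    provinces: pd.Series,
    eligible: np.ndarray | None = None,
    threshold: float = BENEFIT_THRESHOLD,
) -> pd.Series:
    """Per-province benefit for one objective.

    ``benefit_p = |{i in p eligible: freq_i >= threshold}| / |{i in p
    eligible}|``.  Provinces without eligible units are dropped with a
    warning.

    Parameters
    ----------
    ensemble : RunEnsemble
        Output of :func:`reefplan.prioritizer.run_scenario`.
    provinces : Series
        Province label per planning unit, indexed by pu_id.
    eligible : bool array, optional
        Eligibility mask aligned with the ensemble's planning units;
        defaults to all units.
    """
    freq = ensemble.selection_frequency
    if eligible is None:
        eligible = np.ones(freq.size, dtype=bool)
    prov = provinces.loc[freq.index].to_numpy()
    hit = (freq.to_numpy() >= threshold) & eligible
    out = {}
    for p in np.unique(prov):
        mask = (prov == p) & eligible
        n_elig = int(mask.sum())
        if n_elig == 0:
            warnings.warn(
                f"province {p} has no eligible planning units; excluded",
                stacklevel=2,
            )
            continue
        out[p] = float((hit & (prov == p)).sum()) / n_elig
    return pd.Series(out, name=ensemble.scenario_name)


def benefit_table(
    ensembles: dict[str, RunEnsemble],
    provinces: pd.Series,
    eligible: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Province x objective benefit matrix."""
    cols = {}
    for name, ens in ensembles.items():
        elig = eligible.get(name) if eligible else None
        cols[name] = province_benefit(ens, provinces, elig)
    return pd.DataFrame(cols)


def find_hotspots(
    benefits: pd.DataFrame, percentile: float = HOTSPOT_PERCENTILE
) -> HotspotResult:
    """Provinces at/above the per-objective upper-quartile benefit.

    Thresholds use the linear-interpolation percentile; comparisons are
    inclusive, so degenerate ties (all provinces equal) make every province
    a hotspot.
    """
    if len(benefits) < 4:
        raise ValueError("quartile thresholds need at least 4 provinces")
    thresholds = benefits.apply(
        lambda col: float(np.percentile(col, percentile, method="linear"))
    )
    above = benefits.ge(thresholds, axis=1)
    counts = above.sum(axis=1)
    return HotspotResult(
        counts=counts,
        hotspot=counts == benefits.shape[1],
        thresholds=thresholds,
    )


def top_decile(
    benefits: pd.DataFrame,
    objective: str,
    percentile: float = TOP_DECILE_PERCENTILE,
) -> set:
    """Provinces at/above the 90th-percentile benefit for one objective."""
    col = benefits[objective]
    thr = float(np.percentile(col, percentile, method="linear"))
    return set(col.index[col >= thr])


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = to_tree(Z)

    def recurse(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


def complementarity_cluster(
    benefits: pd.DataFrame,
    n_clusters: int = 4,
    decile_percentile: float = TOP_DECILE_PERCENTILE,
) -> ComplementarityResult:
    """Cluster provinces by the similarity of their benefit profiles.

    Each objective column is scaled to [0, 1] by its maximum (a monotone
    transform that leaves per-objective ranks unchanged), provinces are
    compared by Euclidean distance, and the average-linkage dendrogram is
    cut into ``n_clusters`` groups.  Each cluster is annotated with the
    objectives for which at least one member is a top-decile province.
    """
    if len(benefits) < 2:
        raise ValueError("clustering needs at least 2 provinces")
    scaled = benefits.copy().astype(float)
    for col in scaled.columns:
        m = scaled[col].max()
        if m > 0:
            scaled[col] = scaled[col] / m
    condensed = pdist(scaled.to_numpy(), metric="euclidean")
    Z = linkage(condensed, method="average")
    k = min(n_clusters, len(benefits))
    labels = pd.Series(
        fcluster(Z, t=k, criterion="maxclust"), index=benefits.index, name="cluster"
    )
    deciles = {obj: top_decile(benefits, obj, decile_percentile) for obj in benefits}
    cluster_objectives: dict[int, set] = {}
    for cluster_id in sorted(labels.unique()):
        members = set(labels.index[labels == cluster_id])
        cluster_objectives[int(cluster_id)] = {
            obj for obj, provs in deciles.items() if members & provs
        }
    distances = pd.DataFrame(
        squareform(condensed), index=benefits.index, columns=benefits.index
    )
    newick = _linkage_to_newick(Z, [str(p) for p in benefits.index])
    return ComplementarityResult(
        top_decile=deciles,
        distances=distances,
        linkage_matrix=Z,
        labels=labels,
        cluster_objectives=cluster_objectives,
        newick=newick,
    )
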