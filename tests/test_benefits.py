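"""Province benefits, hotspot detection and complementarity clustering."""

import numpy as np
import pandas as pd
import pytest

from reefplan.benefits import (
    complementarity_cluster,
    find_hotspots,
    province_benefit,
    top_decile,
)
from reefplan.prioritizer import RunEnsemble


def fake_ensemble(freqs, name="representation"):
    freq = pd.Series(freqs, index=pd.RangeIndex(1, len(freqs) + 1, name="pu_id"))
    return RunEnsemble(
        scenario_name=name, solutions=[], selection_frequency=freq, best=None
    )


def provinces_for(freqs, label=0):
    return pd.Series(label, index=pd.RangeIndex(1, len(freqs) + 1, name="pu_id"))


def test_benefit_threshold_count_arithmetic():
    """Four eligible units with freqs (0.6, 0.5, 0.4, 0.0) -> benefit 0.5."""
    freqs = [0.6, 0.5, 0.4, 0.0]
    out = province_benefit(fake_ensemble(freqs), provinces_for(freqs))
    assert out.loc[0] == pytest.approx(0.5)  # >= is inclusive at 0.5


@pytest.mark.parametrize("value, expected", [(1.0, 1.0), (0.0, 0.0)])
def test_benefit_degenerate_frequencies(value, expected):
    freqs = [value] * 6
    prov = pd.Series(
        [0, 0, 0, 1, 1, 1], index=pd.RangeIndex(1, 7, name="pu_id")
    )
    out = province_benefit(fake_ensemble(freqs), prov)
    assert (out == expected).all()


def test_benefit_eligibility_mask_shrinks_denominator():
    freqs = [1.0, 1.0, 0.0, 0.0]
    eligible = np.array([True, True, True, False])
    out = province_benefit(fake_ensemble(freqs), provinces_for(freqs), eligible)
    assert out.loc[0] == pytest.approx(2 / 3)


def test_benefit_warns_on_empty_province():
    freqs = [1.0, 1.0]
    prov = pd.Series([0, 1], index=pd.RangeIndex(1, 3, name="pu_id"))
    eligible = np.array([True, False])
    with pytest.warns(UserWarning, match="no eligible"):
        out = province_benefit(fake_ensemble(freqs), prov, eligible)
    assert list(out.index) == [0]


# ---------------------------------------------------------------- hotspots


def test_all_identical_provinces_are_all_hotspots():
    table = pd.DataFrame(0.4, index=range(6), columns=list("abcdef"))
    result = find_hotspots(table)
    assert result.hotspot.all()
    assert (result.counts == 6).all()


def test_hotspots_match_independent_percentile_arithmetic():
    values = 0.1 * np.arange(8)
    table = pd.DataFrame({c: values for c in "abcdef"}, index=range(8))
    result = find_hotspots(table)
    thr = np.percentile(values, 75)  # independent threshold
    expected = values >= thr
    assert list(result.hotspot) == list(expected)
    assert int(result.hotspot.sum()) == 2


def test_single_nonzero_column_restricts_hotspots():
    rng = np.random.default_rng(13)
    table = pd.DataFrame(
        rng.uniform(0.5, 1.0, (6, 5)), index=range(6), columns=list("abcde")
    )
    table["f"] = 0.0
    table.loc[2, "f"] = 0.9
    result = find_hotspots(table)
    assert result.hotspot.sum() <= 1
    assert not result.hotspot.drop(2).any()


def test_hotspots_against_bruteforce_oracle():
    rng = np.random.default_rng(14)
    for _ in range(100):
        n_prov = int(rng.integers(4, 15))
        n_obj = int(rng.integers(2, 7))
        table = pd.DataFrame(
            rng.uniform(0, 1, (n_prov, n_obj)),
            index=range(n_prov),
            columns=[f"o{k}" for k in range(n_obj)],
        )
        result = find_hotspots(table)
        for p in table.index:  # independent percentile + comparison loop
            count = 0
            for col in table.columns:
                if table.loc[p, col] >= np.percentile(table[col].to_numpy(), 75):
                    count += 1
            assert result.counts[p] == count
            assert result.hotspot[p] == (count == n_obj)


def test_hotspot_counts_invariant_under_monotone_transforms():
    rng = np.random.default_rng(15)
    table = pd.DataFrame(
        rng.uniform(0, 1, (10, 4)), index=range(10), columns=list("abcd")
    )
    transformed = table.copy()
    transformed["a"] = table["a"] ** 3
    transformed["b"] = 2.0 * table["b"] + 5.0
    transformed["c"] = np.exp(table["c"])
    transformed["d"] = np.sqrt(table["d"])
    a = find_hotspots(table)
    b = find_hotspots(transformed)
    assert (a.counts == b.counts).all()


def test_hotspots_need_four_provinces():
    table = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
    with pytest.raises(ValueError):
        find_hotspots(table)


# -------------------------------------------------------------- top decile


def test_top_decile_uniform_column_returns_all():
    table = pd.DataFrame({"a": [0.3] * 5}, index=range(5))
    assert top_decile(table, "a") == {0, 1, 2, 3, 4}


def test_top_decile_strictly_increasing_column():
    table = pd.DataFrame({"a": np.linspace(0.1, 1.0, 10)}, index=range(10))
    thr = np.percentile(table["a"], 90)
    expected = set(table.index[table["a"] >= thr])
    assert top_decile(table, "a") == expected
    assert len(expected) in (1, 2)


def test_top_decile_subset_of_upper_quartile():
    rng = np.random.default_rng(16)
    table = pd.DataFrame(
        rng.uniform(0, 1, (12, 3)), index=range(12), columns=list("abc")
    )
    hotspots = find_hotspots(table)
    for obj in table.columns:
        deciles = top_decile(table, obj)
        quartile = set(table.index[table[obj] >= hotspots.thresholds[obj]])
        assert deciles <= quartile


# ---------------------------------------------------------- clustering


def test_identical_provinces_merge_first():
    table = pd.DataFrame(
        {"a": [0.5, 0.5, 0.0], "b": [0.2, 0.2, 0.9]}, index=["p", "q", "r"]
    )
    result = complementarity_cluster(table, n_clusters=2)
    first_merge = set(result.linkage_matrix[0, :2].astype(int))
    assert first_merge == {0, 1}
    assert result.linkage_matrix[0, 2] == pytest.approx(0.0)
    assert result.labels["p"] == result.labels["q"] != result.labels["r"]


def test_distances_symmetric_zero_diagonal():
    rng = np.random.default_rng(17)
    table = pd.DataFrame(rng.uniform(0, 1, (6, 4)), index=range(6))
    result = complementarity_cluster(table)
    d = result.distances.to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert d.min() >= 0


def test_column_scaling_preserves_ranks():
    rng = np.random.default_rng(18)
    col = pd.Series(rng.uniform(0, 5, 8))
    scaled = col / col.max()
    assert (col.rank() == scaled.rank()).all()


def test_cluster_annotations_use_top_decile_membership():
    table = pd.DataFrame(
        {"a": [1.0, 0.1, 0.1, 0.1], "b": [0.1, 1.0, 0.1, 0.1]},
        index=["w", "x", "y", "z"],
    )
    result = complementarity_cluster(table, n_clusters=3)
    cluster_of_w = result.labels["w"]
    assert "a" in result.cluster_objectives[int(cluster_of_w)]


def test_newick_export_is_parseable():
    import dendropy

    rng = np.random.default_rng(19)
    table = pd.DataFrame(
        rng.uniform(0, 1, (7, 3)), index=[f"prov{i}" for i in range(7)]
    )
    result = complementarity_cluster(table)
    tree = dendropy.Tree.get(data=result.newick, schema="newick")
    assert len(tree.leaf_nodes()) == 7
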