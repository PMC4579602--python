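"""Track accumulation, dispersal upscaling and the connectivity penalty."""

import numpy as np
import pytest
from scipy import sparse

from reefplan.connectivity import (
    ConnMatrix,
    TurtleTrack,
    accumulate_tracks,
    connectivity_penalty,
    track_to_pairs,
    upscale_dispersal,
)

GRID = (2, 2)  # ids: (0,0)->1 (0,1)->2 (1,0)->3 (1,1)->4


def track(*cells, tid=0):
    return TurtleTrack(individual_id=tid, species="green", path=tuple(cells))


def test_track_to_pairs_collapses_consecutive_duplicates():
    t = track((0, 0), (0, 0), (0, 1), (1, 1))
    assert track_to_pairs(t, GRID) == [(1, 2), (2, 4)]


def test_track_inside_one_cell_yields_no_pairs():
    assert track_to_pairs(track((0, 0), (0, 0)), GRID) == []


def test_track_revisits_accumulate():
    t = track((0, 0), (0, 1), (0, 0))
    assert track_to_pairs(t, GRID) == [(1, 2), (2, 1)]


def test_track_off_grid_rejected():
    with pytest.raises(ValueError):
        track_to_pairs(track((0, 0), (5, 5)), GRID)


def test_accumulate_single_track_unit_mass():
    m = accumulate_tracks([track((0, 0), (0, 1), (1, 1))], GRID)
    assert m.total_mass() == pytest.approx(1.0)
    assert m.matrix[0, 1] == pytest.approx(0.5)
    assert m.matrix[1, 0] == pytest.approx(0.5)  # symmetric storage
    assert m.matrix[1, 3] == pytest.approx(0.5)


def test_accumulate_mass_counts_pair_bearing_tracks():
    tracks = [
        track((0, 0), (0, 1), tid=0),
        track((1, 0), (1, 1), (0, 1), tid=1),
        track((0, 0), tid=2),  # pairless, does not contribute
    ]
    m = accumulate_tracks(tracks, GRID)
    assert m.total_mass() == pytest.approx(2.0, abs=1e-12)


def test_accumulate_two_identical_tracks_double():
    one = accumulate_tracks([track((0, 0), (0, 1))], GRID)
    two = accumulate_tracks([track((0, 0), (0, 1)), track((0, 0), (0, 1), tid=1)], GRID)
    assert np.allclose(two.matrix.toarray(), 2 * one.matrix.toarray())


def test_accumulate_per_pair_normalization_switch():
    t = track((0, 0), (0, 1), (1, 1))
    m = accumulate_tracks([t], GRID, normalization="per_pair")
    assert m.matrix[0, 1] == pytest.approx(1.0)
    assert m.total_mass() == pytest.approx(2.0)


def test_accumulate_pairless_only_warns():
    with pytest.warns(UserWarning):
        m = accumulate_tracks([track((0, 0))], GRID)
    assert m.total_mass() == 0.0


# -------------------------------------------------------------- upscaling


def test_upscale_singleton_complexes_is_identity():
    L = np.array([[0.5, 0.2], [0.1, 0.4]])
    membership = np.array([0, 1])
    cv = upscale_dispersal(L, membership, np.array([3.0, 7.0]))
    assert np.allclose(cv.matrix.toarray(), L)
    assert cv.directed


def test_upscale_area_weighted_arithmetic():
    # complex A = cells 0,1 (amounts 2,2); complex B = cell 2; L_AB = 0.3
    L = np.zeros((2, 2))
    L[0, 1] = 0.3
    cv = upscale_dispersal(L, np.array([0, 0, 1]), np.array([2.0, 2.0, 1.0]))
    dense = cv.matrix.toarray()
    assert dense[0, 2] == pytest.approx(0.15)
    assert dense[1, 2] == pytest.approx(0.15)
    assert dense.sum() == pytest.approx(0.3)


def test_upscale_conserves_pairwise_flows():
    rng = np.random.default_rng(6)
    for _ in range(100):
        k = int(rng.integers(2, 5))
        n = int(rng.integers(k, 12))
        L = rng.uniform(0, 0.3, (k, k))
        membership = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
        rng.shuffle(membership)
        reef = rng.uniform(0.1, 5.0, n)
        cv = upscale_dispersal(L, membership, reef).matrix.toarray()
        for a in range(k):
            ia = membership == a
            for b in range(k):
                ib = membership == b
                assert cv[np.ix_(ia, ib)].sum() == pytest.approx(L[a, b], abs=1e-9)


def test_upscale_zero_reef_complex_named():
    L = np.eye(2)
    with pytest.raises(ValueError, match="complex 1"):
        upscale_dispersal(L, np.array([0, 1]), np.array([1.0, 0.0]))


# ---------------------------------------------------------------- penalty


def toy_conn():
    m = np.zeros((3, 3))
    m[0, 1] = 0.4
    m[0, 2] = 0.3
    m[1, 2] = 0.2
    return ConnMatrix(sparse.csr_matrix(m), directed=True)


def test_penalty_trivial_selections():
    conn = toy_conn()
    assert connectivity_penalty(np.ones(3, bool), conn, 2.0) == 0.0
    assert connectivity_penalty(np.zeros(3, bool), conn, 2.0) == 0.0


def test_penalty_hand_arithmetic():
    sel = np.array([True, False, False])
    assert connectivity_penalty(sel, toy_conn(), 2.0) == pytest.approx(
        2.0 * (0.4 + 0.3)
    )


def test_penalty_negative_weight_rejected():
    with pytest.raises(ValueError):
        connectivity_penalty(np.ones(3, bool), toy_conn(), -1.0)


def test_adding_target_removes_cut_contribution():
    """If i is selected and CV_ij > 0, selecting j drops that edge's cost."""
    conn = toy_conn()
    before = connectivity_penalty(np.array([True, False, False]), conn, 1.0)
    after = connectivity_penalty(np.array([True, True, False]), conn, 1.0)
    # edge 0->1 (0.4) leaves the cut; j's own out-edge 1->2 (0.2) enters
    assert after == pytest.approx(before - 0.4 + 0.2)


def test_self_recruitment_never_penalized():
    m = np.zeros((2, 2))
    m[0, 0] = 0.9
    conn = ConnMatrix(sparse.csr_matrix(m), directed=True)
    assert connectivity_penalty(np.array([True, False]), conn, 1.0) == 0.0


# ------------------------------------------------------------ round trips


def test_conn_frame_round_trip_directed():
    rng = np.random.default_rng(7)
    m = rng.uniform(0, 1, (5, 5)) * (rng.random((5, 5)) < 0.4)
    conn = ConnMatrix(sparse.csr_matrix(m), directed=True)
    back = ConnMatrix.from_frame(conn.to_frame(), 5, directed=True)
    assert np.allclose(back.matrix.toarray(), conn.matrix.toarray())


def test_conn_frame_round_trip_symmetric():
    m = np.zeros((4, 4))
    m[0, 1] = m[1, 0] = 0.7
    m[2, 2] = 0.1
    conn = ConnMatrix(sparse.csr_matrix(m), directed=False)
    frame = conn.to_frame()
    assert len(frame) == 2  # each unordered pair written once
    back = ConnMatrix.from_frame(frame, 4, directed=False)
    assert np.allclose(back.matrix.toarray(), m)
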