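"""Pairwise planning-unit connectivity from telemetry tracks and larval dispersal.

Two kinds of connectivity feed the reserve-selection objective:

* **Turtle migration** — each satellite track is mapped onto the planning
  grid, consecutive distinct cells form connected pairs, and each track
  contributes a standardized total weight of 1 split equally over its pairs.
  Summing over individuals yields a symmetric accumulated matrix ``CV_ij``
  whose entries grow with the number of animals using a corridor.

* **Larval dispersal** — a biophysical-model stand-in provides asymmetric
  flows ``L_AB`` (proportion of larvae leaving complex A that settle in
  complex B) at the reef-complex scale.  These are disaggregated to planning
  units by reef-area weighting, conserving every pairwise complex flow.

Selected planning units whose outgoing flow leaves the reserve set are
penalized: ``penalty = b * sum_{i in R, j not in R} CV_ij``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass(frozen=True)
class TurtleTrack:
    """One individual's telemetry track as an ordered walk of grid cells."""

    individual_id: int
    species: str
    path: tuple[tuple[int, int], ...]  # (row, col) positions, visit order kept

    def __post_init__(self) -> None:
        if len(self.path) < 1:
            raise ValueError("track must contain at least one position")


class ConnMatrix:
    """Sparse pairwise connectivity strengths between planning units.

    Entries are indexed by 0-based planning-unit index (``pu_id - 1`` for
    row-major ids).  Turtle matrices are symmetric (migration corridors are
    used in both directions); dispersal matrices are directed.
    """

    def __init__(self, matrix: sparse.spmatrix, directed: bool):
        m = sparse.csr_matrix(matrix)
        if m.shape[0] != m.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if m.nnz and m.data.min() < 0:
            raise ValueError("connectivity strengths must be non-negative")
        m.eliminate_zeros()
        self.matrix = m
        self.directed = bool(directed)
        self._csc: sparse.csc_matrix | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def csc(self) -> sparse.csc_matrix:
        if self._csc is None:
            self._csc = self.matrix.tocsc()
        return self._csc

    def total_mass(self) -> float:
        """Sum of distinct connection weights.

        For symmetric matrices each unordered off-diagonal pair is stored in
        both orientations and counted once; diagonal (self-recruitment)
        entries count once.
        """
        total = float(self.matrix.sum())
        if self.directed:
            return total
        diag = float(self.matrix.diagonal().sum())
        return (total - diag) / 2.0 + diag

    def to_frame(self) -> pd.DataFrame:
        """Long table (id1, id2, value) with 1-based planning-unit ids.

        Directed matrices list both orientations explicitly; symmetric ones
        list each unordered pair once with ``id1 <= id2``.
        """
        coo = self.matrix.tocoo()
        i, j, v = coo.row + 1, coo.col + 1, coo.data
        if not self.directed:
            keep = i <= j
            i, j, v = i[keep], j[keep], v[keep]
        order = np.lexsort((j, i))
        return pd.DataFrame(
            {"id1": i[order], "id2": j[order], "boundary": v[order]}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n: int, directed: bool) -> "ConnMatrix":
        i = frame["id1"].to_numpy(int) - 1
        j = frame["id2"].to_numpy(int) - 1
        v = frame["boundary"].to_numpy(float)
        if directed:
            m = sparse.coo_matrix((v, (i, j)), shape=(n, n))
        else:
            off = i != j
            m = sparse.coo_matrix(
                (
                    np.concatenate([v, v[off]]),
                    (np.concatenate([i, j[off]]), np.concatenate([j, i[off]])),
                ),
                shape=(n, n),
            )
        return cls(m, directed)


def track_to_pairs(
    track: TurtleTrack, grid_shape: tuple[int, int]
) -> list[tuple[int, int]]:
    """Unordered planning-unit pairs connected by one track, in path order.

    Positions are mapped to row-major 1-based planning-unit ids, consecutive
    duplicates collapsed, and each consecutive distinct pair emitted.
    Revisited corridors appear multiple times and therefore accumulate.  A
    track confined to a single cell yields no pairs.
    """
    n_rows, n_cols = grid_shape
    ids: list[int] = []
    for row, col in track.path:
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise ValueError(
                f"track {track.individual_id} leaves the grid at ({row}, {col})"
            )
        pu = row * n_cols + col + 1
        if not ids or ids[-1] != pu:
            ids.append(pu)
    return [(ids[k], ids[k + 1]) for k in range(len(ids) - 1)]


def accumulate_tracks(
    tracks: list[TurtleTrack],
    grid_shape: tuple[int, int],
    normalization: str = "per_track",
) -> ConnMatrix:
    """Accumulated symmetric turtle connectivity matrix ``CV_ij``.

    With ``normalization="per_track"`` (default) each track contributes total
    weight 1 split equally over its pairs, so long tracks do not dominate;
    with ``"per_pair"`` every traversed pair contributes weight 1.  The total
    mass under the default equals the number of tracks with at least one pair.
    """
    if normalization not in ("per_track", "per_pair"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if not tracks:
        raise ValueError("at least one track is required")
    n = grid_shape[0] * grid_shape[1]
    weights: dict[tuple[int, int], float] = {}
    contributing = 0
    for track in tracks:
        pairs = track_to_pairs(track, grid_shape)
        if not pairs:
            continue
        contributing += 1
        w = 1.0 / len(pairs) if normalization == "per_track" else 1.0
        for a, b in pairs:
            key = (min(a, b), max(a, b))
            weights[key] = weights.get(key, 0.0) + w
    if contributing == 0:
        import warnings

        warnings.warn("no track connected two distinct planning units", stacklevel=2)
        return ConnMatrix(sparse.csr_matrix((n, n)), directed=False)
    i = np.array([a - 1 for a, _ in weights], dtype=int)
    j = np.array([b - 1 for _, b in weights], dtype=int)
    v = np.array(list(weights.values()))
    off = i != j
    m = sparse.coo_matrix(
        (
            np.concatenate([v, v[off]]),
            (np.concatenate([i, j[off]]), np.concatenate([j, i[off]])),
        ),
        shape=(n, n),
    )
    return ConnMatrix(m, directed=False)


def upscale_dispersal(
    complex_matrix: np.ndarray,
    membership: np.ndarray,
    reef_amounts: np.ndarray,
) -> ConnMatrix:
    """Disaggregate complex-scale larval flows to planning units.

    For cells ``i`` in complex A and ``j`` in complex B (including A == B and
    i == j, i.e. self-recruitment), ``CV_ij = L_AB * (a_i / A_A) * (a_j / A_B)``
    where ``a_i`` is the reef amount in cell ``i`` and ``A_A`` the complex
    total.  Pairwise complex flows are exactly conserved:
    ``sum_{i in A, j in B} CV_ij = L_AB``.

    Parameters
    ----------
    complex_matrix : (K, K) array
        Directed flows ``L_AB`` between reef complexes.
    membership : (n_units,) int array
        Complex index per planning unit, ``-1`` for non-reef cells.
    reef_amounts : (n_units,) array
        Reef habitat amount per planning unit.
    """
    L = np.asarray(complex_matrix, dtype=float)
    membership = np.asarray(membership)
    reef = np.asarray(reef_amounts, dtype=float)
    n = membership.size
    n_complex = L.shape[0]
    if L.shape != (n_complex, n_complex):
        raise ValueError("complex matrix must be square")
    cells = [np.flatnonzero(membership == k) for k in range(n_complex)]
    weights = []
    for k, idx in enumerate(cells):
        total = reef[idx].sum() if idx.size else 0.0
        if total <= 0:
            raise ValueError(f"reef complex {k} has zero total reef amount")
        weights.append(reef[idx] / total)
    rows, cols, vals = [], [], []
    for a in range(n_complex):
        for b in range(n_complex):
            flow = L[a, b]
            if flow == 0.0:
                continue
            block = flow * np.outer(weights[a], weights[b])
            rr, cc = np.meshgrid(cells[a], cells[b], indexing="ij")
            rows.append(rr.ravel())
            cols.append(cc.ravel())
            vals.append(block.ravel())
    if rows:
        m = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
    else:
        m = sparse.coo_matrix((n, n))
    return ConnMatrix(m, directed=True)


def connectivity_penalty(
    selected: np.ndarray, conn: ConnMatrix, b: float
) -> float:
    """Penalty for flow leaving the reserve set.

    ``b * sum_{i in R, j not in R} CV_ij``: selected source units whose
    connectivity exits the candidate reserve system are penalized.  Empty and
    full selections both score 0 (no cut edges).
    """
    if b < 0:
        raise ValueError("connectivity weight b must be non-negative")
    sel = np.asarray(selected, dtype=bool)
    if sel.size != conn.n:
        raise ValueError("selection vector does not match matrix size")
    if b == 0 or not sel.any() or sel.all():
        return 0.0
    return float(b * conn.matrix[sel][:, ~sel].sum())
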