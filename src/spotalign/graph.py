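"""Spatial neighbor graphs over spot coordinates.

Each slice gets an undirected graph whose adjacency ``A`` connects two spots
iff their Euclidean distance is strictly less than a radius ``r``.  Message
passing in the autoencoder aggregates over the neighbor set ``S_i``, which
always contains the spot itself so that isolated spots still propagate their
own features; the adjacency matrix itself keeps a zero diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

__all__ = ["SpatialGraph", "build_graph", "suggest_radius", "block_diagonal"]


@dataclass
class SpatialGraph:
    """Binary symmetric radius graph of one (or several stacked) slices."""

    adjacency: sp.csr_matrix  # n x n, zero diagonal, symmetric {0,1}
    radius: float

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def neighbor_sets(self) -> list[np.ndarray]:
        """Neighbor index sets ``S_i``, each including ``i`` itself."""
        A = self.adjacency.tolil()
        return [
            np.unique(np.append(np.asarray(row, dtype=int), i))
            for i, row in enumerate(A.rows)
        ]

    def mask_with_self(self) -> np.ndarray:
        """Dense boolean mask of A + I, the support of the attention."""
        A = self.adjacency.toarray().astype(bool)
        np.fill_diagonal(A, True)
        return A

    def mean_neighbors(self) -> float:
        """Mean degree excluding self."""
        return float(self.adjacency.sum() / self.n_spots)

    def to_edge_list(self) -> pd.DataFrame:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return pd.DataFrame({"source": coo.row, "target": coo.col})


def build_graph(slice_or_coords, radius: float) -> SpatialGraph:
    """Radius graph: edge iff Euclidean distance < ``radius`` (strict).

    Accepts an ``STSlice`` or a raw (n x 2) coordinate array.  Duplicate
    coordinates are legal (distance 0 < r gives an edge).
    """
    coords = getattr(slice_or_coords, "coords", slice_or_coords)
    coords = np.asarray(coords, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]  # query_pairs is <=; the graph is strict <
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        A = sp.csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
    else:
        A = sp.csr_matrix((n, n), dtype=np.int8)
    return SpatialGraph(adjacency=A, radius=float(radius))


def suggest_radius(slice_or_coords, target_mean_neighbors: float = 6.0,
                   max_candidates: int = 2000) -> float:
    """Smallest radius whose mean neighbor count reaches the target.

    Candidates are the observed pairwise distances; the returned value sits
    just above the selected distance so the strict ``<`` test includes it.
    If the target exceeds what any radius can reach, the largest pairwise
    distance (plus epsilon) is returned.  For very large slices the candidate
    set is estimated from a seeded subsample of spots.
    """
    coords = getattr(slice_or_coords, "coords", slice_or_coords)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two spots")
    if n > max_candidates:
        idx = np.random.RandomState(0).choice(n, max_candidates, replace=False)
        coords = coords[idx]
        n = max_candidates
    d = np.sort(pdist(coords))
    d = d[d > 0]
    if d.size == 0:
        warnings.warn("all coordinates identical; returning a token radius")
        return 1e-6
    # mean neighbor count at radius just above d[k] is 2*(k+1)/n
    needed = int(np.ceil(target_mean_neighbors * n / 2.0))
    k = min(needed, d.size) - 1
    return float(d[k]) * (1.0 + 1e-9)


def block_diagonal(graphs: list[SpatialGraph]) -> SpatialGraph:
    """Stack per-slice graphs with no cross-slice edges."""
    A = sp.block_diag([g.adjacency for g in graphs], format="csr")
    return SpatialGraph(adjacency=A, radius=max(g.radius for g in graphs))
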