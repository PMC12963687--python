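"""Neighbour-graph smoothing and local hotspot detection.

Hotspots of a per-spot feature (a gene's expression or a signature score) are
called with the classical Getis-Ord Gi* local statistic on the spatial
k-nearest-neighbour graph with binary weights including self:

    z_i = (S_i - xbar * W_i) / (s * sqrt((n * W_i - W_i^2) / (n - 1)))

where S_i is the sum of the value over spot i and its k neighbours,
W_i = k + 1 the neighbourhood size, and xbar, s the global mean and
(population) standard deviation. One-sided upper p-values from the standard
normal reference are corrected across spots by Benjamini-Hochberg; spots with
q <= alpha are flagged as hotspots. z is location/scale free, so the flags
are invariant under affine transforms of the values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .cooccurrence import adjust_bh

__all__ = [
    "NeighborGraph",
    "HotspotResult",
    "knn_neighbors",
    "smooth_values",
    "local_gi_star",
    "call_hotspots",
]


@dataclass
class NeighborGraph:
    """k nearest neighbours per spot by Euclidean um distance.

    ``indices`` is ``(n, k)``; no spot lists itself. Distance ties are broken
    by spot index order, so the graph is deterministic. ``symmetric`` records
    whether every edge is mutual.
    """

    indices: np.ndarray
    k: int
    symmetric: bool

    @property
    def n(self) -> int:
        return len(self.indices)

    def edges(self) -> np.ndarray:
        """Directed (i, j) edge list, shape (n * k, 2)."""
        n, k = self.indices.shape
        src = np.repeat(np.arange(n), k)
        return np.column_stack([src, self.indices.ravel()])


def knn_neighbors(coords, k: int = 6) -> NeighborGraph:
    """k nearest neighbours per spot, ties broken by spot index order."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n <= k:
        raise ValueError(f"need more than k={k} spots, got {n}")
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1, kind="stable")  # stable => index tie-break
    indices = order[:, :k]
    mutual = np.zeros((n, n), dtype=bool)
    mutual[np.repeat(np.arange(n), k), indices.ravel()] = True
    return NeighborGraph(indices=indices, k=k, symmetric=bool((mutual == mutual.T).all()))


def smooth_values(values, graph: NeighborGraph, include_self: bool = True) -> np.ndarray:
    """Per-spot mean of the value over the neighbourhood (optionally incl. self)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if values.shape != (graph.n,):
        raise ValueError("one value per spot required")
    neighbor_sum = values[graph.indices].sum(axis=1)
    if include_self:
        return (neighbor_sum + values) / (graph.k + 1)
    return neighbor_sum / graph.k


def local_gi_star(values, graph: NeighborGraph) -> np.ndarray:
    """Getis-Ord Gi* z-score per spot (binary weights including self).

    A zero-variance field is a degenerate input: every z is defined as 0.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (graph.n,):
        raise ValueError("one value per spot required")
    n = graph.n
    xbar = values.mean()
    s = values.std()  # population sd, as in the classical formulation
    if s == 0:
        return np.zeros(n)
    w = graph.k + 1
    local_sum = values[graph.indices].sum(axis=1) + values
    denom = s * np.sqrt((n * w - w**2) / (n - 1))
    return (local_sum - xbar * w) / denom


@dataclass
class HotspotResult:
    """Per-spot Gi* z, one-sided p, BH q, and the hotspot flag (q <= alpha)."""

    z: np.ndarray
    pvalue: np.ndarray
    qvalue: np.ndarray
    flag: np.ndarray
    alpha: float
    degenerate: bool = False


def call_hotspots(z, alpha: float = 0.05) -> HotspotResult:
    """Flag hotspots from Gi* z-scores.

    One-sided upper p from the standard normal reference, BH correction
    across spots, flag iff q <= alpha. An all-zero z field (the degenerate
    zero-variance path) yields no hotspots and sets ``degenerate``.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    degenerate = bool(np.all(z == 0))
    p = stats.norm.sf(z)
    q = adjust_bh(p)
    flag = q <= alpha
    if degenerate:
        flag = np.zeros_like(flag)
    return HotspotResult(z=z, pvalue=p, qvalue=q, flag=flag, alpha=alpha, degenerate=degenerate)
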