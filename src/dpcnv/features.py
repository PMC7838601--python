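"""Density-peak statistics over the segment set.

Each segment is a point in the one-dimensional space of its fitted RD level,
so the pairwise distance is d(i, j) = |level_i - level_j|.  From the distance
structure two features are derived per segment:

* local density rho_i — the number of other segments strictly within the
  radius gamma of segment i;
* minimum distance delta_i — the distance from segment i to its nearest
  segment of higher density (for the single densest segment, the maximum
  distance to any other segment).

Segments carrying copy-number changes sit in the sparse tail of the level
distribution: low rho, high delta.  Density ties are broken deterministically
by genomic order (rho descending, then segment index ascending), which
reduces to the strictly-denser rule whenever rho values are unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import SegmentSet

__all__ = [
    "DistanceMatrix",
    "FeatureTable",
    "pairwise_distances",
    "select_gamma",
    "local_density",
    "min_distance",
    "compute_features",
]


class DistanceMatrix:
    """Symmetric distance accessor over scalar segment levels."""

    def __init__(self, levels: np.ndarray):
        self.levels = np.asarray(levels, dtype=float)
        if len(self.levels) < 2:
            raise ValueError("density structure needs at least 2 segments")

    @property
    def n(self) -> int:
        return len(self.levels)

    def __call__(self, i: int, j: int) -> float:
        return abs(self.levels[i] - self.levels[j])

    def full(self) -> np.ndarray:
        return np.abs(self.levels[:, None] - self.levels[None, :])

    def offdiag(self) -> np.ndarray:
        """The n(n-1)/2 pairwise distances, unordered."""
        d = self.full()
        return d[np.triu_indices(self.n, k=1)]


def pairwise_distances(segments: SegmentSet) -> DistanceMatrix:
    """Distance structure over segment RD levels; requires >= 2 segments."""
    return DistanceMatrix(segments.level)


def select_gamma(distances: DistanceMatrix, neighbor_fraction: float = 0.02) -> float:
    """Radius as the ``neighbor_fraction`` quantile of the pairwise distances.

    Linear-interpolation quantile; if massive ties drive the quantile to 0,
    the smallest positive distance is used instead.  A profile in which every
    pairwise distance is zero has no density structure and raises.
    """
    if not (0.0 < neighbor_fraction < 1.0):
        raise ValueError(f"neighbor_fraction must be in (0,1), got {neighbor_fraction}")
    d = distances.offdiag()
    positive = d[d > 0]
    if len(positive) == 0:
        raise ValueError("all pairwise distances are zero: degenerate profile")
    gamma = float(np.quantile(d, neighbor_fraction))
    if gamma <= 0.0:
        gamma = float(positive.min())
    return gamma


def local_density(distances: DistanceMatrix, gamma: float) -> np.ndarray:
    """rho_i = #{ j != i : d(i,j) < gamma }, strict inequality."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    d = distances.full()
    rho = (d < gamma).sum(axis=1) - 1  # the diagonal always satisfies d < gamma
    return rho.astype(np.int64)


def min_distance(distances: DistanceMatrix, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """delta per segment plus the deterministic density ordering.

    A segment with at least one strictly denser segment takes
    delta_i = min_{j : rho_j > rho_i} d(i, j).  Segments of globally maximal
    density have no denser neighbor; the first of them in genomic order is
    the density peak and takes delta = max_j d(i, j), while any further
    maximal-density segment takes its minimum distance to the maximal-density
    segments preceding it in genomic order (deterministic resolution of a
    non-unique peak).  Returns (delta, order_rank) where order_rank[i] is
    segment i's position in the (rho descending, index ascending) ordering.
    """
    rho = np.asarray(rho)
    n = distances.n
    if len(rho) != n:
        raise ValueError("rho length mismatch")
    order = np.lexsort((np.arange(n), -rho))  # rho desc, index asc
    d = distances.full()
    delta = np.empty(n)
    rho_max = rho.max()
    top_set = np.flatnonzero(rho == rho_max)
    peak = top_set[0]
    delta[peak] = d[peak].max()
    for pos, i in enumerate(top_set[1:], start=1):
        delta[i] = d[i, top_set[:pos]].min()
    for i in np.flatnonzero(rho < rho_max):
        delta[i] = d[i, rho > rho[i]].min()
    order_rank = np.empty(n, dtype=np.int64)
    order_rank[order] = np.arange(n)
    return delta, order_rank


@dataclass
class FeatureTable:
    """Per-segment (rho, delta) plus the distance structure and gamma."""

    rho: np.ndarray
    delta: np.ndarray
    order_rank: np.ndarray
    gamma: float
    distances: DistanceMatrix

    @property
    def n(self) -> int:
        return len(self.rho)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rho": self.rho, "delta": self.delta, "order_rank": self.order_rank})


def compute_features(
    segments: SegmentSet,
    gamma: float | None = None,
    neighbor_fraction: float = 0.02,
) -> FeatureTable:
    """Full feature computation: distances, gamma, rho, delta."""
    distances = pairwise_distances(segments)
    if gamma is None:
        gamma = select_gamma(distances, neighbor_fraction)
    rho = local_density(distances, gamma)
    delta, order_rank = min_distance(distances, rho)
    return FeatureTable(rho=rho, delta=delta, order_rank=order_rank, gamma=gamma, distances=distances)
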