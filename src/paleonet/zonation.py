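"""Stratigraphic zonation of core records.

Zones — contiguous runs of depth intervals with a distinct assemblage —
are delineated by constrained incremental sum-of-squares clustering
(CONISS) of a Bray–Curtis dissimilarity matrix, and the number of
significant zones is chosen by comparing the dispersion explained by each
successive split against a broken-stick null expectation.

The clustering is agglomerative but only stratigraphically adjacent
clusters may merge.  Within-cluster dispersion of a cluster C is computed
directly from the dissimilarity matrix as ``sum_{i<j in C} d_ij / |C|``
(the within-cluster sum of squares when d is squared Euclidean); each
merge is the adjacent pair whose union increases total dispersion least,
with ties broken toward the stratigraphically earlier pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._errors import UsageError
from .assemblage import AbundanceMatrix

DEFAULT_MIN_INTERVALS = 5


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities between stratigraphically
    ordered samples, zero diagonal."""

    d: pd.DataFrame

    @property
    def samples(self) -> list:
        return list(self.d.index)

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class Merge:
    """One agglomeration step joining two adjacent runs of intervals."""

    left: tuple[int, int]    # inclusive positional range of the left cluster
    right: tuple[int, int]
    increment: float         # increase in total within-cluster dispersion


@dataclass
class ClusterTree:
    """The full constrained agglomeration: n-1 adjacent merges."""

    merges: list[Merge]
    samples: list
    total_dispersion: float

    @property
    def n(self) -> int:
        return len(self.samples)

    def cut(self, n_zones: int) -> np.ndarray:
        """Zone label (1..n_zones, ordered stratigraphically) per interval."""
        if not 1 <= n_zones <= self.n:
            raise UsageError(f"n_zones must be in [1, {self.n}]")
        boundaries = {0}
        # undo the last n_zones-1 merges: their junctions are the boundaries
        for m in self.merges[len(self.merges) - (n_zones - 1):]:
            boundaries.add(m.right[0])
        starts = sorted(boundaries)
        labels = np.empty(self.n, dtype=int)
        for z, s in enumerate(starts, start=1):
            e = starts[z] if z < len(starts) else self.n
            labels[s:e] = z
        return labels


def bray_curtis(am: AbundanceMatrix) -> DissimilarityMatrix:
    """Percentage-difference (Bray–Curtis) dissimilarity between samples:
    ``d_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk)``."""
    x = am.values.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    if np.count_nonzero(totals == 0) >= 2:
        empt = [s for s, t in zip(am.samples, totals) if t == 0]
        raise UsageError(f"Bray-Curtis undefined between all-zero samples: {empt}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(pd.DataFrame(d, index=am.samples, columns=am.samples))


def _dispersion(d: np.ndarray, lo: int, hi: int) -> float:
    """Within-cluster dispersion of the contiguous run [lo, hi]."""
    size = hi - lo + 1
    if size < 2:
        return 0.0
    block = d[lo:hi + 1, lo:hi + 1]
    return float(block.sum() / 2.0 / size)


def coniss(dm: DissimilarityMatrix) -> ClusterTree:
    """Constrained incremental sum-of-squares agglomeration.

    Only adjacent clusters merge; the greedy criterion is the minimal
    increase in within-cluster dispersion.  Ties go to the
    stratigraphically earlier (shallower) adjacent pair.
    """
    n = dm.n
    if n < 3:
        raise UsageError("CONISS needs at least 3 samples")
    d = dm.d.to_numpy(dtype=float)
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise UsageError("dissimilarity matrix must be symmetric with zero diagonal")

    clusters: list[tuple[int, int]] = [(i, i) for i in range(n)]
    disp = [0.0] * n
    merges: list[Merge] = []
    while len(clusters) > 1:
        best_inc, best_k = np.inf, -1
        for k in range(len(clusters) - 1):
            lo, _ = clusters[k]
            _, hi = clusters[k + 1]
            inc = _dispersion(d, lo, hi) - disp[k] - disp[k + 1]
            if inc < best_inc - 1e-15:
                best_inc, best_k = inc, k
        lo, _ = clusters[best_k]
        _, hi = clusters[best_k + 1]
        merges.append(
            Merge(left=clusters[best_k], right=clusters[best_k + 1],
                  increment=float(best_inc))
        )
        clusters[best_k:best_k + 2] = [(lo, hi)]
        disp[best_k:best_k + 2] = [_dispersion(d, lo, hi)]
    total = _dispersion(d, 0, n - 1)
    return ClusterTree(merges=merges, samples=dm.samples, total_dispersion=total)


def broken_stick(tree: ClusterTree) -> int:
    """Number of significant zones by the broken-stick criterion.

    Reading the dendrogram top-down, the k-th split explains the
    dispersion increment of the k-th merge from the end.  Under the
    broken-stick null the k-th largest of n-1 random fractions has
    expectation ``(1/(n-1)) * sum_{j=k}^{n-1} 1/j`` of the total; the zone
    count is 1 plus the number of leading splits whose observed explained
    fraction exceeds that expectation.
    """
    n = tree.n
    total = tree.total_dispersion
    if total <= 0:
        return 1
    n_splits = n - 1
    expected = np.array([
        sum(1.0 / j for j in range(k, n_splits + 1)) / n_splits
        for k in range(1, n_splits + 1)
    ])
    observed = np.array([m.increment for m in reversed(tree.merges)]) / total
    k = 0
    while k < n_splits and observed[k] > expected[k]:
        k += 1
    return 1 + k


@dataclass
class ZoneAssignment:
    """Contiguous partition of a core into zones.

    ``zones`` maps each interval (in stratigraphic order) to a 1-based
    zone label; ``median_age`` gives the median calibrated year per zone.
    """

    samples: list
    labels: np.ndarray
    median_age: dict[int, float]
    n_zones: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.samples, "zone": self.labels})

    def members(self, zone: int) -> list:
        return [s for s, z in zip(self.samples, self.labels) if z == zone]


def assign_zones(
    tree: ClusterTree,
    n_zones: int,
    min_intervals: int = DEFAULT_MIN_INTERVALS,
    ages=None,
) -> ZoneAssignment:
    """Cut the tree at ``n_zones``, enforcing a minimum zone size.

    If any zone has fewer than ``min_intervals`` members (too few for a
    correlation network), the zone count is decremented and the cut
    retried.  ``ages`` is an optional per-interval chronology used for the
    per-zone median year.
    """
    if min_intervals > tree.n:
        raise UsageError(
            f"record has {tree.n} intervals, fewer than min_intervals={min_intervals}"
        )
    k = int(n_zones)
    while k > 1:
        labels = tree.cut(k)
        sizes = np.bincount(labels)[1:]
        if sizes.min() >= min_intervals:
            break
        k -= 1
    else:
        labels = tree.cut(1)
    median_age: dict[int, float] = {}
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        for z in range(1, k + 1):
            median_age[z] = float(np.median(ages[labels == z]))
    return ZoneAssignment(
        samples=tree.samples, labels=labels, median_age=median_age, n_zones=k
    )
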