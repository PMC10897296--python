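"""Temporal clustering of daily mobility matrices into regimes.

Days with similar mobility patterns — measured by the Frobenius distance
between their transition matrices — are grouped by Ward agglomerative
clustering, typically into two regimes: ordinary mobility and confinement
(lockdown).  For each regime the module extracts the entrywise mean matrix,
the *most representative* member (the day closest to the mean), and the
*current matrix*: the representative transition probabilities weighted by
the census origin density, giving the share of the whole population flowing
along each link per step.

The Frobenius distance between matrices equals the Euclidean distance
between their vectorized forms, so classical Ward linkage on the vectorized
series is exactly Ward on the Frobenius geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch

from .matrices import MatrixSeries, TransitionMatrix, p_out
from .quality import DensityVector


@dataclass(frozen=True)
class TemporalClustering:
    """Cluster index per day plus the agglomeration merge history.

    ``day_labels[t]`` is the cluster of day ``t``; labels are contiguous
    from 0 in order of first appearance.  ``linkage_record`` is the scipy
    linkage matrix of the full merge history.
    """

    day_labels: np.ndarray
    linkage_record: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.day_labels, dtype=int)
        object.__setattr__(self, "day_labels", labels)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster labels must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.day_labels.max()) + 1

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.day_labels == k)


@dataclass(frozen=True)
class CurrentMatrix:
    """Population flux per link: transition probability times origin density.

    Entries are nonnegative and sum to 1 over the whole matrix (rows of the
    transition matrix sum to 1 and the density sums to 1).
    """

    values: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        n = len(self.node_labels)
        if values.shape != (n, n):
            raise ValueError("values must be square over the node labels")
        if np.any(values < 0):
            raise ValueError("current entries must be nonnegative")
        if abs(values.sum() - 1.0) > 1e-12:
            raise ValueError(f"currents sum to {values.sum()!r}, not 1")


def frobenius_distance(a: TransitionMatrix, b: TransitionMatrix) -> float:
    """Frobenius distance: sqrt of the summed squared entry differences."""
    if a.node_labels != b.node_labels:
        raise ValueError("matrices are over different node sets")
    return float(np.linalg.norm(a.values - b.values, ord="fro"))


def cluster_days(
    series: MatrixSeries, n_clusters: int = 2
) -> TemporalClustering:
    """Ward agglomerative clustering of a daily matrix series.

    Bottom-up agglomeration under Ward linkage on the pairwise Frobenius
    distances, stopped at ``n_clusters``; deterministic given the input
    (scipy's linkage resolves ties by the lowest pair index).  Labels are
    renumbered by order of first appearance along the series.
    """
    if len(series) < n_clusters:
        raise ValueError(
            f"series of length {len(series)} cannot form {n_clusters} clusters"
        )
    x = series.stacked().reshape(len(series), -1)
    linkage = sch.linkage(x, method="ward")
    # cut_tree honors the requested cluster count even under tied merge
    # heights (e.g. an all-identical series), where fcluster would not
    raw = sch.cut_tree(linkage, n_clusters=n_clusters)[:, 0]
    # renumber by first appearance so labels are stable and contiguous
    order: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for t, r in enumerate(raw):
        if r not in order:
            order[r] = len(order)
        labels[t] = order[r]
    return TemporalClustering(day_labels=labels, linkage_record=linkage)


def cluster_mean_matrix(
    series: MatrixSeries, clustering: TemporalClustering, k: int
) -> TransitionMatrix:
    """Entrywise mean of the matrices in cluster ``k``, row-renormalized.

    The mean of row-stochastic matrices is row-stochastic exactly; the
    renormalization only guards against float drift.
    """
    members = clustering.members(k)
    if members.size == 0:
        raise ValueError(f"cluster {k} is empty")
    mean = series.stacked()[members].mean(axis=0)
    mean /= mean.sum(axis=1, keepdims=True)
    return TransitionMatrix(
        values=mean,
        node_labels=series.node_labels,
        time_tag=f"mean_C{k}",
        window=series[0].window,
    )


def representative_matrix(
    series: MatrixSeries, clustering: TemporalClustering, k: int
) -> TransitionMatrix:
    """The member of cluster ``k`` closest (Frobenius) to the cluster mean.

    Ties are broken in favour of the earliest day.  The result is always an
    actual series member, never the mean itself.
    """
    members = clustering.members(k)
    if members.size == 0:
        raise ValueError(f"cluster {k} is empty")
    mean = cluster_mean_matrix(series, clustering, k)
    distances = [frobenius_distance(series[int(t)], mean) for t in members]
    best = members[int(np.argmin(distances))]  # argmin takes the first tie
    return series[int(best)]


def current_matrix(
    rep: TransitionMatrix, rho: DensityVector
) -> CurrentMatrix:
    """Current matrix ``J_ij = P_ij * rho_i`` from a representative matrix.

    ``rho`` should be the *census* origin density, not the stationary
    density of the matrix itself: the census is the more accurate estimate
    of where people actually are, so the currents better reflect real
    fluxes even though detailed balance is then not exact.  The global sum
    is automatically 1.
    """
    if rep.node_labels != rho.node_labels:
        raise ValueError("node labels of matrix and density do not match")
    values = rep.values * rho.values[:, None]
    return CurrentMatrix(values=values, node_labels=rep.node_labels)


def confined_cluster(
    series: MatrixSeries, clustering: TemporalClustering
) -> int:
    """Index of the cluster with the lower mean outward mobility.

    Identifies which temporal regime is the confined (lockdown) one: the
    cluster whose members have the smaller average probability of leaving
    the home node.
    """
    means = [
        np.mean([p_out(series[int(t)]) for t in clustering.members(k)])
        for k in range(clustering.n_clusters)
    ]
    return int(np.argmin(means))
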