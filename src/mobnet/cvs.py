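"""Critical Variable Selection: effective distances, resolution, relevance.

The method clusters the nodes of a mobility network by an information-
theoretic criterion instead of modularity.  It runs in three stages:

1.  **Effective distance.**  Each directed link with transition probability
    ``P_ij > 0`` gets length ``d_ij = 1 - ln(P_ij)`` (likely hops are
    short); the length of a multi-hop path is the sum of its link lengths
    and ``D_ij`` is the shortest such path.  The all-pairs matrix is
    assembled by an ordered case rule — zero on the diagonal, the direct
    link length if one exists, the reverse link length if only the reverse
    exists, then forward/reverse shortest-path lengths, and finally a large
    finite cap (100x the largest well-defined entry) for mutually
    unreachable pairs.  The matrix is symmetrized and normalized by its
    mean, so downstream clustering does not depend on the cap scale.

2.  **Resolution and relevance.**  For a partition of ``N`` objects with
    cluster sizes ``k_s``, the resolution is the base-N Shannon entropy of
    the size shares ``k_s/N`` (0 for one cluster, 1 for all singletons).
    The relevance is the base-N Shannon entropy of the probability
    ``k*m_k/N`` that a random object sits in a cluster of size ``k``
    (``m_k`` = number of clusters of size ``k``); it vanishes at both
    trivial extremes and peaks at the most informative partitions.

3.  **Optimal partition.**  Agglomerative clustering of the effective
    distance matrix produces one partition per cluster count K = 1..N; the
    partition maximizing the relevance (smallest K on ties) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.sparse
import scipy.sparse.csgraph
from scipy.spatial.distance import squareform

from .gmc import Partition
from .matrices import TransitionMatrix

#: Multiplier turning the largest well-defined distance into the finite cap
#: standing in for "infinite" (mutually unreachable pairs).
UNREACHABLE_CAP_FACTOR = 100.0

Linkage = Literal["average", "complete", "single"]


@dataclass(frozen=True)
class EffectiveDistanceMatrix:
    """Symmetric, mean-normalized all-pairs effective distance matrix.

    ``finite_cap`` is the capped "infinite" value on the normalized scale,
    or None if every pair was reachable in at least one direction.
    """

    values: np.ndarray
    node_labels: tuple[str, ...]
    finite_cap: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        n = len(self.node_labels)
        if values.shape != (n, n):
            raise ValueError("values must be square over the node labels")
        if np.any(values < 0):
            raise ValueError("distances must be nonnegative")
        if np.any(np.diag(values) != 0):
            raise ValueError("diagonal must be zero")
        if not np.allclose(values, values.T, rtol=0, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if abs(values.mean() - 1.0) > 1e-9:
            raise ValueError("matrix must be normalized to mean 1")


@dataclass(frozen=True)
class RelevanceCurve:
    """Resolution/relevance trade-off along an agglomerative path.

    One entry per cluster count ``K = 1..N``: the partition, its resolution
    ``H[s]`` and its relevance ``H[k]``.
    """

    cluster_counts: tuple[int, ...]
    resolutions: tuple[float, ...]
    relevances: tuple[float, ...]
    partitions: tuple[Partition, ...]


@dataclass(frozen=True)
class CvsPartition:
    """The relevance-optimal partition and where it sits on the curve."""

    partition: Partition
    relevance: float
    n_clusters: int


def effective_path_lengths(
    matrix: TransitionMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct link lengths and all-pairs shortest effective path lengths.

    Returns ``(d, D)``: ``d_ij = 1 - ln(P_ij)`` for off-diagonal
    ``P_ij > 0`` (``inf`` where no direct link), and ``D_ij`` the length of
    the shortest directed path under ``d`` (Dijkstra; all link lengths are
    >= 1 since ``P_ij <= 1``, so shortest paths are well-posed).
    """
    p = matrix.values
    n = matrix.n_nodes
    direct_link = p > 0
    np.fill_diagonal(direct_link, False)
    log_p = np.full((n, n), -np.inf)
    np.log(p, out=log_p, where=direct_link)
    d = np.where(direct_link, 1.0 - log_p, np.inf)
    graph = scipy.sparse.csr_matrix(np.where(direct_link, d, 0.0))
    shortest = scipy.sparse.csgraph.dijkstra(graph, directed=True)
    return d, shortest


def effective_distance(
    matrix: TransitionMatrix,
) -> EffectiveDistanceMatrix:
    """All-pairs effective distance matrix of a transition matrix.

    Built from the link and path lengths of
    :func:`effective_path_lengths`; see the module docstring for the
    ordered assembly rule, capping and normalization.
    """
    if matrix.n_nodes < 2:
        raise ValueError("effective distance needs at least 2 nodes")
    n = matrix.n_nodes
    d, shortest = effective_path_lengths(matrix)
    direct_link = np.isfinite(d)

    delta = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    reverse_link = direct_link.T
    fwd_path = np.isfinite(shortest)
    rev_path = fwd_path.T
    # ordered cases: first match wins
    case_direct = direct_link
    case_rev_direct = ~direct_link & reverse_link
    case_fwd_path = ~direct_link & ~reverse_link & fwd_path
    case_rev_path = ~direct_link & ~reverse_link & ~fwd_path & rev_path
    case_unreachable = off & ~direct_link & ~reverse_link & ~fwd_path & ~rev_path

    delta[case_direct] = d[case_direct]
    delta[case_rev_direct] = d.T[case_rev_direct]
    delta[case_fwd_path] = shortest[case_fwd_path]
    delta[case_rev_path] = shortest.T[case_rev_path]

    cap: float | None = None
    if np.any(case_unreachable):
        finite_entries = delta[off & ~case_unreachable]
        if finite_entries.size == 0:
            raise ValueError("no pair of nodes is connected in any direction")
        cap = UNREACHABLE_CAP_FACTOR * float(finite_entries.max())
        delta[case_unreachable] = cap

    sym = (delta + delta.T) / 2.0
    mean = sym.mean()
    sym /= mean
    return EffectiveDistanceMatrix(
        values=sym,
        node_labels=matrix.node_labels,
        finite_cap=None if cap is None else cap / mean,
    )


def resolution(partition: Partition) -> float:
    """Resolution H[s]: base-N entropy of the cluster-size shares.

    0 when all objects share one cluster, 1 when every object is alone.
    """
    n = partition.n_nodes
    if n < 2:
        raise ValueError("resolution needs at least 2 objects")
    shares = partition.cluster_sizes() / n
    return float(-np.sum(shares * np.log(shares)) / np.log(n)) + 0.0


def relevance(partition: Partition) -> float:
    """Relevance H[k]: base-N entropy of the size-frequency distribution.

    With ``m_k`` clusters of size ``k``, the probability that a random
    object lies in a size-``k`` cluster is ``k*m_k/N``; the relevance is
    the entropy of that distribution.  It is 0 at both trivial limits
    (K=1 and K=N) and positive in between, peaking at the most informative
    cluster-size mixtures.
    """
    n = partition.n_nodes
    if n < 2:
        raise ValueError("relevance needs at least 2 objects")
    sizes = partition.cluster_sizes()
    ks, m_k = np.unique(sizes, return_counts=True)
    probs = ks * m_k / n
    return float(-np.sum(probs * np.log(probs)) / np.log(n)) + 0.0


def cvs_partition(
    delta: EffectiveDistanceMatrix, linkage: Linkage = "average"
) -> tuple[CvsPartition, RelevanceCurve]:
    """Relevance-optimal partition from an effective distance matrix.

    Agglomerates the nodes on the precomputed distances (average linkage by
    default: Ward would require a coordinate geometry the distances lack),
    evaluates resolution and relevance for every cluster count K = 1..N,
    and returns the partition with maximum relevance — on ties, the
    smallest K, i.e. the coarsest equally informative partition.
    """
    n = len(delta.node_labels)
    condensed = squareform(delta.values, checks=False)
    z = sch.linkage(condensed, method=linkage)
    counts: list[int] = []
    resolutions: list[float] = []
    relevances: list[float] = []
    partitions: list[Partition] = []
    for k in range(1, n + 1):
        # cut_tree yields exactly k clusters even under tied merge heights
        raw = sch.cut_tree(z, n_clusters=k)[:, 0]
        part = Partition.from_labels(raw, delta.node_labels)
        counts.append(part.n_clusters)
        resolutions.append(resolution(part))
        relevances.append(relevance(part))
        partitions.append(part)

    best = int(np.argmax(relevances))  # argmax takes the smallest K on ties
    curve = RelevanceCurve(
        cluster_counts=tuple(counts),
        resolutions=tuple(resolutions),
        relevances=tuple(relevances),
        partitions=tuple(partitions),
    )
    optimal = CvsPartition(
        partition=partitions[best],
        relevance=relevances[best],
        n_clusters=counts[best],
    )
    return optimal, curve
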