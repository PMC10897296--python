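"""Greedy modularity community detection on weighted mobility graphs.

Modularity compares the edge weight observed inside communities with its
expectation under a degree-preserving random null:

    Q = (1/2m) * sum_ij [ W_ij - k_i k_j / (2m) ] delta(c_i, c_j)

with ``m = (1/2) sum_ij W_ij`` and generalized degrees ``k_i = sum_j W_ij``.
The single-cluster partition scores exactly 0; the all-singleton partition
keeps only the degree-null terms, ``-sum_i (k_i/2m)^2``, which vanishes in
the sparse-graph limit; informative partitions score higher than both.

The optimizer is the classical greedy agglomeration (Clauset-Newman-Moore
lineage): start from singletons and repeatedly merge the community pair
with the largest modularity gain while a positive gain exists.  Since only
strictly positive gains are accepted, the final partition is the peak of
the greedy Q trajectory.  Ties are broken on the lexicographically
smallest community pair, making the result deterministic.

Modularity is defined for undirected graphs without self-loops, so the
directed current matrices are prepared by zeroing the diagonal and
symmetrizing, ``W = (X + X^T) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class Partition:
    """Assignment of labeled nodes to clusters.

    ``labels[i]`` is the cluster of node ``i``; cluster ids are contiguous
    integers from 0.
    """

    labels: np.ndarray
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if labels.ndim != 1 or len(labels) != len(self.node_labels):
            raise ValueError("labels must assign one cluster per node")
        uniq = np.unique(labels)
        if len(labels) and not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("cluster ids must be contiguous from 0")

    @classmethod
    def from_labels(
        cls, raw_labels: Sequence[int], node_labels: Sequence[str]
    ) -> "Partition":
        """Build a partition from arbitrary hashable cluster labels,
        renumbering them contiguously in order of first appearance."""
        seen: dict[object, int] = {}
        labels = np.empty(len(raw_labels), dtype=int)
        for i, r in enumerate(raw_labels):
            if r not in seen:
                seen[r] = len(seen)
            labels[i] = seen[r]
        return cls(labels=labels, node_labels=tuple(node_labels))

    @classmethod
    def singletons(cls, node_labels: Sequence[str]) -> "Partition":
        return cls(
            labels=np.arange(len(node_labels)),
            node_labels=tuple(node_labels),
        )

    @classmethod
    def single_cluster(cls, node_labels: Sequence[str]) -> "Partition":
        return cls(
            labels=np.zeros(len(node_labels), dtype=int),
            node_labels=tuple(node_labels),
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def _check_weights(weights: np.ndarray) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] != weights.shape[1]:
        raise ValueError("weights must be a square matrix")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.diag(weights) != 0):
        raise ValueError(
            "weights carry self-loops; strip the diagonal first "
            "(see prepare_gmc_input)"
        )
    if not np.array_equal(weights, weights.T):
        raise ValueError(
            "weights are asymmetric; symmetrize first (see prepare_gmc_input)"
        )
    return weights


def prepare_gmc_input(matrix) -> np.ndarray:
    """Turn a (possibly directed) flux or transition matrix into GMC weights.

    Zeros the diagonal (self-flux carries no community information) and
    symmetrizes, ``W = (X + X^T) / 2``.
    """
    values = getattr(matrix, "values", matrix)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("input must be a square matrix")
    if np.any(values < 0):
        raise ValueError("input must be nonnegative")
    w = (values + values.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


def modularity(weights: np.ndarray, partition: Partition) -> float:
    """Modularity Q of a partition of a weighted undirected graph.

    ``weights`` must be symmetric with a zero diagonal.  Q is invariant
    under global rescaling of the weights and equals 0 for the
    single-cluster partition.
    """
    weights = _check_weights(weights)
    n = weights.shape[0]
    if partition.n_nodes != n:
        raise ValueError("partition does not cover the weight matrix nodes")
    two_m = weights.sum()
    if two_m == 0:
        raise ValueError("graph has no edges")
    k = weights.sum(axis=1)
    same = partition.labels[:, None] == partition.labels[None, :]
    q = (weights[same].sum() - np.outer(k, k)[same].sum() / two_m) / two_m
    return float(q)


def greedy_modularity_partition(
    weights: np.ndarray, node_labels: Sequence[str] | None = None
) -> tuple[Partition, float]:
    """Greedy agglomerative modularity maximization (CNM lineage).

    Starts from singleton communities and repeatedly merges the pair with
    the largest modularity gain, as long as a strictly positive gain
    exists; ties go to the lexicographically smallest pair of community
    ids (a community is identified by its smallest member node index).
    Isolated (zero-degree) nodes never yield a positive gain and therefore
    remain singletons; disconnected components are never merged together.

    Returns the partition at the peak of the greedy Q trajectory together
    with its modularity.
    """
    weights = _check_weights(weights)
    n = weights.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if node_labels is None:
        node_labels = tuple(f"n{i:03d}" for i in range(n))
    two_m = weights.sum()
    if two_m == 0:
        raise ValueError("graph has no edges")

    # community state: id -> member set; e[a][b] = inter-community weight
    # fraction of 2m; a[c] = degree fraction of community c
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    e = {
        i: {
            j: weights[i, j] / two_m
            for j in range(n)
            if j != i and weights[i, j] > 0
        }
        for i in range(n)
    }
    deg = {i: weights[i].sum() / two_m for i in range(n)}

    while len(members) > 1:
        best_gain = 0.0
        best_pair: tuple[int, int] | None = None
        for a in sorted(members):
            for b in sorted(e[a]):
                if b <= a:
                    continue
                gain = 2.0 * (e[a][b] - deg[a] * deg[b])
                if gain > best_gain + 1e-15 or (
                    best_pair is not None
                    and abs(gain - best_gain) <= 1e-15
                    and (a, b) < best_pair
                ):
                    best_gain = gain
                    best_pair = (a, b)
        if best_pair is None or best_gain <= 0:
            break
        a, b = best_pair
        members[a] |= members.pop(b)
        deg[a] += deg.pop(b)
        e_b = e.pop(b)
        e[a].pop(b, None)
        e_b.pop(a, None)
        for c, w in e_b.items():
            e[c].pop(b, None)
            e[a][c] = e[a].get(c, 0.0) + w
            e[c][a] = e[a][c]

    raw = np.empty(n, dtype=int)
    for cid, nodes in members.items():
        for i in nodes:
            raw[i] = cid
    partition = Partition.from_labels(raw, node_labels)
    return partition, modularity(weights, partition)


def exhaustive_max_modularity(
    weights: np.ndarray, node_labels: Sequence[str] | None = None
) -> tuple[Partition, float]:
    """Exact maximum-modularity partition by exhaustive enumeration.

    Enumerates every set partition (Bell-number growth: feasible only for
    roughly 10 nodes or fewer) and returns the best.  Serves as the
    independent optimum against which the greedy heuristic is scored.
    """
    weights = _check_weights(weights)
    n = weights.shape[0]
    if n > 12:
        raise ValueError("exhaustive search is infeasible beyond ~12 nodes")
    if node_labels is None:
        node_labels = tuple(f"n{i:03d}" for i in range(n))

    def partitions_of(items: list[int]):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions_of(rest):
            for i in range(len(smaller)):
                yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1 :]
            yield [[first]] + smaller

    best_q = -np.inf
    best: Partition | None = None
    for blocks in partitions_of(list(range(n))):
        raw = np.empty(n, dtype=int)
        for cid, block in enumerate(blocks):
            for i in block:
                raw[i] = cid
        p = Partition.from_labels(raw, node_labels)
        q = modularity(weights, p)
        if q > best_q:
            best_q, best = q, p
    assert best is not None
    return best, float(best_q)
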