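"""Variation of Information between partitions of the same node set.

VI[C,C'] = 2 H[C,C'] - H[C] - H[C'], with H[C,C'] the Shannon entropy of
the overlap table n_ij = |C_i ∩ C'_j| and H[C] the entropy of the cluster
sizes (natural logarithms; 0*ln 0 = 0).  VI is a metric on partitions,
ranging from 0 (identical) to ln N (all singletons vs one cluster);
dividing by ln N gives a 0-1 scale independent of the log base.
"""

from __future__ import annotations

import numpy as np

from .gmc import Partition


def _aligned(a: Partition, b: Partition) -> tuple[np.ndarray, np.ndarray]:
    """Return the two label arrays aligned on a common node ordering."""
    if a.node_labels == b.node_labels:
        return a.labels, b.labels
    if set(a.node_labels) != set(b.node_labels):
        raise ValueError("partitions are over different node sets")
    index = {name: i for i, name in enumerate(b.node_labels)}
    perm = np.array([index[name] for name in a.node_labels])
    return a.labels, b.labels[perm]


def _contingency(a: Partition, b: Partition) -> np.ndarray:
    la, lb = _aligned(a, b)
    table = np.zeros((a.n_clusters, b.n_clusters))
    np.add.at(table, (la, lb), 1.0)
    return table


def _entropy(probs: np.ndarray) -> float:
    probs = probs[probs > 0]
    return float(-np.sum(probs * np.log(probs)))


def entropy(partition: Partition) -> float:
    """Shannon entropy (natural log) of the cluster-size distribution."""
    return _entropy(partition.cluster_sizes() / partition.n_nodes)


def joint_entropy(a: Partition, b: Partition) -> float:
    """Joint entropy of the overlap table of two partitions.

    Equals H[C] when the partitions coincide and ln N when either
    partition is all singletons.
    """
    n = a.n_nodes
    return _entropy(_contingency(a, b).ravel() / n)


def mutual_information(a: Partition, b: Partition) -> float:
    """Mutual information I[C,C'] = H[C] + H[C'] - H[C,C'] (natural log)."""
    return entropy(a) + entropy(b) - joint_entropy(a, b)


def variation_of_information(a: Partition, b: Partition) -> float:
    """VI[C,C'] = 2 H[C,C'] - H[C] - H[C']; in [0, ln N]."""
    return 2.0 * joint_entropy(a, b) - entropy(a) - entropy(b)


def normalized_vi(a: Partition, b: Partition) -> float:
    """VI divided by ln N: 0 for identical partitions, 1 between the
    all-singleton and the single-cluster partition."""
    n = a.n_nodes
    if n < 2:
        raise ValueError("normalized VI needs at least 2 objects")
    return variation_of_information(a, b) / np.log(n)
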