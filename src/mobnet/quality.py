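"""Perron-Frobenius quality assessment of anonymized mobility matrices.

The mean transition matrix of a movement panel generates a Markov jump
process over the nodes.  If the panel is a faithful (if thinned) sample of
the true mobility, the stationary density of that process must agree with
an independent census of the node populations.  This module computes the
stationary density, compares density vectors, and measures how progressive
pruning of weak links — a proxy for the information loss of anonymization
thresholds — degrades the agreement until strong connectivity, and with it
the Perron-Frobenius stationary state, is lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

from .matrices import TransitionMatrix
from .synthetic import MovementPanel

logger = logging.getLogger(__name__)

#: Residual tolerance on the stationary equation ``rho P = rho``.
STATIONARY_TOL = 1e-10

Source = Literal["census", "user_counts", "stationary"]


@dataclass(frozen=True)
class DensityVector:
    """Nonnegative unit-sum population density over labeled nodes.

    ``raw_counts`` optionally keeps the unnormalized counts (e.g. census
    populations) the density was derived from.
    """

    values: np.ndarray
    node_labels: tuple[str, ...]
    source: Source
    raw_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if values.ndim != 1 or len(values) != len(self.node_labels):
            raise ValueError("values must be one entry per node label")
        if np.any(values < 0):
            raise ValueError("density entries must be nonnegative")
        if abs(values.sum() - 1.0) > 1e-12:
            raise ValueError(f"density sums to {values.sum()!r}, not 1")
        if self.raw_counts is not None:
            raw = np.asarray(self.raw_counts, dtype=float)
            if raw.shape != values.shape:
                raise ValueError("raw_counts shape mismatch")
            object.__setattr__(self, "raw_counts", raw)


@dataclass(frozen=True)
class PruningReport:
    """Result of a pruning-sensitivity sweep.

    For each cutoff: whether the pruned graph is still strongly connected,
    the stationary density (absent once connectivity is lost), and the RMS
    deviation of the stationary density from the reference (NaN once lost).
    ``breaking_cutoff`` is the smallest cutoff at which strong connectivity
    breaks, or None if it never does.
    """

    cutoffs: tuple[float, ...]
    deviations: tuple[float, ...]
    strongly_connected: tuple[bool, ...]
    stationary_vectors: tuple[DensityVector | None, ...]
    breaking_cutoff: float | None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly increasing")


def density_from_counts(
    counts: Sequence[float] | np.ndarray,
    node_labels: Sequence[str],
    source: Source = "census",
) -> DensityVector:
    """Normalize per-node counts to a unit-sum density vector."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    return DensityVector(
        values=counts / total,
        node_labels=tuple(node_labels),
        source=source,
        raw_counts=counts,
    )


def user_density(panel: MovementPanel) -> DensityVector:
    """Density of time-averaged panel user counts, one entry per node."""
    mean_counts = panel.node_counts.mean(axis=0)
    return density_from_counts(
        mean_counts, panel.node_labels, source="user_counts"
    )


def user_fraction(panel: MovementPanel, census: DensityVector) -> np.ndarray:
    """Per-node fraction of the census population visible in the panel.

    Returns ``mean_h(node_counts[h, i]) / census_counts[i]``; for a
    representative panel this fraction should be roughly homogeneous across
    nodes (3-7 % in the emulated data source).
    """
    if census.node_labels != panel.node_labels:
        raise ValueError("census node labels do not match the panel")
    if census.raw_counts is None:
        raise ValueError("census density must carry raw population counts")
    if np.any(census.raw_counts <= 0):
        raise ValueError("census populations must be positive")
    return panel.node_counts.mean(axis=0) / census.raw_counts


def connectivity_check(
    matrix: TransitionMatrix | np.ndarray,
) -> tuple[Literal["strongly", "weakly", "disconnected"], list[list[int]]]:
    """Classify the connectivity of the positive-entry digraph.

    Self-loops are ignored; the classification is by strongly-connected
    component decomposition, with a fallback to weak connectivity.  Returns
    the classification and the list of strongly connected components (as
    node index lists, sorted).
    """
    values = matrix.values if isinstance(matrix, TransitionMatrix) else matrix
    adj = np.asarray(values) > 0
    np.fill_diagonal(adj, False)
    n_strong, strong_labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong"
    )
    components = [
        sorted(np.flatnonzero(strong_labels == c).tolist())
        for c in range(n_strong)
    ]
    components.sort()
    if n_strong == 1:
        return "strongly", components
    n_weak, _ = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="weak"
    )
    if n_weak == 1:
        return "weakly", components
    return "disconnected", components


def stationary_density(matrix: TransitionMatrix) -> DensityVector:
    """Perron-Frobenius stationary density of a transition matrix.

    For a strongly connected, aperiodic row-stochastic matrix the leading
    eigenvalue is exactly 1 and its left eigenvector, normalized to sum 1,
    is the unique stationary state of the induced Markov jump process; any
    initial density converges to it.  Aperiodicity is guaranteed here by a
    positive diagonal (diagonally dominant mobility matrices always have
    one) and asserted as a precondition.

    Raises
    ------
    ValueError
        If the matrix is not strongly connected (the error names the
        strongly connected components) or has an all-zero diagonal.
    """
    kind, components = connectivity_check(matrix)
    if kind != "strongly":
        raise ValueError(
            f"matrix is {kind}, not strongly connected; "
            f"strongly connected components: {components}"
        )
    if not np.any(np.diag(matrix.values) > 0):
        raise ValueError(
            "no positive diagonal entry: aperiodicity not guaranteed"
        )
    eigvals, left = scipy.linalg.eig(matrix.values, left=True, right=False)
    idx = int(np.argmin(np.abs(eigvals - 1.0)))
    if abs(eigvals[idx] - 1.0) > 1e-9:
        raise ValueError(
            f"leading eigenvalue {eigvals[idx]!r} is not 1; "
            "matrix is not stochastic enough"
        )
    rho = np.real(left[:, idx])
    rho = rho / rho.sum()  # fixes the eigenvector sign as well
    if rho.min() < -1e-12:
        raise ValueError("stationary vector has negative entries")
    rho = np.clip(rho, 0.0, None)
    rho = rho / rho.sum()
    residual = np.max(np.abs(rho @ matrix.values - rho))
    if residual > STATIONARY_TOL:
        raise ValueError(f"stationary residual {residual} above tolerance")
    return DensityVector(
        values=rho, node_labels=matrix.node_labels, source="stationary"
    )


def power_iteration_density(
    matrix: TransitionMatrix,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> DensityVector:
    """Stationary density by forward propagation of the uniform density.

    Independent route to the same quantity as :func:`stationary_density`:
    repeatedly applies ``rho <- rho P`` until the max-norm update falls
    below ``tol``.  Convergence is guaranteed for strongly connected
    aperiodic matrices.
    """
    n = matrix.n_nodes
    rho = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = rho @ matrix.values
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - rho)) < tol:
            rho = nxt
            break
        rho = nxt
    else:
        raise RuntimeError("power iteration did not converge")
    return DensityVector(
        values=rho, node_labels=matrix.node_labels, source="stationary"
    )


def prune_and_renormalize(
    matrix: TransitionMatrix,
    cutoff: float,
    prune_diagonal: bool = False,
) -> TransitionMatrix:
    """Zero entries below ``cutoff`` and renormalize each surviving row.

    Models the information loss of anonymization: links carrying a
    transition probability below the cutoff are dropped and the remaining
    probabilities are rescaled so the matrix stays stochastic.  Diagonal
    entries are exempt by default — pruning targets *links*, and self-stay
    probabilities sit far above any realistic cutoff; pass
    ``prune_diagonal=True`` to override.

    Raises
    ------
    ValueError
        If a row is entirely zeroed (it cannot be renormalized).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    values = matrix.values.copy()
    mask = values < cutoff
    if not prune_diagonal:
        np.fill_diagonal(mask, False)
    values[mask] = 0.0
    totals = values.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        names = [matrix.node_labels[i] for i in dead]
        raise ValueError(f"pruning at {cutoff} zeroed entire rows: {names}")
    values /= totals[:, None]
    return TransitionMatrix(
        values=values,
        node_labels=matrix.node_labels,
        time_tag=matrix.time_tag,
        window=matrix.window,
    )


def deviation(
    rho: DensityVector, reference: DensityVector
) -> tuple[float, np.ndarray]:
    """Signed per-node deviation from a reference density, plus its RMS.

    Returns ``(rms, per_node)`` with ``per_node[i] = rho_i - ref_i`` and
    ``rms = sqrt(mean(per_node**2))``, the aggregate used to track how far
    a stationary density drifts from the census.
    """
    if rho.node_labels != reference.node_labels:
        raise ValueError("node labels of the two densities do not match")
    per_node = rho.values - reference.values
    return float(np.sqrt(np.mean(per_node**2))), per_node


def pruning_sweep(
    matrix: TransitionMatrix,
    cutoffs: Sequence[float],
    reference: DensityVector,
    prune_diagonal: bool = False,
) -> PruningReport:
    """Progressive pruning up to (and past) the connectivity breaking point.

    For each cutoff, in increasing order: prune and renormalize, test
    strong connectivity, and — while it holds — compute the stationary
    density and its RMS deviation from ``reference``.  Once strong
    connectivity is lost the stationary state no longer exists and no
    vector is reported; losing it is a *result* of the sweep, not an error.
    """
    cutoffs = tuple(float(c) for c in cutoffs)
    deviations: list[float] = []
    connected: list[bool] = []
    vectors: list[DensityVector | None] = []
    breaking: float | None = None
    for cutoff in cutoffs:
        pruned = prune_and_renormalize(
            matrix, cutoff, prune_diagonal=prune_diagonal
        )
        kind, _ = connectivity_check(pruned)
        strongly = kind == "strongly"
        connected.append(strongly)
        if strongly:
            rho = stationary_density(pruned)
            rms, _ = deviation(rho, reference)
            vectors.append(rho)
            deviations.append(rms)
        else:
            if breaking is None:
                breaking = cutoff
            vectors.append(None)
            deviations.append(float("nan"))
            logger.info(
                "strong connectivity lost at cutoff %g (%s)", cutoff, kind
            )
    return PruningReport(
        cutoffs=cutoffs,
        deviations=tuple(deviations),
        strongly_connected=tuple(connected),
        stationary_vectors=tuple(vectors),
        breaking_cutoff=breaking,
    )
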