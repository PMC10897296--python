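"""Stochastic transition matrices from origin-destination movement panels.

A movement panel records, for every 8-hour slot ``h``, the number of users
``n^h_ij`` moving from node ``i`` to node ``j``.  Pooling the counts over a
time window and normalizing each row yields a row-stochastic *transition
matrix*: entry ``(i, j)`` is the probability that a user located in node
``i`` at the start of the window is observed in node ``j``.

Three window choices are supported:

* a single calendar day (``epsilon=0 h``, ``delta=24 h``),
* a weekly rolling window centred on a day (``epsilon=72 h``,
  ``delta=96 h``, i.e. the 3 days before through the 3 days after), which
  removes day/night and weekday/weekend seasonality,
* the whole observation period (the *mean* transition matrix).

Counts are pooled *before* normalization: the matrix of a union of disjoint
windows equals the matrix of the pooled counts, not the average of the two
window matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .synthetic import HOURS_PER_SLOT, SLOTS_PER_DAY, MovementPanel

logger = logging.getLogger(__name__)

#: Tolerance on row sums of a stochastic matrix.
ROW_SUM_TOL = 1e-12

#: Window (epsilon hours, delta hours) for single-day matrices.
DAILY_WINDOW = (0, 24)

#: Window for weekly rolled-average matrices: 3 days before through
#: 3 days after the reference day, half-open on the right.
WEEKLY_WINDOW = (72, 96)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix over labeled nodes with a time tag.

    Parameters
    ----------
    values
        ``(N, N)`` array; every row sums to 1 within ``ROW_SUM_TOL`` and all
        entries lie in ``[0, 1]``.
    node_labels
        Node names, one per row/column.
    time_tag
        Day index for daily matrices, or a string such as ``"mean"``.
    window
        ``(epsilon_hours, delta_hours)`` of the pooling window, if any.
    """

    values: np.ndarray
    node_labels: tuple[str, ...]
    time_tag: int | str = "mean"
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        n = len(self.node_labels)
        if values.shape != (n, n):
            raise ValueError(
                f"values shape {values.shape} does not match {n} node labels"
            )
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        row_sums = values.sum(axis=1)
        if not np.allclose(row_sums, 1.0, rtol=0, atol=ROW_SUM_TOL):
            worst = int(np.argmax(np.abs(row_sums - 1.0)))
            raise ValueError(
                f"row {worst} ({self.node_labels[worst]}) sums to "
                f"{row_sums[worst]!r}, not 1"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass(frozen=True)
class MatrixSeries:
    """Ordered daily sequence of transition matrices on a common node set."""

    matrices: tuple[TransitionMatrix, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrices", tuple(self.matrices))
        if not self.matrices:
            raise ValueError("a matrix series cannot be empty")
        labels = self.matrices[0].node_labels
        window = self.matrices[0].window
        for m in self.matrices[1:]:
            if m.node_labels != labels:
                raise ValueError("inconsistent node labels across the series")
            if m.window != window:
                raise ValueError("inconsistent windows across the series")

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self) -> Iterator[TransitionMatrix]:
        return iter(self.matrices)

    def __getitem__(self, i: int) -> TransitionMatrix:
        return self.matrices[i]

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.matrices[0].node_labels

    def stacked(self) -> np.ndarray:
        """Return the series as a ``(T, N, N)`` array."""
        return np.stack([m.values for m in self.matrices])


def _normalize_rows(
    counts: np.ndarray, node_labels: Sequence[str], context: str
) -> np.ndarray:
    """Row-normalize pooled counts; empty rows become absorbing self-loops.

    A node with no recorded movers in the window gets ``P_ii = 1`` so that
    the matrix stays stochastic; the event is logged for quality control.
    """
    totals = counts.sum(axis=1, dtype=float)
    zero = totals == 0
    if np.any(zero):
        names = [node_labels[i] for i in np.flatnonzero(zero)]
        logger.warning(
            "%s: nodes %s have no movers in the window; "
            "assigned absorbing self-loops",
            context,
            names,
        )
    values = np.zeros(counts.shape, dtype=float)
    nz = ~zero
    values[nz] = counts[nz] / totals[nz, None]
    values[zero, zero.nonzero()[0]] = 1.0
    # exact re-normalization guards float drift in long count sums
    values[nz] /= values[nz].sum(axis=1)[:, None]
    return values


def transition_matrix(
    panel: MovementPanel,
    day: int,
    epsilon_hours: float,
    delta_hours: float,
) -> TransitionMatrix:
    """Build the transition matrix for the window ``[day - eps, day + delta)``.

    Counts of all 8-hour slots whose start falls in the half-open window
    ``[24*day - epsilon_hours, 24*day + delta_hours)`` are pooled and each
    row is normalized to sum 1.

    Raises
    ------
    ValueError
        If the window contains no panel slot.
    """
    lo = 24.0 * day - epsilon_hours
    hi = 24.0 * day + delta_hours
    slot_starts = panel.slots * HOURS_PER_SLOT
    in_window = (slot_starts >= lo) & (slot_starts < hi)
    if not np.any(in_window):
        raise ValueError(
            f"window [{lo}, {hi}) hours contains no slot of the panel "
            f"(panel spans [{slot_starts[0]}, {slot_starts[-1] + HOURS_PER_SLOT}))"
        )
    counts = panel.counts[in_window].sum(axis=0)
    values = _normalize_rows(counts, panel.node_labels, f"day {day}")
    return TransitionMatrix(
        values=values,
        node_labels=panel.node_labels,
        time_tag=day,
        window=(float(epsilon_hours), float(delta_hours)),
    )


def daily_series(
    panel: MovementPanel,
    mode: Literal["daily", "weekly_rolled"] = "weekly_rolled",
    truncate_edges: bool = True,
) -> MatrixSeries:
    """Build the daily time series of transition matrices.

    ``mode="daily"`` pools each calendar day on its own
    (``epsilon=0, delta=24 h``); ``mode="weekly_rolled"`` pools the 3 days
    before through the 3 days after each day (``epsilon=72, delta=96 h``),
    which suppresses day/night and weekday/weekend seasonality.

    Parameters
    ----------
    truncate_edges
        In weekly-rolled mode the first and last 3 days have incomplete
        windows.  If true (default) they are built from the truncated
        windows; if false they are dropped and the series covers interior
        days only.
    """
    if mode == "daily":
        eps, delta = DAILY_WINDOW
        if panel.n_days < 1:
            raise ValueError("panel must span at least one day")
        days = range(panel.n_days)
    elif mode == "weekly_rolled":
        eps, delta = WEEKLY_WINDOW
        if panel.n_days < 7:
            raise ValueError(
                f"weekly rolled series needs >= 7 days, panel has {panel.n_days}"
            )
        if truncate_edges:
            days = range(panel.n_days)
        else:
            days = range(3, panel.n_days - 3)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    first_day = int(panel.slots[0]) // SLOTS_PER_DAY
    return MatrixSeries(
        tuple(
            transition_matrix(panel, first_day + d, eps, delta) for d in days
        )
    )


def mean_transition_matrix(panel: MovementPanel) -> TransitionMatrix:
    """Mean transition matrix over the whole observation period.

    All slots of the panel are pooled before row normalization, so the
    result weights every recorded move equally (it is *not* the average of
    the daily matrices).
    """
    counts = panel.counts.sum(axis=0)
    values = _normalize_rows(counts, panel.node_labels, "whole period")
    return TransitionMatrix(
        values=values, node_labels=panel.node_labels, time_tag="mean"
    )


def p_out(matrix: TransitionMatrix) -> float:
    """Mean probability of leaving one's node: ``1 - trace(P)/N``.

    Averages the per-node departure probabilities ``1 - P_ii``; 0 for the
    identity matrix (nobody moves), close to 1 when the diagonal is empty.
    """
    n = matrix.n_nodes
    return float(1.0 - np.trace(matrix.values) / n)
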