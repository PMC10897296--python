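"""Delimited-text serialization of panels, matrices, densities, partitions.

All formats are plain text: movement panels as long-format CSV (one row per
slot/origin/destination with a nonzero count, plus a node-count CSV that
also fixes the slot grid), matrices as labeled CSV tables, partitions and
densities as two-column CSVs, generator configs as YAML, pruning reports as
JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cvs import RelevanceCurve
from .gmc import Partition
from .matrices import MatrixSeries, TransitionMatrix
from .quality import DensityVector, PruningReport, density_from_counts
from .synthetic import HOURS_PER_SLOT, GeneratorConfig, MovementPanel

#: Calendar origin of slot 0 when writing ISO timestamps.
PANEL_EPOCH = pd.Timestamp("2020-01-01 00:00:00")


def _slot_times(slots: np.ndarray) -> pd.DatetimeIndex:
    return PANEL_EPOCH + pd.to_timedelta(slots * HOURS_PER_SLOT, unit="h")


def write_panel(
    panel: MovementPanel, counts_path: str | Path, node_counts_path: str | Path
) -> None:
    """Write a panel as two CSVs: movement counts and per-node user counts.

    The movement CSV lists only nonzero counts; the node-count CSV lists
    every (slot, node) pair and therefore fixes the slot grid and the node
    label set on read-back.
    """
    times = _slot_times(panel.slots)
    h, i, j = np.nonzero(panel.counts)
    pd.DataFrame(
        {
            "slot_start_iso": times[h].astype(str),
            "origin": np.array(panel.node_labels)[i],
            "destination": np.array(panel.node_labels)[j],
            "count": panel.counts[h, i, j],
        }
    ).to_csv(counts_path, index=False)
    hh, ii = np.indices(panel.node_counts.shape)
    pd.DataFrame(
        {
            "slot_start_iso": times[hh.ravel()].astype(str),
            "node": np.array(panel.node_labels)[ii.ravel()],
            "count": panel.node_counts.ravel(),
        }
    ).to_csv(node_counts_path, index=False)


def read_panel(
    counts_path: str | Path, node_counts_path: str | Path
) -> MovementPanel:
    """Read a panel written by :func:`write_panel`."""
    node_df = pd.read_csv(node_counts_path)
    times = pd.to_datetime(node_df["slot_start_iso"].unique())
    slots = np.array(
        sorted((times - PANEL_EPOCH) // pd.Timedelta(hours=HOURS_PER_SLOT))
    )
    slot_index = {s: k for k, s in enumerate(slots)}
    labels = tuple(sorted(node_df["node"].unique()))
    node_index = {name: k for k, name in enumerate(labels)}

    node_counts = np.zeros((len(slots), len(labels)), dtype=int)
    s = (
        (pd.to_datetime(node_df["slot_start_iso"]) - PANEL_EPOCH)
        // pd.Timedelta(hours=HOURS_PER_SLOT)
    ).map(slot_index)
    node_counts[s, node_df["node"].map(node_index)] = node_df["count"]

    counts = np.zeros((len(slots), len(labels), len(labels)), dtype=int)
    move_df = pd.read_csv(counts_path)
    if len(move_df):
        s = (
            (pd.to_datetime(move_df["slot_start_iso"]) - PANEL_EPOCH)
            // pd.Timedelta(hours=HOURS_PER_SLOT)
        ).map(slot_index)
        counts[
            s,
            move_df["origin"].map(node_index),
            move_df["destination"].map(node_index),
        ] = move_df["count"]
    return MovementPanel(
        counts=counts, node_counts=node_counts, slots=slots, node_labels=labels
    )


def write_matrix(matrix, path: str | Path) -> None:
    """Write a transition/current/distance matrix as a labeled CSV table."""
    pd.DataFrame(
        matrix.values, index=matrix.node_labels, columns=matrix.node_labels
    ).to_csv(path)


def read_matrix_values(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Read a labeled CSV table back into values and node labels."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)


def read_transition_matrix(
    path: str | Path, time_tag: int | str = "mean"
) -> TransitionMatrix:
    values, labels = read_matrix_values(path)
    return TransitionMatrix(values=values, node_labels=labels, time_tag=time_tag)


def write_series(series: MatrixSeries, path: str | Path) -> None:
    """Write a matrix series as a long-format CSV (day, origin, destination,
    value)."""
    frames = []
    labels = np.array(series.node_labels)
    for m in series:
        i, j = np.indices(m.values.shape)
        frames.append(
            pd.DataFrame(
                {
                    "day": m.time_tag,
                    "origin": labels[i.ravel()],
                    "destination": labels[j.ravel()],
                    "value": m.values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series(path: str | Path) -> MatrixSeries:
    df = pd.read_csv(path)
    labels = tuple(sorted(df["origin"].unique()))
    matrices = []
    for day, sub in df.groupby("day", sort=True):
        table = sub.pivot(index="origin", columns="destination", values="value")
        table = table.reindex(index=labels, columns=labels)
        matrices.append(
            TransitionMatrix(
                values=table.to_numpy(dtype=float),
                node_labels=labels,
                time_tag=int(day),
            )
        )
    return MatrixSeries(tuple(matrices))


def write_census(census: DensityVector, path: str | Path) -> None:
    if census.raw_counts is None:
        raise ValueError("census density carries no raw counts")
    pd.DataFrame(
        {"node": census.node_labels, "population": census.raw_counts}
    ).to_csv(path, index=False)


def read_census(path: str | Path) -> DensityVector:
    """Read a (node, population) CSV into a census density vector."""
    df = pd.read_csv(path)
    return density_from_counts(
        df["population"].to_numpy(dtype=float),
        tuple(df["node"].astype(str)),
        source="census",
    )


def write_partition(partition: Partition, path: str | Path) -> None:
    pd.DataFrame(
        {"node": partition.node_labels, "cluster": partition.labels}
    ).to_csv(path, index=False)


def read_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path)
    return Partition.from_labels(
        df["cluster"].tolist(), tuple(df["node"].astype(str))
    )


def write_relevance_curve(curve: RelevanceCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "n_clusters": curve.cluster_counts,
            "resolution": curve.resolutions,
            "relevance": curve.relevances,
        }
    ).to_csv(path, index=False)


def write_pruning_report(report: PruningReport, path: str | Path) -> None:
    payload = {
        "cutoffs": list(report.cutoffs),
        "deviations": [
            None if np.isnan(d) else d for d in report.deviations
        ],
        "strongly_connected": list(report.strongly_connected),
        "breaking_cutoff": report.breaking_cutoff,
        "stationary_vectors": [
            None if v is None else dict(zip(v.node_labels, v.values.tolist()))
            for v in report.stationary_vectors
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_config(config: GeneratorConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def read_config(path: str | Path) -> GeneratorConfig:
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("sampling_fraction_range", "population_range", "seasonal_amplitudes"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if raw.get("populations") is not None:
        raw["populations"] = tuple(raw["populations"])
    if raw.get("lockdown_periods") is not None:
        raw["lockdown_periods"] = tuple(
            tuple(p) for p in raw["lockdown_periods"]
        )
    return GeneratorConfig(**raw)
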