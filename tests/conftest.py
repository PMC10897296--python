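"""Shared fixtures: small synthetic panels and constructed matrices."""

from __future__ import annotations

import numpy as np
import pytest

import mobnet as mn
from mobnet.synthetic import SLOTS_PER_DAY


def make_panel_from_counts(counts: np.ndarray) -> mn.MovementPanel:
    """Wrap explicit (slots, N, N) count arrays into a panel."""
    counts = np.asarray(counts)
    h, n, _ = counts.shape
    assert h % SLOTS_PER_DAY == 0
    return mn.MovementPanel(
        counts=counts,
        node_counts=counts.sum(axis=2),
        slots=np.arange(h),
        node_labels=tuple(f"n{i:03d}" for i in range(n)),
    )


def make_transition(values, labels=None, **kw) -> mn.TransitionMatrix:
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = tuple(f"n{i:03d}" for i in range(values.shape[0]))
    return mn.TransitionMatrix(values=values, node_labels=labels, **kw)


def stochastic_from_offdiag(offdiag: np.ndarray) -> mn.TransitionMatrix:
    """Complete an off-diagonal flux matrix into a stochastic matrix."""
    v = np.asarray(offdiag, dtype=float).copy()
    np.fill_diagonal(v, 0.0)
    np.fill_diagonal(v, 1.0 - v.sum(axis=1))
    assert np.all(np.diag(v) >= 0)
    return make_transition(v / v.sum(axis=1, keepdims=True))


def two_scale_mobility(seed: int = 0, n_remote: int = 3):
    """Hierarchical mobility matrix: sub-blocks within super-blocks, plus
    remote weakly-attached nodes.

    Off-diagonal transition probabilities come in three tiers — strong
    within sub-blocks, intermediate within super-blocks, weak everywhere
    else (including all links of the remote nodes) — with a small
    multiplicative jitter breaking linkage ties.  Returns the off-diagonal
    probabilities plus the sub-block and super-block ground truths.
    """
    sub_sizes = [2, 3, 4, 3, 4, 5, 2, 5, 4, 6]
    super_of_sub = [0, 0, 0, 1, 1, 1, 2, 2, 3, 3]
    sub = np.repeat(np.arange(len(sub_sizes)), sub_sizes)
    sup = np.array([super_of_sub[s] for s in sub])
    n_core = len(sub)
    n = n_core + n_remote
    tiers = np.full((n, n), 0.004)
    tiers[:n_core, :n_core] = np.where(
        sub[:, None] == sub[None, :],
        0.03,
        np.where(sup[:, None] == sup[None, :], 0.009, 0.004),
    )
    rng = np.random.default_rng(seed)
    off = tiers * rng.uniform(0.9, 1.1, (n, n))
    np.fill_diagonal(off, 0.0)
    sub_truth = np.concatenate([sub, len(sub_sizes) + np.arange(n_remote)])
    sup_truth = np.concatenate([sup, len(super_of_sub) + np.arange(n_remote)])
    return off, sub_truth, sup_truth


@pytest.fixture(scope="session")
def small_config() -> mn.GeneratorConfig:
    return mn.GeneratorConfig(n_nodes=10, n_days=14, seed=1)


@pytest.fixture(scope="session")
def small_panel(small_config):
    panel, truth = mn.generate_panel(small_config)
    return panel, truth


@pytest.fixture(scope="session")
def small_mean(small_panel) -> mn.TransitionMatrix:
    panel, _ = small_panel
    return mn.mean_transition_matrix(panel)


@pytest.fixture(scope="session")
def small_census(small_panel) -> mn.DensityVector:
    panel, truth = small_panel
    return mn.density_from_counts(
        truth.populations, panel.node_labels, source="census"
    )


@pytest.fixture(scope="session")
def lockdown_panel():
    """Panel with a 10-day lockdown (days 10-19) at suppression 0.3."""
    cfg = mn.GeneratorConfig(
        n_nodes=10,
        n_days=30,
        seed=7,
        lockdown_periods=((10, 20),),
        lockdown_offdiag_factor=0.3,
    )
    panel, truth = mn.generate_panel(cfg)
    return mn.apply_privacy_censoring(panel, cfg.censoring_threshold), truth
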