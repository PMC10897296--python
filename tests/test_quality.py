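"""Stationary densities, connectivity, pruning sensitivity."""

from __future__ import annotations

import numpy as np
import pytest

import mobnet as mn

from .conftest import make_transition


class TestDensity:
    def test_uniform_counts(self):
        d = mn.density_from_counts([1, 1, 1, 1], list("abcd"))
        assert np.allclose(d.values, 0.25)

    def test_direct_normalization(self):
        d = mn.density_from_counts([2, 1, 1], list("abc"))
        assert np.allclose(d.values, [0.5, 0.25, 0.25])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mn.density_from_counts([0, 0], list("ab"))

    def test_user_fraction_identity(self, small_panel):
        panel, _ = small_panel
        mean_counts = panel.node_counts.mean(axis=0)
        census = mn.density_from_counts(mean_counts, panel.node_labels)
        assert np.allclose(mn.user_fraction(panel, census), 1.0)

    def test_user_density_matches_node_counts(self, small_panel):
        panel, _ = small_panel
        d = mn.user_density(panel)
        expected = panel.node_counts.mean(axis=0)
        assert np.allclose(d.values, expected / expected.sum())
        assert d.source == "user_counts"


class TestStationary:
    def test_two_node_hand_solution(self):
        # rho (0.9,0.1)/(0.2,0.8): balance gives rho = (2/3, 1/3)
        m = make_transition([[0.9, 0.1], [0.2, 0.8]])
        rho = mn.stationary_density(m)
        assert np.allclose(rho.values, [2 / 3, 1 / 3], atol=1e-12)

    def test_doubly_stochastic_gives_uniform(self):
        v = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        rho = mn.stationary_density(make_transition(v))
        assert np.allclose(rho.values, 1 / 3, atol=1e-12)

    def test_leading_eigenvalue_is_one(self, small_mean):
        eigvals = np.linalg.eigvals(small_mean.values)
        assert np.max(np.abs(eigvals)) == pytest.approx(1.0, abs=1e-12)

    def test_power_iteration_agrees_with_eigensolver(self, small_mean):
        rho = mn.stationary_density(small_mean)
        pi = mn.power_iteration_density(small_mean)
        assert np.max(np.abs(rho.values - pi.values)) < 1e-8

    def test_any_density_converges_forward(self, small_mean):
        rng = np.random.default_rng(2)
        rho_star = mn.stationary_density(small_mean).values
        start = rng.dirichlet(np.ones(small_mean.n_nodes))
        for _ in range(2000):
            start = start @ small_mean.values
        assert np.max(np.abs(start - rho_star)) < 1e-8

    def test_recovers_latent_stationary_density(self):
        """The stationary density of the empirical mean matrix converges to
        the stationary density of the latent regime mixture (parameter
        recovery under unbiased sampling)."""
        cfg = mn.GeneratorConfig(n_nodes=10, n_days=60, seed=9,
                                 sampling_fraction_range=(0.05, 0.05))
        panel, truth = mn.generate_panel(cfg)
        rho = mn.stationary_density(mn.mean_transition_matrix(panel))
        latent = mn.TransitionMatrix(
            truth.expected_mean_matrix(), panel.node_labels
        )
        ref = mn.stationary_density(latent)
        assert np.max(np.abs(rho.values - ref.values)) < 1e-3

    def test_not_strongly_connected_raises_with_components(self):
        v = np.array([[0.5, 0.5, 0.0], [0.0, 1.0, 0.0], [0.0, 0.5, 0.5]])
        with pytest.raises(ValueError, match="strongly connected components"):
            mn.stationary_density(make_transition(v))


class TestConnectivity:
    def test_identity_is_disconnected(self):
        kind, comps = mn.connectivity_check(make_transition(np.eye(3)))
        assert kind == "disconnected"
        assert comps == [[0], [1], [2]]

    def test_directed_cycle_is_strong(self):
        v = np.array([[0.5, 0.5, 0], [0, 0.5, 0.5], [0.5, 0, 0.5]])
        kind, comps = mn.connectivity_check(make_transition(v))
        assert kind == "strongly"
        assert comps == [[0, 1, 2]]

    def test_one_way_chain_is_weak(self):
        v = np.array([[0.5, 0.5, 0], [0, 0.5, 0.5], [0, 0, 1.0]])
        kind, _ = mn.connectivity_check(make_transition(v))
        assert kind == "weakly"


class TestPruning:
    def test_zero_cutoff_is_identity(self, small_mean):
        out = mn.prune_and_renormalize(small_mean, 0.0)
        assert np.allclose(out.values, small_mean.values)

    def test_hand_renormalization(self):
        m = make_transition([[0.9, 0.0004, 0.0996], [0.1, 0.8, 0.1],
                             [0.1, 0.1, 0.8]])
        out = mn.prune_and_renormalize(m, 0.001)
        assert out.values[0, 1] == 0.0
        assert np.allclose(
            out.values[0], [0.9 / 0.9996, 0.0, 0.0996 / 0.9996]
        )
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-12)

    def test_diagonal_exempt_by_default(self):
        m = make_transition([[0.05, 0.95], [0.95, 0.05]])
        out = mn.prune_and_renormalize(m, 0.1)
        assert np.all(np.diag(out.values) > 0)

    def test_fully_zeroed_row_raises(self):
        m = make_transition([[0.05, 0.95], [0.95, 0.05]])
        with pytest.raises(ValueError, match="zeroed entire rows"):
            mn.prune_and_renormalize(m, 0.99, prune_diagonal=True)


class TestDeviation:
    def test_identical_vectors(self):
        d = mn.density_from_counts([1, 2, 3], list("abc"))
        rms, per = mn.deviation(d, d)
        assert rms == 0.0 and np.all(per == 0)

    def test_hand_rms(self):
        a = mn.density_from_counts([0.6, 0.4], list("ab"))
        b = mn.density_from_counts([0.5, 0.5], list("ab"))
        rms, per = mn.deviation(a, b)
        assert rms == pytest.approx(0.1)
        assert np.allclose(per, [0.1, -0.1])

    def test_label_mismatch_rejected(self):
        a = mn.density_from_counts([1, 1], list("ab"))
        b = mn.density_from_counts([1, 1], list("ac"))
        with pytest.raises(ValueError, match="labels"):
            mn.deviation(a, b)


@pytest.fixture(scope="module")
def sweep():
    cfg = mn.GeneratorConfig(n_nodes=12, n_days=20, seed=1)
    panel, truth = mn.generate_panel(cfg)
    panel = mn.apply_privacy_censoring(panel, 10)
    mean = mn.mean_transition_matrix(panel)
    census = mn.density_from_counts(truth.populations, panel.node_labels)
    cutoffs = [0, 1e-5, 1e-4, 2.75e-4, 1e-3, 3e-3, 1e-2, 3e-2]
    return mn.pruning_sweep(mean, cutoffs, census), mean, census


class TestPruningSweep:

    def test_zero_cutoff_matches_unpruned_deviation(self, sweep):
        report, mean, census = sweep
        rms, _ = mn.deviation(mn.stationary_density(mean), census)
        assert report.deviations[0] == pytest.approx(rms)

    def test_deviation_grows_until_breakdown(self, sweep):
        report, _, _ = sweep
        alive = [d for d, ok in zip(report.deviations,
                                    report.strongly_connected) if ok]
        assert len(alive) >= 3
        assert np.all(np.diff(alive) >= -1e-12)

    def test_no_stationary_vector_past_breaking_point(self, sweep):
        report, _, _ = sweep
        assert report.breaking_cutoff is not None
        for c, ok, vec in zip(report.cutoffs, report.strongly_connected,
                              report.stationary_vectors):
            if c >= report.breaking_cutoff:
                assert not ok and vec is None
            else:
                assert ok and vec is not None
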