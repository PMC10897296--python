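"""Effective distances, resolution/relevance, and the CVS optimum."""

from __future__ import annotations

import numpy as np
import pytest

import mobnet as mn
from mobnet.cvs import effective_path_lengths

from .conftest import make_transition, stochastic_from_offdiag, two_scale_mobility


def partition_of(sizes: list[int]) -> mn.Partition:
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return mn.Partition.from_labels(
        labels, [f"n{i}" for i in range(labels.size)]
    )


class TestEffectivePathLengths:
    def test_certain_link_has_unit_length(self):
        m = make_transition([[0.0, 1.0], [1.0, 0.0]])
        d, _ = effective_path_lengths(m)
        assert d[0, 1] == pytest.approx(1.0)
        assert d[1, 0] == pytest.approx(1.0)

    def test_three_node_dijkstra_hand_oracle(self):
        # A->B direct 1-ln(0.01) ~ 5.605; A->C->B: 2*(1-ln 0.3) ~ 4.408
        v = np.array([[0.69, 0.01, 0.3],
                      [0.0, 0.7, 0.3],
                      [0.1, 0.3, 0.6]])
        m = make_transition(v, labels=("A", "B", "C"))
        d, paths = effective_path_lengths(m)
        assert d[0, 1] == pytest.approx(1 - np.log(0.01))
        assert paths[0, 1] == pytest.approx(2 * (1 - np.log(0.3)))
        assert paths[0, 1] < d[0, 1]

    def test_triangle_inequality_among_reachable(self, small_mean):
        _, paths = effective_path_lengths(small_mean)
        n = small_mean.n_nodes
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert paths[i, j] <= paths[i, k] + paths[k, j] + 1e-9


class TestEffectiveDistance:
    def test_mean_is_exactly_one(self, small_mean):
        delta = mn.effective_distance(small_mean)
        assert delta.values.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(delta.values, delta.values.T)
        assert np.all(np.diag(delta.values) == 0)

    def test_direct_link_case_takes_precedence(self):
        # ordered rule: a direct link supplies its own length even when a
        # shorter indirect path exists
        v = np.array([[0.69, 0.01, 0.3],
                      [0.05, 0.65, 0.3],
                      [0.1, 0.3, 0.6]])
        m = make_transition(v)
        delta = mn.effective_distance(m)
        d, _ = effective_path_lengths(m)
        raw = (d + d.T) / 2  # all pairs directly linked both ways here
        np.fill_diagonal(raw, 0.0)
        assert np.allclose(delta.values, raw / raw.mean())

    def test_reverse_link_fills_missing_direction(self):
        v = np.array([[0.9, 0.1, 0.0],
                      [0.05, 0.9, 0.05],
                      [0.0, 0.1, 0.9]])
        # no direct 0->2 or 2->0 link; paths exist through 1
        m = make_transition(v)
        d, paths = effective_path_lengths(m)
        delta = mn.effective_distance(m)
        expected_02 = (paths[0, 2] + paths[2, 0]) / 2
        raw = np.zeros((3, 3))
        raw[0, 1] = raw[1, 0] = (d[0, 1] + d[1, 0]) / 2
        raw[1, 2] = raw[2, 1] = (d[1, 2] + d[2, 1]) / 2
        raw[0, 2] = raw[2, 0] = expected_02
        assert np.allclose(delta.values, raw / raw.mean())

    def test_unreachable_pair_gets_finite_cap(self):
        # two 2-node islands: cross-island entries fall back to the cap
        v = np.array([[0.9, 0.1, 0.0, 0.0],
                      [0.1, 0.9, 0.0, 0.0],
                      [0.0, 0.0, 0.9, 0.1],
                      [0.0, 0.0, 0.1, 0.9]])
        m = make_transition(v)
        delta = mn.effective_distance(m)
        assert delta.finite_cap is not None
        intra = delta.values[0, 1]
        cross = delta.values[0, 2]
        assert cross == pytest.approx(delta.finite_cap)
        # cap = 100 x the largest well-defined entry (here every intra-
        # island link has length 1 - ln 0.1), surviving mean-normalization
        # as a pure ratio
        assert cross / intra == pytest.approx(100.0)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mn.effective_distance(make_transition([[1.0]]))


class TestResolutionRelevance:
    def test_trivial_limits(self):
        n = 10
        one = mn.Partition.single_cluster([f"n{i}" for i in range(n)])
        alone = mn.Partition.singletons([f"n{i}" for i in range(n)])
        assert mn.resolution(one) == 0.0
        assert mn.resolution(alone) == pytest.approx(1.0)
        assert mn.relevance(one) == 0.0
        assert mn.relevance(alone) == 0.0

    def test_balanced_pair_hand_values(self):
        p = partition_of([2, 2])
        assert mn.resolution(p) == pytest.approx(0.5)
        # both clusters have size 2 => k*m_k/N = 1 => zero relevance
        assert mn.relevance(p) == 0.0

    def test_uneven_pair_hand_value(self):
        p = partition_of([1, 3])
        expected = 0.25 + 0.75 * np.log(4 / 3) / np.log(4)
        assert mn.relevance(p) == pytest.approx(expected)
        assert mn.resolution(p) == pytest.approx(
            -(0.25 * np.log(0.25) + 0.75 * np.log(0.75)) / np.log(4)
        )

    def test_single_object_rejected(self):
        p = mn.Partition.from_labels([0], ["a"])
        with pytest.raises(ValueError):
            mn.resolution(p)


class TestCvsPartition:
    def test_two_nodes_tie_resolved_to_coarsest(self):
        m = make_transition([[0.9, 0.1], [0.1, 0.9]])
        opt, curve = mn.cvs_partition(mn.effective_distance(m))
        assert curve.relevances == (0.0, 0.0)
        assert opt.n_clusters == 1

    def test_curve_invariants(self, small_mean):
        opt, curve = mn.cvs_partition(mn.effective_distance(small_mean))
        res = np.array(curve.resolutions)
        assert res[0] == 0.0
        assert res[-1] == pytest.approx(1.0)
        assert np.all(np.diff(res) >= -1e-12)
        assert curve.relevances[0] == 0.0
        assert curve.relevances[-1] == 0.0
        assert opt.relevance == max(curve.relevances)
        assert all(np.asarray(curve.relevances) >= 0)

    def test_planted_blocks_never_merged(self):
        """With intra-block distances far below inter-block ones, the
        optimal partition refines the planted blocks."""
        rng = np.random.default_rng(6)
        sizes = [4, 5, 6]
        blocks = np.repeat(np.arange(3), sizes)
        n = blocks.size
        dist = np.where(blocks[:, None] == blocks[None, :],
                        rng.uniform(0.5, 1.0, (n, n)),
                        rng.uniform(50.0, 60.0, (n, n)))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        delta = mn.EffectiveDistanceMatrix(
            dist / dist.mean(), tuple(f"n{i}" for i in range(n))
        )
        opt, _ = mn.cvs_partition(delta)
        for k in range(opt.n_clusters):
            members = blocks[opt.partition.labels == k]
            assert len(set(members.tolist())) == 1

    def test_reduced_mobility_yields_more_clusters(self):
        """Scaling off-diagonal flux down by the lockdown factor pushes the
        intermediate links of a two-scale mobility hierarchy below the
        censoring-equivalent probability cutoff; the relevance optimum then
        settles on more, finer clusters (mean over tie-break seeds)."""
        k_unconf, k_conf = [], []
        for seed in range(10):
            off, _, _ = two_scale_mobility(seed)
            for ks, scale in ((k_unconf, 1.0), (k_conf, 0.3)):
                tm = stochastic_from_offdiag(off * scale)
                pruned = mn.prune_and_renormalize(tm, 0.0034)
                opt, _ = mn.cvs_partition(mn.effective_distance(pruned))
                ks.append(opt.n_clusters)
        assert np.mean(k_conf) > np.mean(k_unconf)
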