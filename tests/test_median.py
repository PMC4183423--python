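"""Chromatic-median alignment, thresholding, networks and similarity."""

import numpy as np
import pytest

from ctnet.core import HomologID
from ctnet.interactions import InteractionMatrix
from ctnet.median import (
    ChromaticMedian,
    apply_flips,
    brute_force_median,
    build_network,
    compare_networks,
    select_threshold,
    sorenson,
)


def _random_matrix(rng, chromosomes, density=0.3):
    n = 2 * len(chromosomes)
    a = rng.random((n, n)) < density
    a = np.triu(a, 1)
    return InteractionMatrix(a | a.T, chromosomes)


class TestFlips:
    def test_zero_vector_is_identity(self):
        m = _random_matrix(np.random.default_rng(0), (1, 4, 11))
        assert apply_flips(m, [0, 0, 0]) == m

    def test_involution(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            m = _random_matrix(rng, (1, 4, 11, 12, 16, 17, 18))
            bits = rng.integers(0, 2, 7)
            assert apply_flips(apply_flips(m, bits), bits) == m

    def test_single_edge_bookkeeping(self):
        m = InteractionMatrix.from_edges(
            [(HomologID(1, "a"), HomologID(4, "a"))], chromosomes=(1, 4)
        )
        f = apply_flips(m, [1, 0])
        assert f.has_edge(HomologID(1, "b"), HomologID(4, "a"))
        assert f.n_edges() == 1


class TestAlignment:
    def test_single_nucleus_is_its_own_median(self):
        m = _random_matrix(np.random.default_rng(3), (1, 4, 11))
        res = ChromaticMedian([m]).fit(restarts=5, seed=0)
        assert res.objective == 0
        assert np.array_equal(res.percent_triu, 100.0 * m.triu_values())

    def test_flip_equivalent_pair_aligns_exactly(self):
        m = _random_matrix(np.random.default_rng(4), (1, 4, 11, 12, 16, 17, 18))
        res = ChromaticMedian([m, apply_flips(m, [1, 0, 0, 0, 0, 0, 0])]).fit(
            restarts=10, seed=0
        )
        assert res.objective == 0

    def test_objective_counts_hamming_disagreement(self):
        a = InteractionMatrix.from_edges(
            [(HomologID(1, "a"), HomologID(4, "a"))], chromosomes=(1, 4)
        )
        b = InteractionMatrix(chromosomes=(1, 4))
        res = ChromaticMedian([a, b, b]).fit(restarts=5, seed=0)
        assert res.objective == 1  # majority empties the median; one nucleus dissents

    def test_gauge_invariance_of_objective_and_percent(self):
        rng = np.random.default_rng(5)
        mats = [_random_matrix(rng, (1, 4, 11)) for _ in range(6)]
        res1 = ChromaticMedian(mats).fit(restarts=30, seed=0)
        flipped = [apply_flips(m, [1, 0, 1]) for m in mats]
        res2 = ChromaticMedian(flipped).fit(restarts=30, seed=0)
        assert res1.objective == res2.objective
        assert sorted(res1.percent_triu) == pytest.approx(sorted(res2.percent_triu))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ChromaticMedian([])

    def test_summary_mentions_objective(self):
        m = _random_matrix(np.random.default_rng(6), (1, 4))
        res = ChromaticMedian([m]).fit(restarts=2, seed=0)
        assert "objective" in res.summary()


class TestBruteForce:
    def test_single_and_identical_inputs(self):
        m = _random_matrix(np.random.default_rng(7), (1, 4))
        assert brute_force_median([m]).objective == 0
        res = brute_force_median([m, m.copy()])
        assert res.objective == 0

    def test_refuses_large_instances(self):
        rng = np.random.default_rng(8)
        mats = [_random_matrix(rng, (1, 4, 11, 12)) for _ in range(2)]
        with pytest.raises(ValueError):
            brute_force_median(mats)

    def test_never_above_heuristic(self):
        rng = np.random.default_rng(9)
        for inst in range(20):
            mats = [_random_matrix(rng, (1, 4, 11)) for _ in range(4)]
            bf = brute_force_median(mats)
            h = ChromaticMedian(mats).fit(restarts=20, seed=inst)
            assert bf.objective <= h.objective


class TestThresholdAndNetwork:
    def test_threshold_definition(self):
        exp = np.full(91, 50.0)
        assert select_threshold(exp, [np.full(91, 27.0)]) == 28
        assert select_threshold(exp, [np.full(91, 31.4)]) == 32
        assert select_threshold(exp, [np.zeros(91)]) == 1

    def test_empty_network_warns(self):
        with pytest.warns(RuntimeWarning):
            tau = select_threshold(np.full(91, 10.0), [np.full(91, 50.0)])
        assert tau == 51

    def _labels(self, n):
        return [(HomologID(1, "a"), HomologID(4, "a"))] * n  # labels only carry names

    def test_three_edges_one_per_tier(self):
        pct = np.array([60.0, 40.0, 35.0, 10.0])
        net = build_network(pct, self._labels(4), threshold=30)
        assert [e.tier for e in net.edges] == ["top", "middle", "bottom"]

    def test_eighteen_edges_split_six_six_six(self):
        pct = np.linspace(80, 35, 18)
        net = build_network(pct, self._labels(18), threshold=30)
        tiers = [e.tier for e in net.edges]
        assert tiers.count("top") == 6 and tiers.count("middle") == 6 and tiers.count("bottom") == 6

    def test_boundary_ties_promote_upwards(self):
        pct = np.array([60.0, 50.0, 50.0, 40.0, 30.0, 20.0])
        net = build_network(pct, self._labels(6), threshold=10)
        tiers = [e.tier for e in net.edges]
        assert tiers[1] == tiers[2] == "top"

    def test_no_edges_above_threshold(self):
        net = build_network(np.array([10.0, 5.0]), self._labels(2), threshold=50)
        assert len(net) == 0


class TestSimilarityAndComparison:
    def test_sorenson_closed_forms(self):
        a = {frozenset({1, 2}), frozenset({3, 4})}
        assert sorenson(a, a) == 1.0
        assert sorenson(a, {frozenset({5, 6})}) == 0.0
        four = {frozenset({i, i + 10}) for i in range(4)}
        other = set(list(four)[:2]) | {frozenset({99, 100}), frozenset({98, 97})}
        assert sorenson(four, other) == 0.5
        with pytest.raises(ValueError):
            sorenson(set(), set())

    def test_compare_networks_set_algebra(self):
        e1 = {frozenset({1, 2}), frozenset({3, 4})}
        e2 = {frozenset({3, 4}), frozenset({5, 6})}
        cmp = compare_networks(e1, e2)
        assert cmp.shared == {frozenset({3, 4})}
        assert cmp.unique_to_1 == {frozenset({1, 2})}
        assert cmp.unique_to_2 == {frozenset({5, 6})}

    def test_identical_and_disjoint_networks(self):
        e = {frozenset({1, 2})}
        assert compare_networks(e, e).shared == e
        assert compare_networks(e, {frozenset({7, 8})}).shared == set()


class TestRangeCompression:
    def test_randomized_controls_compress_percent_range(self):
        """Aligning randomized inputs must not fabricate the planted pattern."""
        from ctnet.nullmodels import randomize_population
        from ctnet.synthetic import sample_interaction_matrices

        from conftest import bench_spec

        samp = sample_interaction_matrices(bench_spec(50, seed=7))
        exp = ChromaticMedian(samp.matrices).fit(restarts=50, seed=0)
        ctrl_mats = randomize_population(samp.matrices, seed=77)
        ctrl = ChromaticMedian(ctrl_mats).fit(restarts=50, seed=1)
        ratio = np.ptp(exp.percent_triu) / np.ptp(ctrl.percent_triu)
        assert ratio > 2.0
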