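"""Interaction calling and population statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ctnet.core import HomologID
from ctnet.interactions import (
    InteractionMatrix,
    call_interactions,
    chromosome_pairs,
    classify_multiplet,
    homolog_vs_heterolog_ranking,
    pair_profiles,
    partners_per_ct,
    radial_regression,
)


class _FakeTable:
    """Minimal stand-in exposing the pairs frame call_interactions reads."""

    def __init__(self, chromosomes, pbd):
        hids = [HomologID(c, t) for c in sorted(chromosomes) for t in "ab"]
        rows = []
        for i, hi in enumerate(hids):
            for hj in hids[i + 1:]:
                rows.append({
                    "chrom_i": hi.chromosome, "tag_i": hi.tag,
                    "chrom_j": hj.chromosome, "tag_j": hj.tag,
                    "pbd_um": pbd.get((hi, hj), 5.0),
                })
        self.pairs = pd.DataFrame(rows)


class TestCallInteractions:
    def test_threshold_is_inclusive(self):
        e = (HomologID(1, "a"), HomologID(4, "a"))
        for pbd, expected in [(0.0, True), (0.28, True), (0.29, False)]:
            m = call_interactions(_FakeTable([1, 4], {e: pbd}))
            assert m.has_edge(*e) is expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        hids = [HomologID(c, t) for c in (1, 4, 11) for t in "ab"]
        pbd = {}
        for i, hi in enumerate(hids):
            for hj in hids[i + 1:]:
                pbd[(hi, hj)] = float(rng.uniform(0, 0.6))
        table = _FakeTable([1, 4, 11], pbd)
        edges = [call_interactions(table, thr).n_edges() for thr in (0.1, 0.28, 0.5)]
        assert edges == sorted(edges)

    def test_incomplete_table_raises(self):
        t = _FakeTable([1, 4], {})
        t.pairs = t.pairs.iloc[:-1]
        with pytest.raises(ValueError):
            call_interactions(t)


class TestPartners:
    def test_empty_matrices_give_zero(self):
        mats = [InteractionMatrix() for _ in range(3)]
        assert (partners_per_ct(mats) == 0).all()

    def test_saturated_heterologs_give_twelve(self):
        m = InteractionMatrix()
        for u, v in itertools.combinations(m.index, 2):
            if u.chromosome != v.chromosome:
                m.set_edge(u, v)
        assert (partners_per_ct([m]) == 12).all()

    def test_whole_genome_panel_gives_forty_four(self):
        chroms = list(range(1, 24))
        m = InteractionMatrix(chromosomes=chroms)
        for u, v in itertools.combinations(m.index, 2):
            if u.chromosome != v.chromosome:
                m.set_edge(u, v)
        assert (partners_per_ct([m]) == 44).all()

    def test_hand_built_population(self):
        m1 = InteractionMatrix.from_edges([
            (HomologID(1, "a"), HomologID(17, "a")),
            (HomologID(1, "a"), HomologID(17, "b")),
        ])
        m2 = InteractionMatrix.from_edges([(HomologID(1, "b"), HomologID(4, "a"))])
        m3 = InteractionMatrix()
        p = partners_per_ct([m1, m2, m3])
        assert p[1] == pytest.approx((2 + 1 + 0) / 6)
        assert p[17] == pytest.approx(2 / 6)
        by_type = partners_per_ct([m1, m2, m3], by="type")
        assert by_type[1] == pytest.approx((2 + 1 + 0) / 3)


class TestProfiles:
    def _pair_count_matrix(self, count):
        slots = [("a", "a"), ("b", "b"), ("a", "b"), ("b", "a")][:count]
        return InteractionMatrix.from_edges(
            [(HomologID(1, t1), HomologID(4, t2)) for t1, t2 in slots]
        )

    def test_tabulation_matches_hand_counts(self):
        counts = [0, 0, 1, 1, 1, 2, 2, 3, 4, 0]
        mats = [self._pair_count_matrix(c) for c in counts]
        prof = pair_profiles(mats)
        row = prof.loc[(1, 4)]
        assert row["pct_ge1"] == 70 and row["pct_eq1"] == 30 and row["pct_ge2"] == 40

    def test_identity_holds_for_every_pair(self, g1_matrices):
        prof = pair_profiles(g1_matrices)
        assert np.allclose(prof["pct_ge1"], prof["pct_eq1"] + prof["pct_ge2"])

    def test_pattern_counts_partition_multiplet_nuclei(self, g1_matrices):
        prof = pair_profiles(g1_matrices)
        two = prof["pat_2a"] + prof["pat_2b"] + prof["pat_2c"]
        counts = {
            pair: [int(m.pair_block(*pair).sum()) for m in g1_matrices]
            for pair in prof.index
        }
        for pair in prof.index:
            n2 = sum(1 for c in counts[pair] if c == 2)
            assert two.loc[pair] == n2
            assert (prof.loc[pair, ["pat_2a", "pat_2b", "pat_2c", "pat_3", "pat_4"]].sum()
                    == prof.loc[pair, "n_ge2"])


class TestMultipletPatterns:
    @pytest.mark.parametrize("block, expected", [
        ([[0, 0], [0, 0]], "0"),
        ([[1, 0], [0, 0]], "1"),
        ([[1, 0], [0, 1]], "2a"),  # disjoint pairwise contacts
        ([[0, 1], [1, 0]], "2a"),
        ([[1, 1], [0, 0]], "2b"),  # triplet sharing a copy of the first chromosome
        ([[1, 0], [1, 0]], "2c"),  # triplet sharing a copy of the second
        ([[1, 1], [1, 0]], "3"),   # alternating four-territory chain
        ([[1, 1], [1, 1]], "4"),
    ])
    def test_all_configurations(self, block, expected):
        assert classify_multiplet(np.array(block)) == expected


class TestRanking:
    def test_normalizations(self):
        once = InteractionMatrix.from_edges([(HomologID(1, "a"), HomologID(4, "a"))])
        hom = InteractionMatrix.from_edges([(HomologID(1, "a"), HomologID(1, "b"))])
        df = homolog_vs_heterolog_ranking([once, hom])
        het = df[df["pair"] == "1-4"].iloc[0]
        assert het["frequency"] == pytest.approx(1 / (4 * 2))
        homr = df[df["pair"] == "1-1"].iloc[0]
        assert homr["frequency"] == pytest.approx(1 / 2)

    def test_planted_homolog_deficit_ranks_low(self, g1_matrices):
        df = homolog_vs_heterolog_ranking(g1_matrices)
        mean_rank_hom = df.loc[df["kind"] == "homologous", "rank"].mean()
        mean_rank_het = df.loc[df["kind"] == "heterologous", "rank"].mean()
        assert mean_rank_hom < mean_rank_het


class TestRadialRegression:
    def test_collinear_points_have_unit_r2(self):
        sr = {c: 10 + 0.1 * c for c in (1, 4, 11, 12, 16, 17, 18)}
        cov = {c: float(c) for c in sr}
        fit = radial_regression(sr, cov)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.1)

    def test_constant_sr_gives_zero_r2(self):
        sr = {c: 50.0 for c in (1, 4, 11, 12, 16, 17, 18)}
        assert radial_regression(sr, "length").r_squared == 0.0

    def test_constant_covariate_raises(self):
        sr = {c: 50.0 + c for c in (1, 4)}
        with pytest.raises(ValueError):
            radial_regression(sr, {1: 2.0, 4: 2.0})

    def test_planted_size_dependence_recovered(self, sparse_tables):
        from ctnet.morphometry import mean_subtended_radii

        fit = radial_regression(mean_subtended_radii(sparse_tables), "length")
        assert fit.slope > 0
        assert fit.r_squared > 0.5
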