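"""Synthetic nucleus and population generator."""

import numpy as np
import pytest

from ctnet.core import VoxelSpacing
from ctnet.interactions import InteractionMatrix, chromosome_pairs, pair_profiles
from ctnet.synthetic import (
    PopulationSpec,
    default_spec,
    default_volume_fractions,
    generate_nucleus_mask,
    plant_and_grow_population,
    sample_interaction_matrices,
)

SP = VoxelSpacing()


class TestNucleusMask:
    def test_plain_ellipsoid_volume_within_two_percent(self):
        m = generate_nucleus_mask((5, 5, 2.5), 0.0, SP)
        expected = 4 / 3 * np.pi * 5 * 5 * 2.5 / SP.voxel_volume
        assert abs(m.volume_voxels() / expected - 1) < 0.02

    def test_zero_irregularity_is_seed_independent(self):
        a = generate_nucleus_mask((4, 4, 2), 0.0, SP, seed=1)
        b = generate_nucleus_mask((4, 4, 2), 0.0, SP, seed=99)
        assert np.array_equal(a.data, b.data)

    def test_irregular_masks_connected_and_volume_bounded(self):
        expected = 4 / 3 * np.pi * 5 * 5 * 2.5 / SP.voxel_volume
        for seed in range(50):
            m = generate_nucleus_mask((5, 5, 2.5), 0.3, SP, seed=seed)
            assert m.n_components() == 1
            assert abs(m.volume_voxels() / expected - 1) < 0.10

    def test_too_small_grid_raises(self):
        with pytest.raises(ValueError):
            generate_nucleus_mask((5, 5, 2.5), 0.0, SP, shape=(3, 10, 10))


class TestSpecValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_nuclei=1, pair_probabilities={(1, 4): 1.5})

    def test_volume_fractions_must_leave_room(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_nuclei=1, volume_fractions={c: 0.2 for c in (1, 4, 11, 12, 16, 17, 18)})

    def test_n_nuclei_positive(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_nuclei=0)

    def test_default_fractions_proportional_to_length(self):
        f = default_volume_fractions()
        assert f[1] > f[4] > f[18]
        assert sum(f.values()) == pytest.approx(0.15)


class TestMatrixSampler:
    def test_zero_probabilities_give_empty_truth(self):
        spec = PopulationSpec(
            n_nuclei=20, pair_probabilities={p: 0.0 for p in chromosome_pairs()},
            homolog_probability=0.0, seed=3,
        )
        samp = sample_interaction_matrices(spec)
        assert all(t.n_edges() == 0 for t in samp.truths)

    def test_forced_saturation_fills_all_four_slots(self):
        probs = {p: 0.0 for p in chromosome_pairs()}
        probs[(1, 17)] = 1.0
        spec = PopulationSpec(
            n_nuclei=10, pair_probabilities=probs, homolog_probability=0.0,
            multiplicity_weights={4: 1.0}, seed=3,
        )
        samp = sample_interaction_matrices(spec)
        for t in samp.truths:
            assert t.pair_block(1, 17).sum() == 4
            assert t.n_edges() == 4

    def test_frequencies_converge_to_probabilities(self):
        spec = default_spec("WI38", "G1", n_nuclei=200, seed=21)
        samp = sample_interaction_matrices(spec)
        prof = pair_profiles(samp.truths)
        for pair in prof.index:
            assert abs(prof.loc[pair, "pct_ge1"] / 100 - spec.pair_probabilities[pair]) < 0.10

    def test_scramble_is_recorded_and_consistent(self):
        from ctnet.median import apply_flips

        spec = default_spec("WI38", "G1", n_nuclei=5, seed=2)
        samp = sample_interaction_matrices(spec)
        for m, t, bits in zip(samp.matrices, samp.truths, samp.flips):
            assert apply_flips(m, bits) == t


class TestPlantedPopulation:
    def test_structure_and_exact_volumes(self, g1_population):
        rec = g1_population[0]
        rec.validate()
        assert len(rec.territories) == 14
        vols = {h: v.volume_voxels() for h, v in rec.territories.items()}
        for c in rec.chromosomes:
            a, b = vols[(c, "a")], vols[(c, "b")]
            assert a > b  # tag 'a' is the larger copy by construction

    def test_truth_matches_recalled_interactions(self, g1_population, g1_matrices):
        matches = sum(r.truth == m for r, m in zip(g1_population, g1_matrices))
        assert matches == len(g1_population)

    def test_overlap_realization_statistics(self, g1_tables):
        import pandas as pd

        pairs = pd.concat([t.pairs for t in g1_tables])
        called = pairs[pairs["pbd_um"] <= 0.28 + 1e-6]
        frac_overlap = (called["overlap_vox"] > 0).mean()
        assert 0.75 <= frac_overlap <= 1.0  # ~90% of contacts are direct overlap
        mean_pct = called.loc[called["overlap_vox"] > 0, "overlap_pct_mean"].mean()
        assert 5.0 <= mean_pct <= 30.0  # ~15% shared volume among overlapping pairs

    def test_s_phase_nuclei_are_larger(self):
        g1 = plant_and_grow_population(default_spec("WI38", "G1", n_nuclei=3, seed=4))
        s = plant_and_grow_population(default_spec("WI38", "S", n_nuclei=3, seed=4))
        vg1 = np.mean([r.nucleus.volume_um3() for r in g1])
        vs = np.mean([r.nucleus.volume_um3() for r in s])
        assert 1.02 < vs / vg1 < 1.25  # ~+12.5 % with cell-to-cell variability

    def test_reproducible_from_seed(self):
        spec = default_spec("WI38", "G1", n_nuclei=2, seed=13)
        a = plant_and_grow_population(spec)
        b = plant_and_grow_population(spec)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.nucleus.data, rb.nucleus.data)
            for h in ra.territories:
                assert np.array_equal(ra.territories[h].data, rb.territories[h].data)
            assert ra.truth == rb.truth

    def test_condition_probability_structure(self):
        from ctnet.synthetic import default_pair_probabilities

        g1 = default_pair_probabilities("WI38", "G1")
        s = default_pair_probabilities("WI38", "S")
        changed = [p for p in g1 if g1[p] != s[p]]
        assert len(changed) == 2  # fibroblast line: only two pairs shift in S
        s10 = default_pair_probabilities("10A", "S")
        assert s10[(1, 18)] > default_pair_probabilities("10A", "G1")[(1, 18)]
        assert g1[(1, 17)] > g1[(1, 4)]  # chromosome-17 pairs are elevated
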