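"""Segmentation, homolog assignment and the 3D measurement engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from ctnet.core import HomologID, LabeledVolume, NucleusRecord, VoxelSpacing
from ctnet.morphometry import (
    InvalidGeometryError,
    MeasurementTable,
    assign_homologs,
    segment_territory,
    subtended_radius,
)

SP = VoxelSpacing()


def _blob_volume(value_bg=10.0, value_fg=200.0, shape=(8, 24, 24)):
    data = np.full(shape, value_bg)
    data[2:6, 8:16, 8:16] = value_fg
    return LabeledVolume(data, SP), (slice(2, 6), slice(8, 16), slice(8, 16))


class TestSegmentation:
    @pytest.mark.parametrize("method", ["isodata", "band", "erosion"])
    def test_bimodal_volume_recovers_blob_exactly(self, method):
        vol, region = _blob_volume()
        expected = np.zeros(vol.data.shape, bool)
        expected[region] = True
        mask = segment_territory(vol, method=method)
        assert np.array_equal(mask.mask, expected)

    def test_constant_volume_raises(self):
        with pytest.raises(ValueError):
            segment_territory(LabeledVolume(np.zeros((4, 4, 4)), SP))

    def test_methods_agree_on_noisy_blurred_blobs(self):
        jaccards = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = np.full((10, 36, 36), 20.0)
            data[3:7, 8:28, 8:28] = 220.0
            data = ndimage.gaussian_filter(data, sigma=(0.4, 0.8, 0.8))
            data += rng.normal(0, 20.0, data.shape)
            vol = LabeledVolume(data, SP)
            masks = [segment_territory(vol, m).mask for m in ("isodata", "band", "erosion")]
            for i in range(3):
                for j in range(i + 1, 3):
                    inter = (masks[i] & masks[j]).sum()
                    union = (masks[i] | masks[j]).sum()
                    jaccards.append(inter / union)
        assert min(jaccards) >= 0.95


class TestHomologAssignment:
    def _mask(self, n, offset=0):
        m = np.zeros((4, 12, 12), bool)
        m.ravel()[offset:offset + n] = True
        return LabeledVolume(m.reshape(4, 12, 12), SP)

    def test_larger_volume_is_a(self):
        res = assign_homologs(self._mask(120), self._mask(100, offset=300), 4)
        assert not res.flagged
        assert res.mapping[HomologID(4, "a")].volume_voxels() == 120

    def test_tie_broken_by_centroid(self):
        m1 = self._mask(50, offset=0)
        m2 = self._mask(50, offset=400)
        res = assign_homologs(m2, m1, 4)
        a = res.mapping[HomologID(4, "a")]
        b = res.mapping[HomologID(4, "b")]
        assert tuple(a.centroid_um()) <= tuple(b.centroid_um())

    def test_missing_homolog_flagged(self):
        res = assign_homologs(self._mask(50), self._mask(0), 4)
        assert res.flagged


def _spherical_record(radius_um=2.0, ct_at=None, spacing=VoxelSpacing(0.07, 0.07, 0.2)):
    pitch = np.array(spacing.sampling)
    shape = (2 * np.ceil(radius_um / pitch).astype(int) + 5)
    center = (shape - 1) / 2
    grids = np.meshgrid(*[(np.arange(s) - c) * p for s, c, p in zip(shape, center, pitch)],
                        indexing="ij", sparse=True)
    rho = np.sqrt(sum(g**2 for g in grids))
    nucleus = LabeledVolume(rho <= radius_um, spacing)
    territories = {}
    if ct_at is not None:
        m = np.zeros(tuple(shape), bool)
        idx = np.round(center + np.asarray(ct_at) / pitch).astype(int)
        m[tuple(idx)] = True
        territories[HomologID(1, "a")] = LabeledVolume(m, spacing)
    return NucleusRecord(nucleus, territories)


class TestSubtendedRadius:
    def test_centre_point_has_zero_sr(self):
        rec = _spherical_record()
        assert subtended_radius(rec.nucleus, rec.nucleus.centroid_um()) == 0.0

    def test_half_radius_point_is_fifty_percent(self):
        rec = _spherical_record(radius_um=2.0)
        c = rec.nucleus.centroid_um()
        sr = subtended_radius(rec.nucleus, c + np.array([0.0, 0.0, 1.0]))
        assert sr == pytest.approx(50.0, abs=3.0)  # half-voxel discretization

    def test_point_outside_nucleus_raises(self):
        rec = _spherical_record(radius_um=2.0)
        c = rec.nucleus.centroid_um()
        with pytest.raises(InvalidGeometryError):
            subtended_radius(rec.nucleus, c + np.array([0.0, 0.0, 5.0]))


class TestMeasurementEngine:
    def test_full_panel_emits_canonical_counts(self, g1_tables):
        t = g1_tables[0]
        assert len(t.homologs) == 14
        assert len(t.pairs) == 91
        assert (t.pairs["kind"] == "heterologous").sum() == 84
        assert (t.pairs["kind"] == "homologous").sum() == 7
        assert t.n_heterologous_distances() == 252
        assert t.n_homologous_distances() == 21
        assert t.n_axis_values() == 28
        assert len(t.homologs[["centroid_z_um", "centroid_y_um", "centroid_x_um"]]) == 14
        assert t.homologs["sr_pct"].between(0, 100).all()

    def test_three_four_five_pixel_distance(self):
        rec = _spherical_record(radius_um=2.0, spacing=SP)
        shape = rec.nucleus.data.shape
        center = np.array([s // 2 for s in shape])
        m1 = np.zeros(shape, bool); m1[tuple(center)] = True
        m2 = np.zeros(shape, bool); m2[tuple(center + [0, 3, 4])] = True
        rec.territories = {
            HomologID(1, "a"): LabeledVolume(m1, SP),
            HomologID(4, "a"): LabeledVolume(m2, SP),
        }
        t = MeasurementTable.measure(rec)
        assert t.pairs.loc[0, "pbd_um"] == pytest.approx(0.35)
        assert t.pairs.loc[0, "pbd_px"] == pytest.approx(5.0)

    def test_overlap_implies_zero_pbd_and_vice_versa(self, g1_tables):
        pairs = pd.concat([t.pairs for t in g1_tables])
        assert (pairs.loc[pairs["overlap_vox"] > 0, "pbd_um"] == 0).all()
        assert (pairs.loc[pairs["pbd_um"] == 0, "overlap_vox"] > 0).all()

    def test_pbd_not_larger_than_pcd_on_convex_fixtures(self):
        # two axis-aligned boxes are convex, so the border gap is below the
        # centroid distance
        shape = (6, 30, 30)
        nuc = LabeledVolume(np.ones(shape, bool), SP)
        m1 = np.zeros(shape, bool); m1[2:4, 5:10, 5:10] = True
        m2 = np.zeros(shape, bool); m2[2:4, 5:10, 18:24] = True
        rec = NucleusRecord(nuc, {
            HomologID(1, "a"): LabeledVolume(m1, SP),
            HomologID(4, "a"): LabeledVolume(m2, SP),
        })
        t = MeasurementTable.measure(rec)
        row = t.pairs.iloc[0]
        assert row["pbd_um"] <= row["pcd_um"]
        assert row["pbcd_um"] <= row["pcd_um"]

    def test_sr_and_mpd_invariant_under_translation(self):
        spacing = VoxelSpacing(0.07, 0.07, 0.2)
        base = _spherical_record(radius_um=1.5, ct_at=(0.2, 0.3, 0.4), spacing=spacing)
        t0 = MeasurementTable.measure(base)
        shifted_nuc = np.roll(base.nucleus.data, (1, 3, 5), axis=(0, 1, 2))
        shifted_ct = np.roll(base.territories[HomologID(1, "a")].data, (1, 3, 5), axis=(0, 1, 2))
        rec = NucleusRecord(
            LabeledVolume(shifted_nuc, spacing),
            {HomologID(1, "a"): LabeledVolume(shifted_ct, spacing)},
        )
        t1 = MeasurementTable.measure(rec)
        # SR carries half-voxel discretization; MPD shifts exactly
        assert t1.homologs.loc[0, "sr_pct"] == pytest.approx(t0.homologs.loc[0, "sr_pct"], abs=3.0)
        assert t1.homologs.loc[0, "mpd_um"] == pytest.approx(t0.homologs.loc[0, "mpd_um"], abs=1e-9)

    def test_csv_roundtrip(self, g1_tables, tmp_path):
        t = g1_tables[0]
        path = tmp_path / "measurements.csv"
        t.to_csv(path)
        back = MeasurementTable.from_csv(path)
        pd.testing.assert_frame_equal(back.pairs, t.pairs, check_dtype=False)
        assert back.n_heterologous_distances() == 252
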