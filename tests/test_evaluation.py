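"""Evaluation operations: landmark RMS, volume change, angulation and
intensity-PDF segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histomri.evaluation import (
    IntensityPDF,
    LandmarkSet,
    VOIMask,
    angulation_report,
    dice,
    estimate_pdf,
    global_volume_change,
    interobserver_rms,
    interquartile_segment,
    landmark_rms,
    voi_volume_mm3,
    volume_change_percent,
)
from histomri.image import VolumeImage, resample
from histomri.pipeline import StageResult
from histomri.transforms import RigidTransform3D, SimilarityTransform3D


def lmset(points, **kw):
    return LandmarkSet({f"L{i}": p for i, p in enumerate(points)}, **kw)


class TestLandmarkRMS:
    def test_identical_sets_zero(self):
        a = lmset([(1, 2, 3), (4, 5, 6)])
        assert landmark_rms(a, a) == 0.0

    def test_two_unit_offsets_along_different_axes(self):
        a = lmset([(0, 0, 0), (5, 5, 5)])
        b = lmset([(1, 0, 0), (5, 6, 5)])
        assert landmark_rms(a, b) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a = lmset(rng.normal(size=(10, 3)))
        b = lmset(rng.normal(size=(10, 3)))
        assert landmark_rms(a, b) == pytest.approx(landmark_rms(b, a))

    def test_transform_applied_to_first_set(self):
        a = lmset([(0, 0, 0)])
        b = lmset([(1, 2, 3)])
        t = RigidTransform3D(translation=(1, 2, 3))
        assert landmark_rms(a, b, t) == pytest.approx(0.0)

    def test_identifier_mismatch_lists_names(self):
        a = LandmarkSet({"p1": (0, 0, 0)})
        b = LandmarkSet({"p2": (0, 0, 0)})
        with pytest.raises(ValueError, match="p1"):
            landmark_rms(a, b)


class TestInterobserver:
    def test_identical_annotations_zero(self):
        a = lmset([(1, 1, 1)], observer="A")
        assert interobserver_rms(a, a) == 0.0

    def test_known_jitter_magnitude_recovered(self, rng):
        pts = rng.uniform(0, 10, (10, 3))
        m = 0.7
        d = rng.normal(size=(10, 3))
        d *= m / np.linalg.norm(d, axis=1, keepdims=True)
        a = lmset(pts, observer="A")
        b = lmset(pts + d, observer="B")
        assert interobserver_rms(a, b) == pytest.approx(m, rel=1e-9)

    def test_single_point_offset(self):
        a = LandmarkSet({"p": (0, 0, 0)})
        b = LandmarkSet({"p": (0.7, 0, 0)})
        assert interobserver_rms(a, b) == pytest.approx(0.7)


class TestVolumeChange:
    @pytest.mark.parametrize("x", [-50.0, -13.2, -1.9, 0.0, 13.2, 50.0])
    def test_relative_formula_exact(self, x):
        v = 1000.0
        assert volume_change_percent(v, v * (1 + x / 100.0)) == pytest.approx(
            x, abs=1e-12)

    def test_mirror_of_reported_shrinkage(self):
        assert volume_change_percent(1000.0, 868.0) == pytest.approx(-13.2)

    def test_zero_original_volume_rejected(self):
        with pytest.raises(ValueError):
            volume_change_percent(0.0, 10.0)

    @given(x=st.floats(-99.0, 300.0))
    @settings(max_examples=100, deadline=None)
    def test_exactness_property(self, x):
        assert volume_change_percent(50.0, 50.0 * (1 + x / 100.0)) == pytest.approx(
            x, abs=1e-9)

    def test_warped_mask_consistent_with_determinant(self, rng):
        # mask warped by isotropic scale s changes volume by ~100 (s^3 - 1)
        mask = np.zeros((64, 64, 64), dtype=float)
        g = np.stack(np.meshgrid(*[np.arange(64)] * 3, indexing="ij"), axis=-1)
        mask[np.linalg.norm(g - 31.5, axis=-1) < 22] = 1.0
        grid = VolumeImage(mask, (0.2, 0.2, 0.2))
        s = 1.05
        t = SimilarityTransform3D(scale=1 / s, center=grid.center())  # pull-back
        warped = resample(grid, t, grid, "nearest")
        v_o = voi_volume_mm3(mask > 0, grid.spacing)
        v_r = voi_volume_mm3(warped.values > 0, grid.spacing)
        # lattice-sphere counting fluctuates ~±2 pp at this radius
        assert volume_change_percent(v_o, v_r) == pytest.approx(
            100 * (s**3 - 1), abs=2.5)

    def test_global_change_identity_zero(self):
        stage = StageResult(affine=SimilarityTransform3D())
        assert global_volume_change(stage) == pytest.approx(0.0)

    def test_global_change_sign_convention(self):
        # pull-back det 0.868: 13.2 % of the fixed volume lost to fixation
        stage = StageResult(affine=SimilarityTransform3D(scale=0.868 ** (1 / 3)))
        assert global_volume_change(stage) == pytest.approx(13.2, abs=1e-9)
        # expansion reads negative (sectioning: -1.9 %)
        stage = StageResult(affine=SimilarityTransform3D(scale=1.019 ** (1 / 3)))
        assert global_volume_change(stage) == pytest.approx(-1.9, abs=1e-9)


class TestAngulation:
    def test_identity_zero(self):
        assert angulation_report(StageResult(rigid=RigidTransform3D())) == 0.0

    def test_out_of_plane_tilt_reported(self):
        stage = StageResult(rigid=RigidTransform3D(angles=np.radians([2.3, 0, 0])))
        assert angulation_report(stage) == pytest.approx(2.3, abs=1e-9)

    def test_pure_in_plane_rotation_zero(self):
        stage = StageResult(rigid=RigidTransform3D(angles=np.radians([0, 0, 10.0])))
        assert angulation_report(stage) == pytest.approx(0.0, abs=1e-9)


class TestIntensityPDF:
    def test_constant_region_single_bin(self):
        img = np.full((6, 6, 6), 42.0)
        pdf = estimate_pdf(img, np.ones_like(img, dtype=bool))
        assert pdf.max_bin_mass() == pytest.approx(1.0)
        assert pdf.q1 == pdf.q2 == pdf.q3

    def test_uniform_quartiles(self, rng):
        vals = rng.uniform(0, 100, (64, 64, 8))
        pdf = estimate_pdf(vals, np.ones(vals.shape, dtype=bool), bins=64)
        binw = 100 / 64
        assert pdf.q1 == pytest.approx(25.0, abs=2 * binw)
        assert pdf.q3 == pytest.approx(75.0, abs=2 * binw)

    def test_disjoint_regions_have_disjoint_supports(self, rng):
        img = np.zeros((10, 10, 10))
        a = np.zeros_like(img, dtype=bool)
        a[:5] = True
        img[a] = rng.uniform(0, 10, a.sum())
        img[~a] = rng.uniform(50, 60, (~a).sum())
        pa = estimate_pdf(img, a)
        pb = estimate_pdf(img, ~a)
        assert pa.bin_edges[-1] < pb.bin_edges[0]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            estimate_pdf(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), dtype=bool))

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            IntensityPDF(np.array([0.0, 1.0, 2.0]), np.array([0.4, 0.4]))


class TestInterquartileSegmentation:
    @given(seed=st.integers(0, 50))
    @settings(max_examples=25, deadline=None)
    def test_selects_half_of_defining_voi(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(100, 15, (24, 24, 8)) + rng.uniform(-30, 30)
        voi = rng.random(vals.shape) < 0.6
        pdf = estimate_pdf(vals, voi)
        seg = interquartile_segment(vals, pdf)
        frac = np.count_nonzero(seg & voi) / np.count_nonzero(voi)
        assert abs(frac - 0.5) <= pdf.max_bin_mass() + 0.02

    def test_image_below_range_gives_empty_mask(self, rng):
        vals = rng.uniform(100, 110, (8, 8, 8))
        pdf = estimate_pdf(vals, np.ones(vals.shape, dtype=bool))
        low = np.zeros((8, 8, 8))
        assert not interquartile_segment(low, pdf).any()

    def test_domain_mask_restricts_selection(self, rng):
        vals = rng.normal(50, 5, (10, 10, 10))
        pdf = estimate_pdf(vals, np.ones(vals.shape, dtype=bool))
        domain = np.zeros(vals.shape, dtype=bool)
        domain[:5] = True
        seg = interquartile_segment(vals, pdf, domain_mask=domain)
        assert not seg[5:].any()


class TestDiceAndMasks:
    def test_dice_extremes(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[:2] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0

    def test_voi_mask_volume(self):
        m = VOIMask(np.ones((10, 10, 10)), "necrotic", spacing=(0.2, 0.2, 0.2))
        assert m.volume_mm3() == pytest.approx(1000 * 0.008)

    def test_voi_label_vocabulary_enforced(self):
        with pytest.raises(ValueError):
            VOIMask(np.ones((2, 2, 2)), "tumour")
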