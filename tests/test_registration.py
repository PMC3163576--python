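"""Similarity metrics (with an independent exhaustive MI oracle), pyramid,
and registration recovery of known transforms."""

import numpy as np
import pytest

from histomri.image import VolumeImage, resample
from histomri.registration import (
    MetricError,
    OverlapError,
    RegistrationConfig,
    build_pyramid,
    mean_squared_difference,
    mutual_information,
    normalized_correlation,
    optimize,
    register,
)
from histomri.transforms import RigidTransform3D, SimilarityTransform3D


def exhaustive_mi_bits(f, m, bins):
    """Independent brute-force MI from the full joint histogram (bits).

    Hard binning with the same bin-center layout as the sampled estimator
    (values at bin centers fall into exactly one bin).
    """
    def hard_bin(v):
        lo, hi = float(v.min()), float(v.max())
        z = (v - lo) / (hi - lo) * bins - 0.5
        return np.clip(np.round(z), 0, bins - 1).astype(int)

    joint = np.zeros((bins, bins))
    for a, b in zip(hard_bin(f.ravel()), hard_bin(m.ravel())):
        joint[a, b] += 1
    p = joint / joint.sum()
    pf = p.sum(axis=1)
    pm = p.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if p[i, j] > 0:
                mi += p[i, j] * np.log2(p[i, j] / (pf[i] * pm[j]))
    return mi


def bin_center_values(rng, shape, bins, lo=0.0, hi=255.0, corr=0.9):
    """Pair of images quantized so each value falls in exactly one bin.

    With the estimator's data-range binning (z = (v-min)/(max-min)*B - 0.5),
    the extremes clip into the first/last bin and interior levels are placed
    at integer bin coordinates, so partial-volume weights degenerate and the
    joint histogram equals the hard-binned one.
    """
    levels = np.empty(bins)
    levels[0] = lo
    levels[-1] = hi
    levels[1:-1] = lo + (np.arange(1, bins - 1) + 0.5) * (hi - lo) / bins
    ka = rng.integers(0, bins, size=shape)
    noise = rng.integers(-2, 3, size=shape)
    kb = np.where(rng.random(shape) < corr, np.clip(ka + noise, 0, bins - 1),
                  rng.integers(0, bins, size=shape))
    a = levels[ka].astype(float)
    b = levels[kb].astype(float)
    # pin extremes so the data range spans [lo, hi] in both images
    a.flat[0], a.flat[-1] = lo, hi
    b.flat[0], b.flat[-1] = lo, hi
    return a, b


def vol(values):
    return VolumeImage(np.asarray(values, dtype=float))


class TestMutualInformation:
    def test_self_similarity_equals_marginal_entropy(self, rng):
        a, _ = bin_center_values(rng, (16, 16, 4), bins=16)
        image = vol(a)
        cfg = RegistrationConfig(histogram_bins=16)
        mi = -mutual_information(image, image, None, cfg).value
        p = np.unique(a, return_counts=True)[1] / a.size
        h = -np.sum(p * np.log2(p))
        assert mi == pytest.approx(h, abs=1e-9)

    def test_independent_images_near_zero(self, rng):
        # large-n independence limit; finite-sample bias ~ (B-1)^2/(2N ln 2)
        a = vol(rng.uniform(0, 255, (64, 64, 4)))
        b = vol(rng.uniform(0, 255, (64, 64, 4)))
        cfg = RegistrationConfig(histogram_bins=32)
        mi = -mutual_information(a, b, None, cfg).value
        assert 0.0 <= mi < 0.05  # bits

    def test_hand_computed_one_bit_case(self):
        # joint counts {(0,0): 8, (1,1): 8} -> exactly 1 bit
        a = np.zeros((4, 4, 1))
        a[2:, :, 0] = 1.0
        cfg = RegistrationConfig(histogram_bins=8)
        mi = -mutual_information(vol(a), vol(a.copy()), None, cfg).value
        assert mi == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_oracle_at_full_sampling(self, rng):
        a, b = bin_center_values(rng, (64, 64, 1), bins=32)
        cfg = RegistrationConfig(histogram_bins=32)
        mine = -mutual_information(vol(a), vol(b), None, cfg, full_sampling=True).value
        oracle = exhaustive_mi_bits(a, b, 32)
        assert mine == pytest.approx(oracle, abs=1e-9)

    def test_sampled_estimator_close_to_exhaustive(self, rng):
        a, b = bin_center_values(rng, (64, 64, 2), bins=32)
        oracle = exhaustive_mi_bits(a, b, 32)
        cfg = RegistrationConfig(histogram_bins=32,
                                 samples_per_iteration=int(0.9 * a.size),
                                 random_seed=3)
        sampled = -mutual_information(vol(a), vol(b), None, cfg,
                                      full_sampling=False).value
        assert sampled == pytest.approx(oracle, rel=0.02)

    def test_bin_relabeling_invariance(self, rng):
        # MI is unchanged by bijective relabeling of one image's bins
        a, b = bin_center_values(rng, (32, 32, 1), bins=16)
        cfg = RegistrationConfig(histogram_bins=16)
        base = mutual_information(vol(a), vol(b), None, cfg).value
        centers = np.unique(b)
        perm = centers[::-1]  # value -> reversed center (bijective, monotone bins)
        relabeled = perm[np.searchsorted(centers, b)]
        flipped = mutual_information(vol(a), vol(relabeled), None, cfg).value
        assert flipped == pytest.approx(base, abs=1e-9)

    def test_empty_mask_rejected(self, rng):
        a = vol(rng.uniform(0, 1, (8, 8, 8)))
        cfg = RegistrationConfig(fixed_mask=np.zeros((8, 8, 8), dtype=bool))
        with pytest.raises(MetricError):
            mutual_information(a, a, None, cfg)


class TestNormalizedCorrelation:
    def test_identical_images_give_minus_one(self, rng):
        a = vol(rng.normal(size=(10, 10, 10)))
        cfg = RegistrationConfig(metric="normalized_correlation")
        assert normalized_correlation(a, a, None, cfg).value == pytest.approx(-1.0)

    def test_affine_intensity_invariance(self, rng):
        a = rng.normal(size=(10, 10, 10))
        cfg = RegistrationConfig(metric="normalized_correlation")
        val = normalized_correlation(vol(a), vol(3.2 * a + 10.0), None, cfg).value
        assert val == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        ramp = np.arange(64, dtype=float).reshape(4, 4, 4)
        flat = np.full((4, 4, 4), 5.0)
        cfg = RegistrationConfig(metric="normalized_correlation")
        with pytest.raises(MetricError):
            normalized_correlation(vol(ramp), vol(flat), None, cfg)

    def test_msd_zero_for_identical(self, rng):
        a = vol(rng.normal(size=(6, 6, 6)))
        cfg = RegistrationConfig(metric="mean_squared_difference")
        assert mean_squared_difference(a, a, None, cfg).value == pytest.approx(0.0)


class TestPyramid:
    def test_single_level_is_original(self, rng):
        image = vol(rng.normal(size=(16, 16, 16)))
        cfg = RegistrationConfig(shrink_factors=(1,), smoothing_sigmas=(0.0,))
        levels = build_pyramid(image, cfg)
        assert len(levels) == 1
        assert np.array_equal(levels[0].values, image.values)

    def test_constant_stays_constant(self):
        image = vol(np.full((16, 16, 16), 2.5))
        cfg = RegistrationConfig(shrink_factors=(4, 2, 1),
                                 smoothing_sigmas=(2.0, 1.0, 0.0))
        for level in build_pyramid(image, cfg):
            assert np.allclose(level.values, 2.5)

    def test_shapes_and_spacing_follow_factors(self, rng):
        image = vol(rng.normal(size=(64, 64, 64)))
        cfg = RegistrationConfig(shrink_factors=(4, 2, 1),
                                 smoothing_sigmas=(2.0, 1.0, 0.0))
        levels = build_pyramid(image, cfg)
        assert [lv.shape for lv in levels] == [(16,) * 3, (32,) * 3, (64,) * 3]
        assert levels[0].spacing[0] == pytest.approx(4.0)

    def test_too_small_image_drops_levels(self, rng, caplog):
        image = vol(rng.normal(size=(8, 8, 8)))
        cfg = RegistrationConfig(shrink_factors=(8, 1), smoothing_sigmas=(2.0, 0.0))
        levels = build_pyramid(image, cfg)
        assert len(levels) == 1


@pytest.fixture(scope="module")
def realigned(exvivo_phantom):
    return exvivo_phantom.invivo_realigned


@pytest.fixture(scope="module")
def tumor_mask(exvivo_phantom):
    return exvivo_phantom.truth.labels["plane"] > 0


class TestOptimizeAndRegister:
    def test_fixed_point_stays_at_identity(self, realigned, tumor_mask):
        cfg = RegistrationConfig(fixed_mask=tumor_mask, random_seed=7)
        t = register(realigned, realigned, "rigid", cfg)
        voxel = realigned.spacing[0]
        assert np.all(np.abs(t.translation) < 0.1 * voxel)
        assert np.all(np.abs(np.degrees(t.angles)) < 0.1)

    def test_known_translation_recovered(self, realigned, tumor_mask):
        # phantom shifted by (2, 1, 0) voxels; pull-back recovery is the inverse
        voxel = realigned.spacing
        shift = np.array([2.0, 1.0, 0.0]) * voxel
        true = RigidTransform3D(translation=shift, center=realigned.center())
        moved = resample(realigned, true, realigned)
        cfg = RegistrationConfig(fixed_mask=tumor_mask, random_seed=7)
        t = register(realigned, moved, "rigid", cfg)
        assert np.all(np.abs(t.translation + shift) < 0.2 * voxel)

    def test_known_scale_recovered(self, realigned, tumor_mask):
        # moving rendered 1/1.05 of fixed; similarity stage recovers 1.05.
        # Linear stages use the dilated mask (tumor plus margin), the
        # pipeline's policy: a tight mask un-anchors the boundary scale.
        from scipy import ndimage

        true = SimilarityTransform3D(scale=1.0 / 1.05, center=realigned.center())
        moved = resample(realigned, true, realigned)
        dilated = ndimage.binary_dilation(tumor_mask, iterations=10)
        cfg = RegistrationConfig(fixed_mask=dilated, random_seed=7)
        rigid = register(realigned, moved, "rigid", cfg)
        sim = register(realigned, moved, "similarity", cfg, init=rigid)
        assert 1.045 <= sim.scale <= 1.055

    def test_guard_never_worsens_full_metric(self, realigned, tumor_mask):
        from histomri.registration import evaluate_metric

        cfg = RegistrationConfig(fixed_mask=tumor_mask, random_seed=7)
        t0 = RigidTransform3D(center=realigned.center())
        result = optimize(realigned, realigned, t0, cfg)
        assert evaluate_metric(realigned, realigned, result, cfg) <= \
            evaluate_metric(realigned, realigned, t0, cfg) + 1e-12

    def test_disjoint_initialization_raises_overlap_error(self, realigned, tumor_mask):
        cfg = RegistrationConfig(fixed_mask=tumor_mask, random_seed=7)
        far = RigidTransform3D(translation=(500.0, 0, 0))
        with pytest.raises(OverlapError):
            register(realigned, realigned, "rigid", cfg, init=far)

    def test_fixed_seed_reproduces_parameters_exactly(self, realigned, tumor_mask):
        true = RigidTransform3D(translation=(0.3, -0.2, 0.1), center=realigned.center())
        moved = resample(realigned, true, realigned)
        cfg = RegistrationConfig(fixed_mask=tumor_mask, random_seed=11)
        t1 = register(realigned, moved, "rigid", cfg)
        t2 = register(realigned, moved, "rigid", cfg)
        assert np.array_equal(t1.angles, t2.angles)
        assert np.array_equal(t1.translation, t2.translation)
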