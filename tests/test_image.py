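"""Image container, interpolation, resampling and realignment geometry."""

import numpy as np
import pytest

from histomri.image import (
    GeometryError,
    ReferencePlane,
    SectionStack,
    VolumeImage,
    extract_channel,
    interpolate,
    realign_to_reference_plane,
    resample,
)
from histomri.transforms import AffineTransform3D, RigidTransform3D


def make_volume(values, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return VolumeImage(np.asarray(values, dtype=float), spacing, origin)


class TestVolumeImage:
    def test_geometry_round_trip(self, rng):
        vol = VolumeImage(rng.normal(size=(4, 5, 6)), (0.5, 0.25, 2.0), (1, -2, 3))
        idx = rng.uniform(0, 3, (20, 3))
        assert np.allclose(vol.index_from_world(vol.world_from_index(idx)), idx)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            VolumeImage(np.zeros((3, 3, 3)), spacing=(1, -1, 1))
        with pytest.raises(GeometryError):
            VolumeImage(np.zeros((3, 3, 3)), direction=2 * np.eye(3))
        with pytest.raises(GeometryError):  # left-handed
            VolumeImage(np.zeros((3, 3, 3)), direction=np.diag([1, 1, -1]))


class TestInterpolate:
    @pytest.mark.parametrize("scheme", ["nearest", "linear", "cubic_bspline"])
    def test_grid_node_identity(self, rng, scheme):
        vol = make_volume(rng.normal(size=(5, 5, 5)))
        pts = vol.world_from_index(np.array([[1, 2, 3], [0, 0, 0], [4, 4, 4]], float))
        vals = interpolate(vol, pts, scheme)
        assert np.allclose(vals, [vol.values[1, 2, 3], vol.values[0, 0, 0],
                                  vol.values[4, 4, 4]], atol=1e-9)

    def test_constant_preserved_linear(self, rng):
        vol = make_volume(np.full((6, 6, 6), 3.7))
        pts = rng.uniform(0.5, 4.5, (50, 3))
        assert np.allclose(interpolate(vol, pts, "linear"), 3.7)

    def test_ramp_midpoint_is_half(self):
        # 1D ramp {0,1,2} along x: the midpoint of nodes 0 and 1 reads 0.5
        vals = np.zeros((3, 1, 1))
        vals[:, 0, 0] = [0, 1, 2]
        vol = make_volume(vals)
        assert interpolate(vol, (0.5, 0.0, 0.0), "linear") == pytest.approx(0.5)

    def test_linear_exact_for_affine_field(self, rng):
        # linear interpolation reproduces affine intensity fields exactly
        g = np.stack(np.meshgrid(*[np.arange(6)] * 3, indexing="ij"), axis=-1)
        vals = 2.0 * g[..., 0] - 1.5 * g[..., 1] + 0.25 * g[..., 2] + 3.0
        vol = make_volume(vals)
        pts = rng.uniform(0.2, 4.8, (100, 3))
        expect = 2.0 * pts[:, 0] - 1.5 * pts[:, 1] + 0.25 * pts[:, 2] + 3.0
        assert np.allclose(interpolate(vol, pts, "linear"), expect, atol=1e-10)

    def test_outside_returns_fill(self):
        vol = make_volume(np.ones((3, 3, 3)))
        assert interpolate(vol, (50.0, 0.0, 0.0), "linear", fill=-7.0) == -7.0

    def test_non_finite_point_rejected(self):
        vol = make_volume(np.ones((3, 3, 3)))
        with pytest.raises(GeometryError):
            interpolate(vol, (np.nan, 0, 0))


class TestResample:
    def test_identity_is_bitwise_copy(self, rng):
        vol = make_volume(rng.normal(size=(6, 6, 6)))
        for scheme in ("nearest", "linear"):
            out = resample(vol, None, vol, scheme)
            assert np.array_equal(out.values, vol.values)

    def test_one_voxel_translation_shifts_indices(self, rng):
        vol = make_volume(rng.normal(size=(6, 6, 6)))
        t = RigidTransform3D(translation=(1.0, 0, 0))  # pull-back: +1 voxel in x
        out = resample(vol, t, vol, "nearest", fill=0.0)
        assert np.array_equal(out.values[:-1], vol.values[1:])
        assert np.all(out.values[-1] == 0.0)

    def test_round_trip_close_on_smooth_volume(self):
        g = np.stack(np.meshgrid(*[np.linspace(0, 1, 24)] * 3, indexing="ij"), axis=-1)
        vals = np.sin(3 * g[..., 0]) * np.cos(2 * g[..., 1]) + g[..., 2]
        vol = VolumeImage(vals, (0.5, 0.5, 0.5))
        t = RigidTransform3D(angles=(0.02, -0.03, 0.05), translation=(0.2, -0.1, 0.15),
                             center=vol.center())
        back = resample(resample(vol, t, vol), t.inverse(), vol)
        inner = (slice(4, -4),) * 3
        mae = np.mean(np.abs(back.values[inner] - vol.values[inner]))
        assert mae < 5e-3

    def test_singular_transform_rejected(self):
        vol = make_volume(np.ones((4, 4, 4)))
        bad = AffineTransform3D(matrix=np.zeros((3, 3)))
        with pytest.raises(GeometryError):
            resample(vol, bad, vol)


class TestRealign:
    def test_native_first_slice_plane_is_identity(self, rng):
        vol = make_volume(rng.normal(size=(7, 7, 7)))
        # plane = native z=0 slice plane, native axes, centered in-plane
        plane = ReferencePlane(normal=(0, 0, 1), point=(3, 3, 0),
                               in_plane_axes=[(1, 0, 0), (0, 1, 0)])
        out = realign_to_reference_plane(vol, plane, (1, 1, 1), (7, 7, 7))
        assert np.allclose(out.values, vol.values, atol=1e-9)

    def test_axis_permutation_preserves_world_values(self, rng):
        vol = make_volume(rng.normal(size=(9, 9, 9)))
        plane = ReferencePlane(normal=(0, 1, 0), point=(4, 4, 4),
                               in_plane_axes=[(0, 0, 1), (1, 0, 0)])
        out = realign_to_reference_plane(vol, plane, (1, 1, 1), (9, 9, 4))
        # a plane-frame grid point corresponds to the native point
        # p0 + B @ xi; values must agree there
        B = plane.basis()
        p0 = plane.point - 4 * plane.in_plane_axes[0] - 4 * plane.in_plane_axes[1]
        xi = np.array([2.0, 3.0, 1.0])
        native = p0 + B @ xi
        assert out.values[2, 3, 1] == pytest.approx(
            interpolate(vol, native, "linear"), abs=1e-9)

    def test_plane_outside_domain_rejected(self, rng):
        vol = make_volume(rng.normal(size=(5, 5, 5)))
        plane = ReferencePlane(normal=(0, 0, 1), point=(50, 0, 0),
                               in_plane_axes=[(1, 0, 0), (0, 1, 0)])
        with pytest.raises(GeometryError):
            realign_to_reference_plane(vol, plane, (1, 1, 1), (5, 5, 5))

    def test_phantom_reference_plane_cross_section(self, default_phantom):
        # slice 0 of the realigned volume is the reference-plane cross-section
        ph = default_phantom
        pts3 = np.zeros((0, 3))
        nx, ny, _ = ph.invivo_realigned.shape
        wsp = ph.cfg.working_spacing_mm
        idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij"),
                       axis=-1).reshape(-1, 2) * wsp
        plane_pts = np.column_stack([idx, np.zeros(idx.shape[0])])
        lab_direct = ph.label_plane(plane_pts).reshape(nx, ny)
        lab_stored = ph.truth.labels["plane"][:, :, 0]
        agree = np.mean((lab_direct > 0) == (lab_stored > 0))
        assert agree > 0.99


class TestSections:
    def test_extract_channels(self):
        red = np.zeros((4, 4, 3))
        red[:, :, 0] = 255.0
        stack = SectionStack([red, red], pixel_size_mm=0.01, interval_mm=0.08)
        assert np.all(extract_channel(stack, "red")[0] == 255)
        assert np.all(extract_channel(stack, "green")[0] == 0)

    def test_grayscale_replicated_channels_identical(self, rng):
        gray = rng.uniform(0, 255, (5, 5))
        sec = np.stack([gray] * 3, axis=-1)
        stack = SectionStack([sec], pixel_size_mm=0.01, interval_mm=0.08)
        r, g, b = (extract_channel(stack, c)[0] for c in ("red", "green", "blue"))
        assert np.array_equal(r, g) and np.array_equal(g, b)

    def test_invalid_channel(self):
        stack = SectionStack([np.zeros((2, 2, 3))], 0.01, 0.08)
        with pytest.raises(ValueError):
            extract_channel(stack, "magenta")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            SectionStack([np.zeros((2, 2, 3)), np.zeros((3, 3, 3))], 0.01, 0.08)

    def test_phantom_red_channel_contrast(self, default_phantom):
        # H&E-like sections: red separates necrotic from viable most strongly
        ph = default_phantom
        k = int(np.argmax([(l == 2).sum() for l in ph.truth.section_labels]))
        lab = ph.truth.section_labels[k]
        sec = ph.sections.sections[k]
        gaps = [abs(sec[:, :, c][lab == 2].mean() - sec[:, :, c][lab == 1].mean())
                for c in range(3)]
        assert gaps[0] == max(gaps)
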