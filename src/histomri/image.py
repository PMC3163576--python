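"""Image containers, world/index geometry, interpolation and resampling.

All world coordinates are in millimetres.  Volumes live on regular,
node-centered grids: the voxel value at index ``i`` is the image sampled at
``world(i) = origin + direction @ (spacing * i)`` with 0-based indices and a
right-handed orthonormal direction matrix.  Histology pixel sizes given in
micrometres are converted to mm on load (see :mod:`histomri.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "VolumeImage",
    "SectionStack",
    "ReferencePlane",
    "interpolate",
    "resample",
    "resample_section",
    "realign_to_reference_plane",
    "plane_frame_affine",
    "extract_channel",
]

_ORDERS = {"nearest": 0, "linear": 1, "cubic_bspline": 3}


class GeometryError(ValueError):
    """Raised for invalid points, grids or planes."""


@dataclass
class VolumeImage:
    """Scalar 3D image on a regular grid with world geometry.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensity per voxel, indexed x-fastest-first.
    spacing : (3,) float
        Voxel spacing in mm, strictly positive.
    origin : (3,) float
        World position (mm) of voxel (0, 0, 0).
    direction : (3, 3) float
        Orthonormal matrix with determinant +1 mapping index axes to world
        axes; identity when the source format omits it.
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError("VolumeImage.values must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing components must be > 0")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-6):
            raise GeometryError("direction must be orthonormal")
        if np.linalg.det(self.direction) < 0:
            raise GeometryError("direction must have determinant +1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_from_index(self, index) -> np.ndarray:
        """Map (…, 3) continuous indices to world mm coordinates."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.direction.T

    def index_from_world(self, point) -> np.ndarray:
        """Map (…, 3) world mm coordinates to continuous indices."""
        point = np.asarray(point, dtype=float)
        return ((point - self.origin) @ self.direction) / self.spacing

    def grid_points(self) -> np.ndarray:
        """World coordinates of every grid node, shape (nx*ny*nz, 3)."""
        nx, ny, nz = self.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return self.world_from_index(idx)

    def center(self) -> np.ndarray:
        """World coordinate of the grid center."""
        return self.world_from_index((np.asarray(self.shape, dtype=float) - 1) / 2)

    def copy_with(self, values: np.ndarray) -> "VolumeImage":
        return VolumeImage(values, self.spacing.copy(), self.origin.copy(), self.direction.copy())


@dataclass
class SectionStack:
    """Ordered RGB 2D sections with shared in-plane geometry.

    Sections are float arrays of shape (nx, ny, 3) indexed ``[ix, iy, channel]``
    with world in-plane coordinates ``(ix * pixel_size_mm, iy * pixel_size_mm)``.
    Section index 0 corresponds to the reference cutting plane; successive
    sections lie ``interval_mm`` apart along the cutting direction.
    """

    sections: list
    pixel_size_mm: float
    interval_mm: float
    thickness_mm: float = 0.004

    def __post_init__(self):
        self.sections = [np.asarray(s, dtype=float) for s in self.sections]
        if not self.sections:
            raise GeometryError("SectionStack needs at least one section")
        shapes = {s.shape for s in self.sections}
        if len(shapes) != 1:
            raise GeometryError("all sections must share one shape (pad on load)")
        shp = next(iter(shapes))
        if len(shp) != 3 or shp[2] != 3:
            raise GeometryError("sections must be (nx, ny, 3) RGB")
        if self.interval_mm <= 0 or self.pixel_size_mm <= 0:
            raise GeometryError("pixel size and interval must be > 0")

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def section_shape(self) -> tuple[int, int]:
        return self.sections[0].shape[:2]


@dataclass
class ReferencePlane:
    """The reference cutting plane in the in vivo world frame.

    The plane is cut through the fixed tumor along its longest axis,
    perpendicular to the subcutaneous side; it anchors all three 3D images.
    ``normal`` must equal ``in_plane_axes[0] x in_plane_axes[1]`` so the plane
    frame is right-handed.
    """

    normal: np.ndarray
    point: np.ndarray
    in_plane_axes: np.ndarray

    def __post_init__(self):
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        self.in_plane_axes = np.asarray(self.in_plane_axes, dtype=float).reshape(2, 3)
        a1, a2 = self.in_plane_axes
        for v in (self.normal, a1, a2):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
                raise GeometryError("plane vectors must be unit length")
        if abs(a1 @ a2) > 1e-8 or abs(self.normal @ a1) > 1e-8 or abs(self.normal @ a2) > 1e-8:
            raise GeometryError("plane axes must be mutually orthogonal")
        if not np.allclose(np.cross(a1, a2), self.normal, atol=1e-8):
            raise GeometryError("normal must equal a1 x a2 (right-handed frame)")

    def basis(self) -> np.ndarray:
        """3x3 matrix whose columns are (a1, a2, normal)."""
        return np.column_stack([self.in_plane_axes[0], self.in_plane_axes[1], self.normal])


def _check_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 3:
        raise GeometryError("points must have 3 components")
    if not np.all(np.isfinite(pts)):
        raise GeometryError("non-finite point coordinates")
    return pts if not squeeze else pts


def interpolate(image: VolumeImage, point, scheme: str = "linear", fill: float = 0.0):
    """Sample ``image`` at world points.

    Points outside the image domain return ``fill`` (default 0).  ``scheme``
    is one of ``nearest``, ``linear``, ``cubic_bspline``.
    """
    if scheme not in _ORDERS:
        raise ValueError(f"unknown interpolation scheme {scheme!r}")
    pts = _check_points(point)
    idx = image.index_from_world(pts)
    out = ndimage.map_coordinates(
        np.asarray(image.values, dtype=float),
        idx.T,
        order=_ORDERS[scheme],
        mode="grid-constant" if scheme == "cubic_bspline" else "constant",
        cval=fill,
        prefilter=scheme == "cubic_bspline",
    )
    if np.ndim(point) == 1:
        return float(out[0])
    return out


def resample(
    moving: VolumeImage,
    transform,
    reference: VolumeImage,
    scheme: str = "linear",
    fill: float = 0.0,
) -> VolumeImage:
    """Pull ``moving`` back onto ``reference``'s grid through ``transform``.

    ``transform`` maps reference-world points into moving-world points
    (pull-back / fixed-to-moving convention); pass ``None`` for identity.
    Each output voxel is ``interpolate(moving, transform(world(index)))``.
    """
    pts = reference.grid_points()
    if transform is not None:
        if hasattr(transform, "is_singular") and transform.is_singular():
            raise GeometryError("cannot resample through a singular transform")
        pts = transform.apply(pts)
    vals = interpolate(moving, pts, scheme=scheme, fill=fill)
    return VolumeImage(
        vals.reshape(reference.shape).astype(moving.values.dtype, copy=False)
        if scheme == "nearest"
        else vals.reshape(reference.shape),
        reference.spacing.copy(),
        reference.origin.copy(),
        reference.direction.copy(),
    )


def resample_section(section: np.ndarray, transform2d, pixel_size_mm: float,
                     out_shape=None, scheme: str = "linear", fill: float = 0.0) -> np.ndarray:
    """Pull a 2D scalar section back through a 2D transform (pull-back).

    ``section`` is (nx, ny) with world coords ``index * pixel_size_mm``;
    ``transform2d`` maps output world points to input world points.
    """
    section = np.asarray(section, dtype=float)
    nx, ny = out_shape if out_shape is not None else section.shape
    idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij"), axis=-1)
    pts = idx.reshape(-1, 2) * pixel_size_mm
    if transform2d is not None:
        pts = transform2d.apply(pts)
    out = ndimage.map_coordinates(
        section, (pts / pixel_size_mm).T, order=_ORDERS[scheme], mode="constant", cval=fill
    )
    return out.reshape(nx, ny)


def plane_frame_affine(plane: ReferencePlane, in_plane_extent_mm) -> "np.ndarray":
    """Return (B, p0): plane frame basis and world origin of the plane frame.

    The plane frame has its origin at the corner such that the in-plane field
    of view of half-extents ``in_plane_extent_mm = (e1, e2)`` is centered on
    ``plane.point``; axis 3 is the plane normal.  A native-world point ``x``
    has plane coordinates ``B.T @ (x - p0)``.
    """
    e1, e2 = in_plane_extent_mm
    B = plane.basis()
    p0 = plane.point - plane.in_plane_axes[0] * e1 / 2 - plane.in_plane_axes[1] * e2 / 2
    return B, p0


def realign_to_reference_plane(
    invivo: VolumeImage,
    plane: ReferencePlane,
    spacing,
    shape,
    scheme: str = "linear",
    fill: float = 0.0,
) -> VolumeImage:
    """Resample the in vivo volume into the reference-plane frame.

    The output grid's first slice coincides with the reference plane, its
    slice normal is the plane normal, and the in-plane field of view is
    centered on ``plane.point``.  The returned volume's world frame *is* the
    plane frame (identity direction, origin 0): the frame that the ex vivo
    MRI and the histology stack share by construction of the cutting plane.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    shape = tuple(int(n) for n in shape)
    # plane must intersect the image domain
    lo = invivo.world_from_index((0.0, 0.0, 0.0))
    hi = invivo.world_from_index(np.asarray(invivo.shape, dtype=float) - 1)
    bmin, bmax = np.minimum(lo, hi), np.maximum(lo, hi)
    if np.any(plane.point < bmin - 1e-9) or np.any(plane.point > bmax + 1e-9):
        raise GeometryError("reference plane point lies outside the image domain")
    extent = (spacing[0] * (shape[0] - 1), spacing[1] * (shape[1] - 1))
    B, p0 = plane_frame_affine(plane, extent)
    nx, ny, nz = shape
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = p0 + (idx * spacing) @ B.T
    vals = interpolate(invivo, world, scheme=scheme, fill=fill)
    return VolumeImage(vals.reshape(shape), spacing, np.zeros(3), np.eye(3))


_CHANNELS = {"red": 0, "green": 1, "blue": 2}


def extract_channel(stack: SectionStack, channel) -> list:
    """Per-section scalar images for one RGB channel (pixel size preserved)."""
    if isinstance(channel, str):
        if channel not in _CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        channel = _CHANNELS[channel]
    if channel not in (0, 1, 2):
        raise ValueError("channel index must be 0, 1 or 2")
    return [s[:, :, channel] for s in stack.sections]
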