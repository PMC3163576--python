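"""Spatial transform models, composition and geometric reports.

All transforms map world points (mm) to world points under the pull-back
(fixed-to-moving) convention used throughout the package.  Euler angles use
intrinsic rotations about x, then y, then z: ``R = Rx(a) @ Ry(b) @ Rz(c)``;
angles are reported in that order.  Gimbal lock (|cos b| ~ 0) is resolved by
setting the third angle to zero.

Serialization is a plain-text key/value format (full ``repr`` float
precision); composite files reference their component files in order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Transform",
    "Rigid2D",
    "RigidTransform3D",
    "SimilarityTransform3D",
    "AffineTransform3D",
    "BSplineTransform3D",
    "CompositeTransform",
    "compose",
    "collapse_affine",
    "euler_to_matrix",
    "matrix_to_euler",
    "rotation_angles_deg",
    "out_of_plane_angulation_deg",
    "determinant",
    "bspline_displacement",
    "write_transform",
    "read_transform",
    "to_sitk",
    "from_sitk",
]


def _vec(v, n):
    return np.asarray(v, dtype=float).reshape(n)


def _pts2d(points):
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    return np.atleast_2d(pts), single


class Transform:
    """Base class: a map from world points to world points."""

    def apply(self, points):
        """Apply to points of shape (3,) or (N, 3) (2D variants: (2,)/(N, 2))."""
        raise NotImplementedError

    def is_singular(self) -> bool:
        return False

    def __call__(self, points):
        return self.apply(points)


def _apply_linear(points, matrix, center, translation):
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = (pts - center) @ matrix.T + center + translation
    return out[0] if single else out


@dataclass
class Rigid2D(Transform):
    """2D rigid transform: ``p -> R(p - c) + c + t`` (angle in radians)."""

    angle: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.angle = float(self.angle)
        self.translation = _vec(self.translation, 2)
        self.center = _vec(self.center, 2)

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, points):
        return _apply_linear(points, self.matrix, self.center, self.translation)

    def inverse(self) -> "Rigid2D":
        R = self.matrix
        # p = R(q - c) + c + t  =>  q = R^T(p - c - t) + c
        return Rigid2D(-self.angle, -(R.T @ self.translation), self.center)


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_to_matrix(angles) -> np.ndarray:
    """Rotation matrix for intrinsic x-y-z Euler angles (radians)."""
    a, b, c = _vec(angles, 3)
    return _rx(a) @ _ry(b) @ _rz(c)


def matrix_to_euler(R) -> np.ndarray:
    """Recover intrinsic x-y-z Euler angles (radians) from a rotation matrix.

    With ``R = Rx(a) Ry(b) Rz(c)``: ``R[0,2] = sin b``; away from gimbal lock
    ``a = atan2(-R[1,2], R[2,2])`` and ``c = atan2(-R[0,1], R[0,0])``.  At
    gimbal lock (|cos b| ~ 0) the convention sets ``c = 0``.
    """
    R = np.asarray(R, dtype=float).reshape(3, 3)
    sb = np.clip(R[0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    if abs(np.cos(b)) < 1e-9:
        c = 0.0
        a = np.arctan2(R[2, 1], R[1, 1])
    else:
        a = np.arctan2(-R[1, 2], R[2, 2])
        c = np.arctan2(-R[0, 1], R[0, 0])
    return np.array([a, b, c])


@dataclass
class RigidTransform3D(Transform):
    """3D rigid transform: ``p -> R(p - c) + c + t``."""

    angles: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.angles = _vec(self.angles, 3)
        self.translation = _vec(self.translation, 3)
        self.center = _vec(self.center, 3)

    @property
    def matrix(self) -> np.ndarray:
        return euler_to_matrix(self.angles)

    def apply(self, points):
        return _apply_linear(points, self.matrix, self.center, self.translation)

    def as_affine(self) -> "AffineTransform3D":
        return AffineTransform3D(self.matrix, self.translation.copy(), self.center.copy())

    def inverse(self) -> "AffineTransform3D":
        return self.as_affine().inverse()

    @classmethod
    def from_matrix(cls, R, translation=(0, 0, 0), center=(0, 0, 0)) -> "RigidTransform3D":
        return cls(matrix_to_euler(R), translation, center)


@dataclass
class SimilarityTransform3D(Transform):
    """Rigid transform plus isotropic scale: ``p -> s R(p - c) + c + t``.

    The single scaling degree of freedom models global specimen volume change
    (``det = scale**3``), e.g. fixation shrinkage.
    """

    angles: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        self.angles = _vec(self.angles, 3)
        self.translation = _vec(self.translation, 3)
        self.center = _vec(self.center, 3)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValueError("similarity scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        return self.scale * euler_to_matrix(self.angles)

    def apply(self, points):
        return _apply_linear(points, self.matrix, self.center, self.translation)

    def as_affine(self) -> "AffineTransform3D":
        return AffineTransform3D(self.matrix, self.translation.copy(), self.center.copy())

    def inverse(self) -> "AffineTransform3D":
        return self.as_affine().inverse()


@dataclass
class AffineTransform3D(Transform):
    """General affine transform: ``p -> M(p - c) + c + t`` with det(M) != 0."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = _vec(self.translation, 3)
        self.center = _vec(self.center, 3)

    def apply(self, points):
        return _apply_linear(points, self.matrix, self.center, self.translation)

    def is_singular(self) -> bool:
        return abs(np.linalg.det(self.matrix)) < 1e-12

    def inverse(self) -> "AffineTransform3D":
        if self.is_singular():
            raise np.linalg.LinAlgError("singular affine transform")
        Minv = np.linalg.inv(self.matrix)
        # p = M(q-c)+c+t => q = Minv(p - c - t) + c
        return AffineTransform3D(Minv, -(Minv @ self.translation), self.center.copy())


def _beta3(t):
    """Cubic B-spline kernel (support |t| < 2, beta3(0) = 2/3)."""
    t = np.abs(t)
    return np.where(
        t < 1.0, (4.0 - 6.0 * t**2 + 3.0 * t**3) / 6.0,
        np.where(t < 2.0, (2.0 - t) ** 3 / 6.0, 0.0),
    )


@dataclass
class BSplineTransform3D(Transform):
    """Free-form deformation: ``p -> p + sum_ijk c_ijk B3(u-i) B3(v-j) B3(w-k)``.

    Control point (i, j, k) sits at ``grid_origin + (i, j, k) * grid_spacing``;
    ``coefficients`` has shape (gx, gy, gz, 3) in mm.  Points without a full
    4x4x4 control support inside the grid get zero displacement (identity
    outside support) — safe extrapolation beyond the tumor border, matching
    ITK's behaviour.
    """

    grid_spacing: np.ndarray
    grid_origin: np.ndarray
    coefficients: np.ndarray

    def __post_init__(self):
        self.grid_spacing = _vec(self.grid_spacing, 3)
        self.grid_origin = _vec(self.grid_origin, 3)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ValueError("coefficients must have shape (gx, gy, gz, 3)")
        if np.any(self.grid_spacing <= 0):
            raise ValueError("grid spacing must be > 0")

    @property
    def grid_shape(self):
        return self.coefficients.shape[:3]

    def displacement(self, points) -> np.ndarray:
        pts, single = np.atleast_2d(np.asarray(points, dtype=float)), np.ndim(points) == 1
        u = (pts - self.grid_origin) / self.grid_spacing
        i0 = np.floor(u).astype(int) - 1
        g = np.asarray(self.grid_shape)
        valid = np.all((i0 >= 0) & (i0 + 3 <= g - 1), axis=1)
        disp = np.zeros_like(pts)
        if np.any(valid):
            uv, iv = u[valid], i0[valid]
            acc = np.zeros((uv.shape[0], 3))
            # 64-term tensor-product accumulation, vectorized over points
            wx = [_beta3(uv[:, 0] - (iv[:, 0] + d)) for d in range(4)]
            wy = [_beta3(uv[:, 1] - (iv[:, 1] + d)) for d in range(4)]
            wz = [_beta3(uv[:, 2] - (iv[:, 2] + d)) for d in range(4)]
            for di in range(4):
                for dj in range(4):
                    wxy = wx[di] * wy[dj]
                    for dk in range(4):
                        c = self.coefficients[iv[:, 0] + di, iv[:, 1] + dj, iv[:, 2] + dk]
                        acc += (wxy * wz[dk])[:, None] * c
            disp[valid] = acc
        return disp[0] if single else disp

    def apply(self, points):
        pts = np.asarray(points, dtype=float)
        return pts + self.displacement(pts)


@dataclass
class CompositeTransform(Transform):
    """Ordered sequence of transforms, applied first-to-last.

    ``CompositeTransform([t1, t2]).apply(p) == t2.apply(t1.apply(p))``.
    """

    transforms: list

    def __post_init__(self):
        flat = []
        for t in self.transforms:
            if isinstance(t, CompositeTransform):
                flat.extend(t.transforms)
            else:
                flat.append(t)
        self.transforms = flat

    def apply(self, points):
        out = points
        for t in self.transforms:
            out = t.apply(out)
        return out

    def is_singular(self) -> bool:
        return any(t.is_singular() for t in self.transforms)


def compose(first: Transform, second: Transform) -> CompositeTransform:
    """Concatenate two transforms: ``compose(a, b).apply(p) == b(a(p))``.

    The first argument is applied first.  Warping histology into in vivo
    space concatenates the ex2in result followed by the stack2ex result under
    the pull-back convention (in vivo point -> ex vivo point -> stack point).
    """
    return CompositeTransform([first, second])


_AFFINE_LIKE = (RigidTransform3D, SimilarityTransform3D, AffineTransform3D)


def collapse_affine(t: Transform) -> AffineTransform3D:
    """Collapse a (composite of) affine-family transform(s) to one affine.

    The collapsed transform has identical action: for ``compose(a, b)``,
    ``M = Mb @ Ma`` and the translation absorbs both centers.
    """
    if isinstance(t, _AFFINE_LIKE):
        a = t if isinstance(t, AffineTransform3D) else t.as_affine()
        # re-center at origin: p -> M p + (c + t - M c)
        off = a.center + a.translation - a.matrix @ a.center
        return AffineTransform3D(a.matrix.copy(), off, np.zeros(3))
    if isinstance(t, CompositeTransform):
        M, off = np.eye(3), np.zeros(3)
        for comp in t.transforms:
            a = collapse_affine(comp)
            M = a.matrix @ M
            off = a.matrix @ off + a.translation
        return AffineTransform3D(M, off, np.zeros(3))
    raise TypeError(f"cannot collapse {type(t).__name__} to an affine transform")


def rotation_angles_deg(t) -> np.ndarray:
    """Euler angles (degrees, intrinsic x-y-z order) of a rigid-family transform."""
    if isinstance(t, RigidTransform3D):
        R = t.matrix
    elif isinstance(t, SimilarityTransform3D):
        R = euler_to_matrix(t.angles)
    elif isinstance(t, AffineTransform3D):
        # polar decomposition: nearest rotation
        U, _, Vt = np.linalg.svd(t.matrix)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            R = U @ np.diag([1, 1, -1]) @ Vt
    else:
        raise TypeError("rotation angles require a rigid/similarity/affine transform")
    return np.degrees(matrix_to_euler(R))


def out_of_plane_angulation_deg(t, plane=None) -> float:
    """Out-of-plane angulation (degrees) of a rigid rotation.

    The angle between the reference-plane normal and its image under the
    rotation component of ``t`` — the rotation about the two in-plane axes,
    ignoring in-plane rotation.  If ``plane`` is None the working frame's z
    axis is taken as the normal (the convention of realigned volumes).
    """
    if isinstance(t, (RigidTransform3D, SimilarityTransform3D)):
        R = euler_to_matrix(t.angles)
    else:
        R = euler_to_matrix(np.radians(rotation_angles_deg(t)))
    n = np.array([0.0, 0.0, 1.0]) if plane is None else plane.normal
    cosang = np.clip(n @ (R @ n), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def determinant(t) -> float:
    """Determinant of the linear part (similarity: ``scale**3``; rigid: 1)."""
    if isinstance(t, SimilarityTransform3D):
        return float(t.scale**3)
    if isinstance(t, RigidTransform3D):
        return 1.0
    if isinstance(t, AffineTransform3D):
        return float(np.linalg.det(t.matrix))
    if isinstance(t, CompositeTransform):
        return float(np.linalg.det(collapse_affine(t).matrix))
    raise TypeError(f"no determinant for {type(t).__name__}")


def bspline_displacement(t: BSplineTransform3D, point) -> np.ndarray:
    """Displacement (mm) of a B-spline transform at world point(s)."""
    return t.displacement(point)


# ---------------------------------------------------------------------------
# plain-text serialization


def _fmt(arr):
    return " ".join(repr(float(v)) for v in np.asarray(arr, dtype=float).ravel())


def _parse(s):
    return np.array([float(v) for v in s.split()])


def write_transform(t: Transform, path: str) -> None:
    """Write a transform as plain text; composites write component files."""
    path = os.fspath(path)
    lines = ["# histomri transform v1"]
    if isinstance(t, Rigid2D):
        lines += [
            "type: rigid2d",
            f"angle: {_fmt([t.angle])}",
            f"translation: {_fmt(t.translation)}",
            f"center: {_fmt(t.center)}",
        ]
    elif isinstance(t, RigidTransform3D):
        lines += [
            "type: rigid3d",
            f"angles: {_fmt(t.angles)}",
            f"translation: {_fmt(t.translation)}",
            f"center: {_fmt(t.center)}",
        ]
    elif isinstance(t, SimilarityTransform3D):
        lines += [
            "type: similarity3d",
            f"angles: {_fmt(t.angles)}",
            f"translation: {_fmt(t.translation)}",
            f"center: {_fmt(t.center)}",
            f"scale: {_fmt([t.scale])}",
        ]
    elif isinstance(t, AffineTransform3D):
        lines += [
            "type: affine3d",
            f"matrix: {_fmt(t.matrix)}",
            f"translation: {_fmt(t.translation)}",
            f"center: {_fmt(t.center)}",
        ]
    elif isinstance(t, BSplineTransform3D):
        gx, gy, gz = t.grid_shape
        lines += [
            "type: bspline3d",
            f"grid_shape: {gx} {gy} {gz}",
            f"grid_spacing: {_fmt(t.grid_spacing)}",
            f"grid_origin: {_fmt(t.grid_origin)}",
            f"coefficients: {_fmt(t.coefficients)}",
        ]
    elif isinstance(t, CompositeTransform):
        lines += ["type: composite", f"count: {len(t.transforms)}"]
        base, ext = os.path.splitext(path)
        for i, comp in enumerate(t.transforms):
            comp_path = f"{base}_{i}{ext or '.txt'}"
            write_transform(comp, comp_path)
            lines.append(f"component: {os.path.basename(comp_path)}")
    else:
        raise TypeError(f"cannot serialize {type(t).__name__}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_transform(path: str) -> Transform:
    """Read a transform written by :func:`write_transform` (lossless)."""
    path = os.fspath(path)
    kv = {}
    components = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            if key == "component":
                components.append(val)
            else:
                kv[key] = val
    ttype = kv.get("type")
    if ttype == "rigid2d":
        return Rigid2D(_parse(kv["angle"])[0], _parse(kv["translation"]), _parse(kv["center"]))
    if ttype == "rigid3d":
        return RigidTransform3D(_parse(kv["angles"]), _parse(kv["translation"]), _parse(kv["center"]))
    if ttype == "similarity3d":
        return SimilarityTransform3D(
            _parse(kv["angles"]), _parse(kv["translation"]), _parse(kv["center"]),
            _parse(kv["scale"])[0],
        )
    if ttype == "affine3d":
        return AffineTransform3D(
            _parse(kv["matrix"]).reshape(3, 3), _parse(kv["translation"]), _parse(kv["center"])
        )
    if ttype == "bspline3d":
        shape = tuple(int(v) for v in kv["grid_shape"].split())
        return BSplineTransform3D(
            _parse(kv["grid_spacing"]),
            _parse(kv["grid_origin"]),
            _parse(kv["coefficients"]).reshape(*shape, 3),
        )
    if ttype == "composite":
        folder = os.path.dirname(path)
        return CompositeTransform([read_transform(os.path.join(folder, c)) for c in components])
    raise ValueError(f"unrecognized transform file {path!r} (type={ttype!r})")


# ---------------------------------------------------------------------------
# SimpleITK interop (used by the registration engine)


def to_sitk(t: Transform):
    """Convert a transform to its SimpleITK equivalent."""
    import SimpleITK as sitk

    if isinstance(t, Rigid2D):
        s = sitk.Euler2DTransform()
        s.SetCenter(tuple(t.center))
        s.SetAngle(float(t.angle))
        s.SetTranslation(tuple(t.translation))
        return s
    if isinstance(t, RigidTransform3D):
        s = sitk.Euler3DTransform()
        s.SetCenter(tuple(t.center))
        s.SetMatrix(tuple(t.matrix.ravel()), 1e-10)
        s.SetTranslation(tuple(t.translation))
        return s
    if isinstance(t, SimilarityTransform3D):
        s = sitk.Similarity3DTransform()
        s.SetCenter(tuple(t.center))
        s.SetMatrix(tuple(t.matrix.ravel()), 1e-10)
        s.SetTranslation(tuple(t.translation))
        return s
    if isinstance(t, AffineTransform3D):
        s = sitk.AffineTransform(3)
        s.SetCenter(tuple(t.center))
        s.SetMatrix(tuple(t.matrix.ravel()))
        s.SetTranslation(tuple(t.translation))
        return s
    if isinstance(t, BSplineTransform3D):
        s = sitk.BSplineTransform(3, 3)
        gx, gy, gz = t.grid_shape
        fixed = [float(gx), float(gy), float(gz), *t.grid_origin, *t.grid_spacing,
                 1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0]
        s.SetFixedParameters(fixed)
        # sitk parameter order: all x, then y, then z coefficients, x-fastest
        params = t.coefficients.transpose(3, 2, 1, 0).ravel()
        s.SetParameters(tuple(params))
        return s
    if isinstance(t, CompositeTransform):
        comp = sitk.CompositeTransform(3)
        # sitk composites apply last-added first; ours apply first-to-last
        for c in reversed(t.transforms):
            comp.AddTransform(to_sitk(c))
        return comp
    raise TypeError(f"cannot convert {type(t).__name__} to SimpleITK")


def from_sitk(s) -> Transform:
    """Convert a SimpleITK transform back to the native hierarchy."""
    import SimpleITK as sitk

    if isinstance(s, sitk.Euler2DTransform):
        return Rigid2D(s.GetAngle(), np.array(s.GetTranslation()), np.array(s.GetCenter()))
    if isinstance(s, sitk.Euler3DTransform):
        R = np.array(s.GetMatrix()).reshape(3, 3)
        return RigidTransform3D(matrix_to_euler(R), np.array(s.GetTranslation()),
                                np.array(s.GetCenter()))
    if isinstance(s, sitk.Similarity3DTransform):
        M = np.array(s.GetMatrix()).reshape(3, 3)
        scale = float(np.cbrt(np.linalg.det(M)))
        return SimilarityTransform3D(matrix_to_euler(M / scale), np.array(s.GetTranslation()),
                                     np.array(s.GetCenter()), scale)
    if isinstance(s, sitk.AffineTransform):
        return AffineTransform3D(np.array(s.GetMatrix()).reshape(3, 3),
                                 np.array(s.GetTranslation()), np.array(s.GetCenter()))
    if isinstance(s, sitk.BSplineTransform):
        fixed = np.array(s.GetFixedParameters())
        size = fixed[:3].astype(int)
        origin, spacing = fixed[3:6], fixed[6:9]
        coeffs = np.array(s.GetParameters()).reshape(3, size[2], size[1], size[0])
        return BSplineTransform3D(spacing, origin, coeffs.transpose(3, 2, 1, 0))
    raise TypeError(f"cannot convert {type(s).__name__} from SimpleITK")
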