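"""Seeded synthetic tumor phantoms with known ground truth.

The generator emulates the study conditions of a subcutaneous rodent tumor
imaged in vivo, excised and fixed (ex vivo MRI), then serially sectioned
from a reference cutting plane:

* ``generate_invivo`` — an ellipsoidal tumor (~10 mm long axis) with a
  lobular boundary, a nested necrotic core and hemorrhagic pockets, rendered
  with T2*-w-like contrast (necrotic distinctly hypo-intense; viable and
  hemorrhagic overlapping), plus the reference cutting plane through the
  longest axis perpendicular to the subcutaneous side, and boundary
  landmarks.
* ``simulate_exvivo`` — fixation shrinkage (isotropic, 13.2 % volume loss by
  default), a small rigid misalignment and a smooth random B-spline
  deformation; intensities re-rendered with fresh noise.
* ``simulate_sections`` — H&E-like RGB sections cut from the reference plane
  at 80 µm intervals with seeded per-slice rigid jitter and a small global
  in-plane sectioning expansion (+1.9 % by default).

Every transform, mask and landmark is recorded in all frames, so recovery by
the registration pipeline can be scored against exact truth.  All outputs
are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .image import ReferencePlane, SectionStack, VolumeImage, realign_to_reference_plane
from .transforms import (
    AffineTransform3D,
    BSplineTransform3D,
    Rigid2D,
    SimilarityTransform3D,
    euler_to_matrix,
)

__all__ = ["PhantomConfig", "PhantomTruth", "Phantom",
           "generate_invivo", "simulate_exvivo", "simulate_sections", "generate"]

LABELS = {"background": 0, "viable": 1, "necrotic": 2, "hemorrhagic": 3}


@dataclass
class PhantomConfig:
    """All phantom parameters; defaults encode the emulated study conditions.

    The grid is desk-scale (64^3 at 0.2 mm, ~10 mm tumor long axis) rather
    than acquisition-scale; geometry scales through spacing, not shape.
    ``deform_amplitude_mm`` is the standard deviation of the B-spline control
    coefficients (typical peak displacement is ~0.5 of it).
    """

    seed: int = 0
    # native in vivo grid
    shape: tuple = (64, 64, 64)
    spacing_mm: tuple = (0.2, 0.2, 0.2)
    tumor_center_mm: tuple = (6.4, 6.4, 6.4)  # on a grid node: the reference
    # plane then hits the native lattice and realignment is an exact axis
    # permutation (no interpolation loss in the fixed image)
    tumor_radii_mm: tuple = (5.0, 3.5, 3.0)  # x = longest axis, y = cut normal
    lobular_amplitude: float = 0.12
    lobular_scale_mm: float = 1.2
    core_amplitude: float = 0.35
    core_scale_mm: float = 1.6
    necrotic_fraction: float = 0.30
    hemorrhagic_fraction: float = 0.10
    n_hemorrhagic_pockets: int = 3
    # intensity models (mean, sigma) per region, arbitrary units in [0, 255]
    invivo_intensities: dict = field(default_factory=lambda: {
        "background": (90.0, 8.0), "viable": (150.0, 12.0),
        "hemorrhagic": (135.0, 15.0), "necrotic": (45.0, 8.0)})
    exvivo_intensities: dict = field(default_factory=lambda: {
        "background": (25.0, 5.0), "viable": (145.0, 12.0),
        "hemorrhagic": (130.0, 15.0), "necrotic": (50.0, 8.0)})
    psf_sigma_mm: float = 0.1
    # smooth intra-region heterogeneity (cell density / susceptibility
    # variation), a tissue property carried through every frame; per-region
    # intensity gain of the unit-variance texture field
    texture_scale_mm: float = 0.8
    texture_gain: dict = field(default_factory=lambda: {
        "background": 6.0, "viable": 14.0, "hemorrhagic": 12.0, "necrotic": 7.0})
    exvivo_texture_gain: dict = field(default_factory=lambda: {
        "background": 1.0, "viable": 14.0, "hemorrhagic": 12.0, "necrotic": 7.0})
    # realigned / ex vivo grids (both anchored at the reference plane);
    # odd in-plane counts keep the plane-centered grid on the native lattice
    realigned_shape: tuple = (65, 65, 20)
    exvivo_shape: tuple = (65, 65, 24)
    working_spacing_mm: float = 0.2  # realigned / ex vivo isotropic voxel
    # ex vivo: fixation shrinkage + pose + smooth deformation
    shrinkage_percent: float = 13.2
    exvivo_rotation_deg: Optional[tuple] = None  # None -> drawn within bound
    exvivo_rotation_bound_deg: float = 2.0
    exvivo_translation_bound_mm: tuple = (0.8, 0.8, 0.15)
    deform_amplitude_mm: float = 0.7
    deform_grid_spacing_mm: float = 4.8
    # sectioning
    n_sections: int = 30
    section_interval_mm: float = 0.08
    section_pixel_mm: float = 0.1
    section_shape: tuple = (128, 128)
    section_thickness_mm: float = 0.004
    jitter_translation_px: float = 5.0
    jitter_rotation_deg: float = 3.0
    expansion_percent: float = 1.9
    # sample every section at the cut face (constant tissue content): the
    # controlled condition for jitter-recovery experiments, where true
    # inter-slice content evolution must not confound the measurement
    uniform_section_content: bool = False
    # H&E-like staining (RGB means per region; red separates necrotic/viable best)
    stain_rgb: dict = field(default_factory=lambda: {
        "background": (248.0, 246.0, 247.0), "viable": (110.0, 85.0, 150.0),
        "necrotic": (235.0, 150.0, 170.0), "hemorrhagic": (190.0, 60.0, 70.0)})
    stain_sigma: float = 22.0
    stain_background_sigma: float = 4.0
    stain_texture_gain: float = 12.0  # cell-density modulation, all channels
    section_blur_px: float = 0.6
    # landmarks
    landmark_count: int = 10
    landmark_min_separation_mm: float = 1.2
    landmark_depth_range_mm: tuple = (0.25, 2.15)

    def __post_init__(self):
        if self.necrotic_fraction + self.hemorrhagic_fraction >= 1.0:
            raise ValueError("region fractions must sum to < 1 (remainder is viable)")
        if min(self.necrotic_fraction, self.hemorrhagic_fraction) < 0:
            raise ValueError("region fractions must be >= 0")
        if self.jitter_translation_px < 0 or self.jitter_rotation_deg < 0:
            raise ValueError("jitter bounds must be >= 0")
        if self.n_sections * self.section_interval_mm <= 0:
            raise ValueError("sectioning extent must be positive")


@dataclass
class PhantomTruth:
    """Ground truth recorded by the generators."""

    plane: ReferencePlane = None
    plane_to_native: AffineTransform3D = None   # embeds plane coords in native world
    native_to_plane: AffineTransform3D = None
    exvivo_similarity: SimilarityTransform3D = None  # ex vivo coords -> plane coords
    exvivo_deform: BSplineTransform3D = None         # displacement in ex vivo coords
    slice_jitters: list = field(default_factory=list)        # Rigid2D, section gen maps
    section_labels: list = field(default_factory=list)       # per-section (nx,ny) labels
    stacking_transforms: list = field(default_factory=list)  # expected recovery (pull-back)
    stack_scale: float = 1.0                                 # in-plane expansion factor
    stack_z0: float = 0.0                                    # cut face z in ex coords
    stack2ex_affine: AffineTransform3D = None                # ex point -> stack point
    landmarks: dict = field(default_factory=dict)            # frame -> (names, (n,3) mm)
    landmark_sections: tuple = None   # (names, section indices, raw-section xy mm)
    labels: dict = field(default_factory=dict)               # frame -> int8 label grid
    programmed: dict = field(default_factory=dict)

    def map_exvivo_to_plane(self, points) -> np.ndarray:
        """The true forward map G: ex vivo coords -> realigned (plane) coords."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.exvivo_similarity.apply(pts + self.exvivo_deform.displacement(pts))
        return out[0] if np.ndim(points) == 1 else out

    def map_plane_to_exvivo(self, points, n_iter: int = 30) -> np.ndarray:
        """Numerical inverse of :meth:`map_exvivo_to_plane` (fixed-point)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        base = self.exvivo_similarity.inverse().apply(pts)
        q = base.copy()
        for _ in range(n_iter):
            q_new = base - self.exvivo_deform.displacement(q)
            if np.max(np.abs(q_new - q)) < 1e-10:
                q = q_new
                break
            q = q_new
        return q[0] if np.ndim(points) == 1 else q


@dataclass
class Phantom:
    """Generated images plus ground truth; filled in by the three generators."""

    cfg: PhantomConfig
    truth: PhantomTruth
    invivo_native: VolumeImage = None
    invivo_realigned: VolumeImage = None
    exvivo: VolumeImage = None
    sections: SectionStack = None
    _model: dict = field(default_factory=dict, repr=False)

    # -- continuous tissue model -------------------------------------------
    def label_native(self, points) -> np.ndarray:
        """Region label (0..3) of the continuous model at native world points."""
        m = self._model
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q0 = np.sum(((pts - m["center"]) / m["radii"]) ** 2, axis=1)
        s1 = _sample_field(m["S1"], pts)
        s2 = _sample_field(m["S2"], pts)
        f = q0 + self.cfg.lobular_amplitude * s1
        f2 = f + self.cfg.core_amplitude * s2
        lab = np.zeros(pts.shape[0], dtype=np.int8)
        tumor = f <= 1.0
        lab[tumor] = LABELS["viable"]
        lab[tumor & (f2 <= m["tau_necrotic"])] = LABELS["necrotic"]
        if m["pockets"] is not None and m["tau_hemorrhagic"] > 0:
            h = np.min(
                np.linalg.norm(pts[:, None, :] - m["pockets"][None, :, :], axis=2), axis=1
            )
            lab[(lab == LABELS["viable"]) & (h <= m["tau_hemorrhagic"])] = LABELS["hemorrhagic"]
        return lab

    def texture_native(self, points) -> np.ndarray:
        """Unit-variance smooth tissue heterogeneity at native world points."""
        return _sample_field(self._model["T"], np.atleast_2d(np.asarray(points, float)))

    def tumor_implicit(self, points) -> np.ndarray:
        """Implicit tumor boundary function (<= 1 inside)."""
        m = self._model
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        q0 = np.sum(((pts - m["center"]) / m["radii"]) ** 2, axis=1)
        return q0 + self.cfg.lobular_amplitude * _sample_field(m["S1"], pts)

    def label_plane(self, points) -> np.ndarray:
        """Labels at realigned (plane-frame) coordinates."""
        return self.label_native(self.truth.plane_to_native.apply(np.atleast_2d(points)))

    def label_exvivo(self, points) -> np.ndarray:
        """Labels at ex vivo coordinates (through the true deformation).

        Tissue below the reference cutting plane was removed with the cut,
        so those points read as background (agar).
        """
        pl = self.truth.map_exvivo_to_plane(np.atleast_2d(points))
        lab = self.label_plane(pl)
        lab[pl[:, 2] < 0.0] = LABELS["background"]
        return lab


def _sample_field(vol: VolumeImage, pts: np.ndarray) -> np.ndarray:
    idx = vol.index_from_world(pts)
    return ndimage.map_coordinates(vol.values, idx.T, order=1, mode="nearest")


def _smooth_noise_field(rng, shape, sigma_vox, spacing) -> VolumeImage:
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma_vox)
    sm /= max(sm.std(), 1e-12)
    return VolumeImage(sm, np.full(3, spacing))


def _render(labels: np.ndarray, intensities: dict, psf_sigma_vox: float, rng,
            texture: np.ndarray = None, gains: dict = None) -> np.ndarray:
    mean = np.zeros(labels.shape)
    sig = np.zeros(labels.shape)
    for name, code in LABELS.items():
        mu, sd = intensities[name]
        mean[labels == code] = mu
        sig[labels == code] = sd
    if texture is not None:
        gain = np.zeros(labels.shape)
        for name, code in LABELS.items():
            gain[labels == code] = gains[name]
        mean = mean + gain * texture
    img = ndimage.gaussian_filter(mean, psf_sigma_vox) + rng.standard_normal(labels.shape) * sig
    return img.astype(np.float32)


def _grid_points(shape, spacing) -> np.ndarray:
    nx, ny, nz = shape
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    return idx * spacing


def _remove_affine_component(deform: BSplineTransform3D, points: np.ndarray) -> None:
    """Subtract the best-fit affine part of a displacement field (in place).

    Fits ``d(q) ~ L q + b`` over the sample points and subtracts the affine
    field from the control coefficients; exact because cubic B-splines
    reproduce affine functions when coefficients sample them at the control
    points.
    """
    d = deform.displacement(points)
    X = np.column_stack([points, np.ones(points.shape[0])])
    sol, *_ = np.linalg.lstsq(X, d, rcond=None)
    L, b = sol[:3].T, sol[3]
    gx, gy, gz = deform.grid_shape
    gidx = np.stack(np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz),
                                indexing="ij"), axis=-1).reshape(-1, 3)
    gpos = deform.grid_origin + gidx * deform.grid_spacing
    deform.coefficients -= (gpos @ L.T + b).reshape(gx, gy, gz, 3)


def _mean_jacobian(deform: BSplineTransform3D, points: np.ndarray,
                   h: float = 0.05) -> float:
    """Mean det(I + grad D) of a displacement field over sample points."""
    grad = np.empty((points.shape[0], 3, 3))
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = h
        grad[:, :, ax] = (deform.displacement(points + e)
                          - deform.displacement(points - e)) / (2 * h)
    jac = np.eye(3) + grad
    return float(np.mean(np.linalg.det(jac)))


def _child_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_invivo(cfg: PhantomConfig) -> Phantom:
    """Generate the in vivo volume, masks, landmarks and the reference plane."""
    (rng_s1, rng_s2, rng_pockets, rng_lm, rng_noise, rng_tex) = _child_rngs(cfg.seed, 6)
    sp = np.asarray(cfg.spacing_mm, dtype=float).reshape(3) if np.ndim(cfg.spacing_mm) \
        else np.full(3, float(cfg.spacing_mm))
    shape = tuple(cfg.shape)
    center = np.asarray(cfg.tumor_center_mm, dtype=float).reshape(3)
    radii = np.asarray(cfg.tumor_radii_mm, dtype=float)

    S1 = _smooth_noise_field(rng_s1, shape, cfg.lobular_scale_mm / sp, sp)
    S2 = _smooth_noise_field(rng_s2, shape, cfg.core_scale_mm / sp, sp)
    T = _smooth_noise_field(rng_tex, shape, cfg.texture_scale_mm / sp, sp)

    pts = _grid_points(shape, sp)
    q0 = np.sum(((pts - center) / radii) ** 2, axis=1)
    f = q0 + cfg.lobular_amplitude * S1.values.ravel()
    f2 = f + cfg.core_amplitude * S2.values.ravel()
    tumor = f <= 1.0
    if not np.any(tumor):
        raise ValueError("infeasible configuration: empty tumor")
    tau_nec = float(np.quantile(f2[tumor], cfg.necrotic_fraction)) \
        if cfg.necrotic_fraction > 0 else -np.inf

    # hemorrhagic pockets: nearest-to-centers voxels in the viable shell
    pockets = None
    tau_hem = 0.0
    if cfg.hemorrhagic_fraction > 0:
        shell = tumor & (f2 > tau_nec + 0.05) & (f2 < 0.8)
        cand = pts[shell]
        if cand.shape[0] < cfg.n_hemorrhagic_pockets:
            raise ValueError("infeasible configuration: no room for hemorrhagic pockets")
        pockets = cand[rng_pockets.choice(cand.shape[0], cfg.n_hemorrhagic_pockets,
                                          replace=False)]
        nonnec = tumor & (f2 > tau_nec)
        h = np.min(np.linalg.norm(pts[nonnec][:, None, :] - pockets[None, :, :], axis=2),
                   axis=1)
        q = cfg.hemorrhagic_fraction / (1.0 - cfg.necrotic_fraction)
        tau_hem = float(np.quantile(h, q))

    truth = PhantomTruth()
    ph = Phantom(cfg=cfg, truth=truth)
    ph._model = {"center": center, "radii": radii, "S1": S1, "S2": S2, "T": T,
                 "tau_necrotic": tau_nec, "pockets": pockets, "tau_hemorrhagic": tau_hem}

    labels_native = ph.label_native(pts).reshape(shape)
    ph.invivo_native = VolumeImage(
        _render(labels_native, cfg.invivo_intensities, cfg.psf_sigma_mm / sp, rng_noise,
                texture=T.values, gains=cfg.texture_gain),
        sp,
    )

    # reference plane: contains the longest (x) axis and the subcutaneous (z)
    # axis, normal along +y; sections advance in +y from the tumor center.
    plane = ReferencePlane(normal=(0, 1, 0), point=center,
                           in_plane_axes=[(0, 0, 1), (1, 0, 0)])
    truth.plane = plane
    rshape = tuple(cfg.realigned_shape)
    wsp = float(cfg.working_spacing_mm)
    extent = (wsp * (rshape[0] - 1), wsp * (rshape[1] - 1))
    B = plane.basis()
    p0 = plane.point - plane.in_plane_axes[0] * extent[0] / 2 \
        - plane.in_plane_axes[1] * extent[1] / 2
    truth.plane_to_native = AffineTransform3D(B, p0, np.zeros(3))
    truth.native_to_plane = truth.plane_to_native.inverse()

    ph.invivo_realigned = realign_to_reference_plane(
        ph.invivo_native, plane, np.full(3, wsp), rshape)
    plane_pts = _grid_points(rshape, wsp)
    truth.labels["native"] = labels_native
    truth.labels["plane"] = ph.label_plane(plane_pts).reshape(rshape)

    # landmarks: lobular extremes of the tumor boundary inside the sectioned
    # band, snapped onto the implicit isosurface along the radial direction
    names, lm = _pick_landmarks(ph, rng_lm)
    truth.landmarks["native"] = (names, lm)
    truth.landmarks["plane"] = (names, truth.native_to_plane.apply(lm))
    truth.programmed.update({
        "necrotic_fraction": cfg.necrotic_fraction,
        "hemorrhagic_fraction": cfg.hemorrhagic_fraction,
        "seed": cfg.seed,
    })
    return ph


def _pick_landmarks(ph: Phantom, rng) -> tuple:
    cfg, m = ph.cfg, ph._model
    sp = ph.invivo_native.spacing
    labels = ph.truth.labels["native"]
    tumor = labels > 0
    surface = tumor & ~ndimage.binary_erosion(tumor)
    pts = np.argwhere(surface) * sp
    depth = (pts - ph.truth.plane.point) @ ph.truth.plane.normal
    lo, hi = cfg.landmark_depth_range_mm
    band = (depth >= lo) & (depth <= hi)
    cand = pts[band]
    if cand.shape[0] < cfg.landmark_count:
        raise ValueError("not enough boundary voxels in the landmark band")
    # prefer lobular extremes (high |S1|) for identifiable features
    score = np.abs(_sample_field(m["S1"], cand)) + 0.01 * rng.standard_normal(cand.shape[0])
    order = np.argsort(-score)
    chosen = []
    for i in order:
        p = cand[i]
        if all(np.linalg.norm(p - q) >= cfg.landmark_min_separation_mm for q in chosen):
            chosen.append(p)
        if len(chosen) == cfg.landmark_count:
            break
    if len(chosen) < cfg.landmark_count:
        raise ValueError("could not place the requested number of landmarks")
    chosen = np.asarray(chosen)
    # snap to the implicit boundary along the ray from the tumor center
    snapped = []
    for p in chosen:
        d = p - m["center"]
        t_lo, t_hi = 0.5, 1.5
        g = lambda t: ph.tumor_implicit(m["center"] + t * d)[0] - 1.0
        glo, ghi = g(t_lo), g(t_hi)
        if glo * ghi > 0:
            snapped.append(p)
            continue
        for _ in range(40):
            tm = 0.5 * (t_lo + t_hi)
            if glo * g(tm) <= 0:
                t_hi = tm
            else:
                t_lo, glo = tm, g(tm)
        snapped.append(m["center"] + 0.5 * (t_lo + t_hi) * d)
    names = [f"L{i+1:02d}" for i in range(cfg.landmark_count)]
    return names, np.asarray(snapped)


def simulate_exvivo(ph: Phantom, cfg: Optional[PhantomConfig] = None) -> Phantom:
    """Simulate fixation: shrinkage, small pose offset, smooth deformation."""
    cfg = cfg or ph.cfg
    (rng_pose, rng_def, rng_noise) = _child_rngs(cfg.seed + 1_000_003, 3)
    sp = float(cfg.working_spacing_mm)
    eshape = tuple(cfg.exvivo_shape)
    truth = ph.truth

    volume_ratio = 1.0 - cfg.shrinkage_percent / 100.0  # V_ex / V_in
    if cfg.exvivo_rotation_deg is not None:
        rot = np.radians(np.asarray(cfg.exvivo_rotation_deg, dtype=float))
    else:
        b = np.radians(cfg.exvivo_rotation_bound_deg)
        rot = rng_pose.uniform(-b, b, 3)
    tb = np.asarray(cfg.exvivo_translation_bound_mm, dtype=float)
    tr = rng_pose.uniform(-tb, tb)
    ecenter = (np.asarray(eshape, dtype=float) - 1) / 2 * sp

    gsp = cfg.deform_grid_spacing_mm
    extent = np.asarray(eshape, dtype=float) * sp
    gshape = np.ceil(extent / gsp).astype(int) + 3
    coeffs = rng_def.normal(0.0, cfg.deform_amplitude_mm, (*gshape, 3))
    deform = BSplineTransform3D(np.full(3, gsp), -np.full(3, gsp), coeffs)

    # The raw random field carries a global affine component (mean strain and
    # dilatation over the specimen); the pose and volume change it encodes
    # belong to the similarity part of the model, so project it out — cubic
    # B-splines reproduce affine fields exactly, making the correction exact
    # on the coefficients.  The small residual mean Jacobian is folded into
    # the similarity scale so the *total* programmed volume change equals the
    # configured shrinkage: G: ex -> plane has det = det_sim * v_def and
    # V_ex / V_in = 1 / (det_sim * v_def).
    pts = _grid_points(eshape, sp)
    sim0 = SimilarityTransform3D(angles=rot, translation=tr, center=ecenter,
                                 scale=float((1.0 / volume_ratio) ** (1.0 / 3.0)))
    truth.exvivo_similarity = sim0
    truth.exvivo_deform = deform
    tumor0 = pts[ph.label_exvivo(pts) > 0]
    _remove_affine_component(deform, tumor0)
    # fixed-point calibration: the specimen region itself depends on the
    # calibrated scale, so recompute the mean Jacobian over the updated
    # region until the programmed ratio is met
    sim = sim0
    for _ in range(3):
        truth.exvivo_similarity = sim
        tumor = pts[ph.label_exvivo(pts) > 0]
        v_def = _mean_jacobian(deform, tumor)
        det_sim = 1.0 / (volume_ratio * v_def)
        sim = SimilarityTransform3D(angles=rot, translation=tr, center=ecenter,
                                    scale=float(det_sim ** (1.0 / 3.0)))
    truth.exvivo_similarity = sim

    pts = _grid_points(eshape, sp)
    labels_ex = ph.label_exvivo(pts).reshape(eshape)
    tex_ex = ph.texture_native(
        truth.plane_to_native.apply(truth.map_exvivo_to_plane(pts))).reshape(eshape)
    ph.exvivo = VolumeImage(
        _render(labels_ex, cfg.exvivo_intensities, cfg.psf_sigma_mm / sp, rng_noise,
                texture=tex_ex, gains=cfg.exvivo_texture_gain),
        np.full(3, sp),
    )
    truth.labels["exvivo"] = labels_ex
    names, lm_plane = truth.landmarks["plane"]
    truth.landmarks["exvivo"] = (names, truth.map_plane_to_exvivo(lm_plane))
    truth.programmed["shrinkage_percent"] = cfg.shrinkage_percent
    truth.programmed["exvivo_rotation_deg"] = np.degrees(rot).tolist()
    return ph


def simulate_sections(ph: Phantom, cfg: Optional[PhantomConfig] = None) -> Phantom:
    """Cut jittered, expanded H&E-like RGB sections from the ex vivo phantom."""
    cfg = cfg or ph.cfg
    if ph.exvivo is None:
        raise ValueError("simulate_exvivo must run before simulate_sections")
    ex_extent = ph.exvivo.spacing[2] * (ph.exvivo.shape[2] - 1)
    if cfg.section_interval_mm > ex_extent:
        raise ValueError("section interval exceeds the specimen extent")
    (rng_jit, rng_noise) = _child_rngs(cfg.seed + 2_000_003, 2)
    truth = ph.truth
    px = cfg.section_pixel_mm
    nx, ny = cfg.section_shape
    ctr2 = (np.asarray([nx, ny], dtype=float) - 1) / 2 * px
    lam = float(np.sqrt(1.0 + cfg.expansion_percent / 100.0))  # in-plane linear

    # sectioning starts at the cut face of the specimen (the first mounted
    # section is the first substantial tissue cross-section, not the agar
    # above it): scan along z for the first slice with >= 25 % of the
    # maximal cross-sectional area
    coarse = np.stack(np.meshgrid(np.linspace(0, (nx - 1) * px, 48),
                                  np.linspace(0, (ny - 1) * px, 48),
                                  indexing="ij"), axis=-1).reshape(-1, 2)
    zs = np.arange(0.0, ph.exvivo.spacing[2] * (ph.exvivo.shape[2] - 1),
                   cfg.section_interval_mm)
    areas = np.array([
        np.count_nonzero(ph.label_exvivo(
            np.column_stack([coarse, np.full(coarse.shape[0], z)])) > 0)
        for z in zs])
    substantial = np.where(areas >= 0.25 * areas.max())[0]
    if substantial.size == 0:
        raise ValueError("no tissue found along the sectioning direction")
    z0 = float(zs[substantial[0]])
    truth.stack_z0 = z0

    grid2 = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij"),
                     axis=-1).reshape(-1, 2) * px
    stain_mu = np.zeros((4, 3))
    stain_sd = np.zeros(4)
    for name, code in LABELS.items():
        stain_mu[code] = cfg.stain_rgb[name]
        stain_sd[code] = cfg.stain_background_sigma if name == "background" \
            else cfg.stain_sigma

    sections, jitters, recov, sec_labels = [], [], [], []
    tmax = cfg.jitter_translation_px * px
    amax = np.radians(cfg.jitter_rotation_deg)
    for k in range(cfg.n_sections):
        if k == 0:
            J = Rigid2D(0.0, np.zeros(2), ctr2)  # the anchor is the reference cut
        else:
            J = Rigid2D(rng_jit.uniform(-amax, amax), rng_jit.uniform(-tmax, tmax, 2), ctr2)
        jitters.append(J)
        Jinv = J.inverse()
        recov.append(Rigid2D(Jinv.angle, lam * Jinv.translation, ctr2))
        # section(w) = tissue at ex-vivo point (J(w / lambda about ctr), z_k)
        w = (grid2 - ctr2) / lam + ctr2
        exy = J.apply(w)
        z_k = z0 if cfg.uniform_section_content else z0 + k * cfg.section_interval_mm
        q = np.column_stack([exy, np.full(exy.shape[0], z_k)])
        pl = truth.map_exvivo_to_plane(q)
        lab = ph.label_plane(pl)
        lab[pl[:, 2] < 0.0] = LABELS["background"]
        tex = ph.texture_native(truth.plane_to_native.apply(pl))
        rgb = (stain_mu[lab]
               - cfg.stain_texture_gain * (lab > 0)[:, None] * tex[:, None]
               + rng_noise.standard_normal((lab.size, 3)) * stain_sd[lab, None])
        img = rgb.reshape(nx, ny, 3)
        if cfg.section_blur_px > 0:
            img = ndimage.gaussian_filter(img, (cfg.section_blur_px, cfg.section_blur_px, 0))
        sections.append(np.clip(img, 0, 255).astype(np.float32))
        sec_labels.append(lab.reshape(nx, ny).astype(np.int8))

    ph.sections = SectionStack(sections, pixel_size_mm=px,
                               interval_mm=cfg.section_interval_mm,
                               thickness_mm=cfg.section_thickness_mm)
    truth.slice_jitters = jitters
    truth.section_labels = sec_labels
    truth.stacking_transforms = recov
    truth.stack_scale = lam
    truth.stack2ex_affine = AffineTransform3D(
        np.diag([lam, lam, 1.0]), np.array([0.0, 0.0, -z0]),
        np.array([ctr2[0], ctr2[1], 0.0]))
    # canonical (jitter-free) stack frame: in-plane expansion of ex vivo coords
    names, lm_ex = truth.landmarks["exvivo"]
    truth.landmarks["stack"] = (names, truth.stack2ex_affine.apply(lm_ex))
    # where each landmark is seen on its nearest raw section (the coordinates
    # an annotator reading the mounted slides would record)
    ks = np.clip(np.round((lm_ex[:, 2] - z0) / cfg.section_interval_mm).astype(int),
                 0, cfg.n_sections - 1)
    w2d = np.array([
        lam * (jitters[k].inverse().apply(p[:2]) - ctr2) + ctr2
        for k, p in zip(ks, lm_ex)])
    truth.landmark_sections = (names, ks, w2d)
    stack_shape = (nx, ny, cfg.n_sections)
    spts = _grid_points(stack_shape, 1.0)
    spts *= np.array([px, px, cfg.section_interval_mm])
    inv = truth.stack2ex_affine.inverse()
    truth.labels["stack"] = ph.label_exvivo(inv.apply(spts)).reshape(stack_shape)
    truth.programmed["expansion_percent"] = cfg.expansion_percent
    return ph


def generate(cfg: PhantomConfig) -> Phantom:
    """Run all three generators (in vivo, ex vivo, sections)."""
    return simulate_sections(simulate_exvivo(generate_invivo(cfg)))
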