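"""Similarity metrics, multiresolution pyramid and the registration driver.

The metric implementations (mutual information from a joint histogram with
partial-volume linear binning, normalized correlation, mean squared
difference) are pure numpy and are used for full-sampling stage evaluations
and the acceptance guard in :func:`optimize`.  The iterative optimization
itself is delegated to SimpleITK's registration framework (multi-resolution
gradient descent with seeded random sampling), configured from
:class:`RegistrationConfig`; runs are fully reproducible for a fixed seed
(single-threaded execution is forced during optimization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .image import VolumeImage, interpolate, resample
from .transforms import (
    AffineTransform3D,
    BSplineTransform3D,
    CompositeTransform,
    RigidTransform3D,
    SimilarityTransform3D,
    Transform,
    compose,
    from_sitk,
    to_sitk,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MetricError",
    "OverlapError",
    "RegistrationConfig",
    "MetricValue",
    "mutual_information",
    "normalized_correlation",
    "mean_squared_difference",
    "build_pyramid",
    "optimize",
    "register",
    "register_sections_2d",
]


class MetricError(ValueError):
    """Degenerate metric input (empty sample set, flat intensities)."""


class OverlapError(RuntimeError):
    """Fixed and moving images do not overlap under the initialization."""


@dataclass
class RegistrationConfig:
    """Settings for one registration stage.

    Parameters
    ----------
    metric : str
        ``mutual_information`` (inter-modality default), ``normalized_correlation``
        (mono-modal, robust to staining intensity drift) or
        ``mean_squared_difference``.
    histogram_bins : int
        Joint-histogram bins per axis for MI (>= 8).
    samples_per_iteration : int
        Fixed-image samples per metric evaluation; when it meets or exceeds
        the (masked) fixed region size — as with the default — every voxel
        is used and the run is fully deterministic.
    shrink_factors, smoothing_sigmas : sequence
        Per-level downsampling factors and Gaussian widths (voxels), coarse to
        fine; the finest level is the original resolution.
    iterations_per_level : int
        Optimizer iterations at each pyramid level.
    step_length : float
        Initial step length (mm) of the gradient-descent line search.
    bspline_grid_spacing_mm : float
        Control-point spacing of the elastic stage.
    random_seed : int
        Seeds the metric sampler; a fixed seed makes runs bit-reproducible.
    fixed_mask : ndarray or None
        Binary mask on the fixed grid restricting the metric to tumor tissue
        (excluding surrounding tissue / agar).
    """

    metric: str = "mutual_information"
    histogram_bins: int = 32
    samples_per_iteration: int = 1_000_000
    shrink_factors: Sequence[int] = (2, 1)
    smoothing_sigmas: Sequence[float] = (1.0, 0.0)
    iterations_per_level: int = 300
    step_length: float = 0.5
    bspline_grid_spacing_mm: float = 4.8
    bspline_iterations: int = 60
    bspline_shrink_factors: Sequence[int] = (2, 1)
    bspline_smoothing_sigmas: Sequence[float] = (1.0, 0.0)
    random_seed: int = 0
    fixed_mask: Optional[np.ndarray] = None
    moving_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.histogram_bins < 8:
            raise ValueError("histogram_bins must be >= 8")
        if len(self.shrink_factors) < 1:
            raise ValueError("at least one pyramid level required")
        if len(self.shrink_factors) != len(self.smoothing_sigmas):
            raise ValueError("shrink_factors and smoothing_sigmas must align")
        if self.metric not in (
            "mutual_information", "normalized_correlation", "mean_squared_difference"
        ):
            raise ValueError(f"unknown metric {self.metric!r}")

    def with_(self, **kw) -> "RegistrationConfig":
        return replace(self, **kw)


@dataclass
class MetricValue:
    """A metric evaluation: cost (lower = better) and optional gradient."""

    value: float
    gradient: Optional[np.ndarray] = None


def _paired_samples(fixed: VolumeImage, moving: VolumeImage, t, cfg: RegistrationConfig,
                    full_sampling: bool):
    """Fixed/moving intensity pairs at (sampled) fixed grid points mapped through t."""
    mask = cfg.fixed_mask
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != fixed.shape:
            raise MetricError("fixed_mask shape does not match the fixed image")
        idx = np.argwhere(mask)
    else:
        nx, ny, nz = fixed.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
    if idx.shape[0] == 0:
        raise MetricError("empty sample set: the fixed mask excludes everything")
    if not full_sampling and cfg.samples_per_iteration < idx.shape[0]:
        rng = np.random.default_rng(cfg.random_seed)
        sel = rng.choice(idx.shape[0], size=cfg.samples_per_iteration, replace=False)
        idx = idx[sel]
    pts = fixed.world_from_index(idx.astype(float))
    fvals = fixed.values[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    if t is not None:
        pts = t.apply(pts)
    midx = moving.index_from_world(pts)
    nvec = np.asarray(moving.shape) - 1
    inside = np.all((midx >= 0) & (midx <= nvec), axis=1)
    if not np.any(inside):
        raise MetricError("no sampled point maps inside the moving image domain")
    midx_in = midx[inside]
    fvals = fvals[inside]
    if cfg.moving_mask is not None:
        mm = ndimage.map_coordinates(
            np.asarray(cfg.moving_mask, dtype=np.uint8), midx_in.T, order=0, mode="constant"
        ).astype(bool)
        if not np.any(mm):
            raise MetricError("no sampled point maps inside the moving mask")
        midx_in, fvals = midx_in[mm], fvals[mm]
    mvals = ndimage.map_coordinates(
        np.asarray(moving.values, dtype=float), midx_in.T, order=1, mode="constant"
    )
    return fvals, mvals


def _pv_histogram(f: np.ndarray, m: np.ndarray, bins: int) -> np.ndarray:
    """Joint histogram with linear (partial-volume style) binning.

    Each sample distributes unit mass bilinearly between the two nearest bins
    on each axis; samples whose value coincides with a bin center contribute
    to that bin only, so integer-valued fixtures reduce to hard binning.
    """

    def coords(v):
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:
            return np.zeros_like(v)
        z = (v - lo) / (hi - lo) * bins - 0.5
        return np.clip(z, 0.0, bins - 1.0)

    zf, zm = coords(f), coords(m)
    f0 = np.floor(zf).astype(int)
    m0 = np.floor(zm).astype(int)
    wf = zf - f0
    wm = zm - m0
    f1 = np.minimum(f0 + 1, bins - 1)
    m1 = np.minimum(m0 + 1, bins - 1)
    hist = np.zeros((bins, bins))
    np.add.at(hist, (f0, m0), (1 - wf) * (1 - wm))
    np.add.at(hist, (f0, m1), (1 - wf) * wm)
    np.add.at(hist, (f1, m0), wf * (1 - wm))
    np.add.at(hist, (f1, m1), wf * wm)
    return hist


def mi_from_joint_histogram(hist: np.ndarray) -> float:
    """Mutual information (bits) of a joint histogram; always >= 0."""
    p = hist / hist.sum()
    pf = p.sum(axis=1, keepdims=True)
    pm = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (pf @ pm)[nz])))


def mutual_information(fixed: VolumeImage, moving: VolumeImage, t: Optional[Transform],
                       cfg: RegistrationConfig, full_sampling: bool = True) -> MetricValue:
    """Negative mutual information of fixed/moving intensities under ``t``.

    MI (bits) is computed from a joint histogram over sampled fixed-image
    points mapped through ``t`` into the moving image; the returned cost is
    ``-MI`` so that lower is better.
    """
    f, m = _paired_samples(fixed, moving, t, cfg, full_sampling)
    if np.unique(f).size < 2 or np.unique(m).size < 2:
        raise MetricError("metric needs >= 2 distinct intensities in each image")
    hist = _pv_histogram(f, m, cfg.histogram_bins)
    return MetricValue(value=-mi_from_joint_histogram(hist))


def normalized_correlation(fixed: VolumeImage, moving: VolumeImage, t: Optional[Transform],
                           cfg: RegistrationConfig, full_sampling: bool = True) -> MetricValue:
    """Negative absolute Pearson correlation of paired intensities, in [-1, 0]."""
    f, m = _paired_samples(fixed, moving, t, cfg, full_sampling)
    if f.std() == 0 or m.std() == 0:
        raise MetricError("zero variance in the sampled intensities")
    r = float(np.corrcoef(f, m)[0, 1])
    return MetricValue(value=-abs(r))


def mean_squared_difference(fixed: VolumeImage, moving: VolumeImage, t: Optional[Transform],
                            cfg: RegistrationConfig, full_sampling: bool = True) -> MetricValue:
    """Mean squared intensity difference (mono-modal, same intensity scale)."""
    f, m = _paired_samples(fixed, moving, t, cfg, full_sampling)
    return MetricValue(value=float(np.mean((f - m) ** 2)))


_METRICS = {
    "mutual_information": mutual_information,
    "normalized_correlation": normalized_correlation,
    "mean_squared_difference": mean_squared_difference,
}


def evaluate_metric(fixed, moving, t, cfg, full_sampling: bool = True) -> float:
    """Full-sampling cost of ``t`` under the configured metric."""
    return _METRICS[cfg.metric](fixed, moving, t, cfg, full_sampling).value


def build_pyramid(image: VolumeImage, cfg: RegistrationConfig) -> list:
    """Gaussian pyramid, coarse to fine; the finest level is the original.

    Level k is smoothed with ``smoothing_sigmas[k]`` (voxels) and subsampled
    by ``shrink_factors[k]``.  Factors too large for the image are dropped
    with a warning.
    """
    levels = []
    for factor, sigma in zip(cfg.shrink_factors, cfg.smoothing_sigmas):
        if min(image.shape) // factor < 4:
            logger.warning(
                "pyramid level with factor %d skipped: image %s too small", factor, image.shape
            )
            continue
        vals = np.asarray(image.values, dtype=float)
        if sigma > 0:
            vals = ndimage.gaussian_filter(vals, sigma)
        sub = vals[::factor, ::factor, ::factor]
        levels.append(VolumeImage(sub, image.spacing * factor, image.origin.copy(),
                                  image.direction.copy()))
    if not levels:
        levels = [image]
    return levels


# ---------------------------------------------------------------------------
# SimpleITK engine


def _to_sitk_image(image: VolumeImage, dtype=np.float32):
    import SimpleITK as sitk

    arr = np.ascontiguousarray(np.asarray(image.values, dtype=dtype).T)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in image.spacing))
    img.SetOrigin(tuple(float(o) for o in image.origin))
    img.SetDirection(tuple(float(d) for d in image.direction.ravel()))
    return img


def _to_sitk_mask(mask: np.ndarray, like: VolumeImage):
    import SimpleITK as sitk

    arr = np.ascontiguousarray(np.asarray(mask, dtype=np.uint8).T)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in like.spacing))
    img.SetOrigin(tuple(float(o) for o in like.origin))
    img.SetDirection(tuple(float(d) for d in like.direction.ravel()))
    return img


def _configure_metric(R, cfg: RegistrationConfig, n_fixed: int, deterministic: bool):
    import SimpleITK as sitk

    if cfg.metric == "mutual_information":
        R.SetMetricAsMattesMutualInformation(numberOfHistogramBins=cfg.histogram_bins)
    elif cfg.metric == "normalized_correlation":
        R.SetMetricAsCorrelation()
    else:
        R.SetMetricAsMeanSquares()
    if deterministic or cfg.samples_per_iteration >= n_fixed:
        R.SetMetricSamplingStrategy(R.NONE)
    else:
        frac = min(1.0, cfg.samples_per_iteration / max(n_fixed, 1))
        R.SetMetricSamplingStrategy(R.REGULAR)
        R.SetMetricSamplingPercentage(frac, int(cfg.random_seed) % (2**31 - 1))
    R.SetInterpolator(sitk.sitkLinear)


def _run_sitk(fixed: VolumeImage, moving: VolumeImage, sitk_t0, cfg: RegistrationConfig,
              bspline: bool):
    import SimpleITK as sitk

    saved_threads = sitk.ProcessObject.GetGlobalDefaultNumberOfThreads()
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)  # reproducibility
    try:
        R = sitk.ImageRegistrationMethod()
        fimg = _to_sitk_image(fixed)
        mimg = _to_sitk_image(moving)
        n_fixed = int(np.prod(fixed.shape)) if cfg.fixed_mask is None else int(
            np.count_nonzero(cfg.fixed_mask))
        _configure_metric(R, cfg, n_fixed, deterministic=bspline)
        if cfg.fixed_mask is not None:
            R.SetMetricFixedMask(_to_sitk_mask(cfg.fixed_mask, fixed))
        if cfg.moving_mask is not None:
            R.SetMetricMovingMask(_to_sitk_mask(cfg.moving_mask, moving))
        shrink = cfg.bspline_shrink_factors if bspline else cfg.shrink_factors
        sigmas = cfg.bspline_smoothing_sigmas if bspline else cfg.smoothing_sigmas
        R.SetShrinkFactorsPerLevel([int(f) for f in shrink])
        R.SetSmoothingSigmasPerLevel([float(s) for s in sigmas])
        R.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)
        if bspline:
            R.SetOptimizerAsLBFGSB(
                gradientConvergenceTolerance=1e-7,
                numberOfIterations=cfg.bspline_iterations,
                maximumNumberOfCorrections=5,
                maximumNumberOfFunctionEvaluations=2000,
            )
        else:
            R.SetOptimizerAsRegularStepGradientDescent(
                learningRate=cfg.step_length,
                minStep=1e-5,
                numberOfIterations=cfg.iterations_per_level,
                relaxationFactor=0.6,
                gradientMagnitudeTolerance=1e-7,
            )
            R.SetOptimizerScalesFromPhysicalShift()
        R.SetInitialTransform(sitk_t0, inPlace=True)
        params_before = sitk_t0.GetParameters()
        try:
            R.Execute(fimg, mimg)
        except RuntimeError as exc:
            # optimizer wandered out of the moving image buffer: fall back to
            # the initialization (the caller's guard keeps the better of the
            # two anyway)
            logger.warning("optimization diverged (%s); keeping initialization",
                           str(exc).splitlines()[-1])
            sitk_t0.SetParameters(params_before)
        return sitk_t0
    finally:
        sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(saved_threads)


def optimize(fixed: VolumeImage, moving: VolumeImage, t0: Transform,
             cfg: RegistrationConfig) -> Transform:
    """Optimize ``t0``'s parameters to align ``moving`` to ``fixed``.

    A multi-resolution gradient-descent run (seeded, reproducible) refines
    the transform; the result is accepted only if its full-sampling metric is
    no worse than ``t0``'s, otherwise ``t0`` is returned unchanged.
    """
    is_bspline = isinstance(t0, BSplineTransform3D)
    result = from_sitk(_run_sitk(fixed, moving, to_sitk(t0), cfg, bspline=is_bspline))
    before = evaluate_metric(fixed, moving, t0, cfg)
    after = evaluate_metric(fixed, moving, result, cfg)
    if not np.isfinite(after):
        raise MetricError("non-finite metric after optimization")
    if after > before:
        logger.info("optimize: result (%.6f) worse than init (%.6f); keeping init",
                    after, before)
        return t0
    logger.info("optimize: metric %.6f -> %.6f", before, after)
    return result


def check_overlap(fixed: VolumeImage, moving: VolumeImage, init: Optional[Transform],
                  cfg: RegistrationConfig, min_fraction: float = 0.10) -> float:
    """Fraction of fixed(-mask) points mapping inside the moving domain."""
    mask = cfg.fixed_mask
    if mask is not None:
        idx = np.argwhere(np.asarray(mask).astype(bool))
    else:
        nx, ny, nz = fixed.shape
        idx = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
    rng = np.random.default_rng(cfg.random_seed)
    if idx.shape[0] > 4096:
        idx = idx[rng.choice(idx.shape[0], 4096, replace=False)]
    pts = fixed.world_from_index(idx.astype(float))
    if init is not None:
        pts = init.apply(pts)
    midx = moving.index_from_world(pts)
    nvec = np.asarray(moving.shape) - 1
    frac = float(np.mean(np.all((midx >= 0) & (midx <= nvec), axis=1)))
    if frac < min_fraction:
        raise OverlapError(
            f"only {frac:.1%} of fixed points map inside the moving image; "
            "the initialization (reference-plane alignment) is the likely cause"
        )
    return frac


def _default_bspline(fixed: VolumeImage, spacing_mm) -> BSplineTransform3D:
    """Zero-coefficient B-spline whose control grid covers the fixed domain
    plus a one-control-point margin on each side.  ``spacing_mm`` may be a
    scalar or a per-axis triple (e.g. finer along a thin slab axis)."""
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), 3).copy()
    lo = fixed.world_from_index((0.0, 0.0, 0.0))
    hi = fixed.world_from_index(np.asarray(fixed.shape, dtype=float) - 1)
    bmin, bmax = np.minimum(lo, hi), np.maximum(lo, hi)
    extent = bmax - bmin
    n_inner = np.maximum(1, np.ceil(extent / spacing).astype(int))
    shape = n_inner + 3  # cubic spline needs a margin of one control point
    origin = bmin - spacing
    return BSplineTransform3D(spacing, origin, np.zeros((*shape, 3)))


def register(fixed: VolumeImage, moving: VolumeImage, model: str,
             cfg: RegistrationConfig, init: Optional[Transform] = None) -> Transform:
    """Single-stage registration for one transform model.

    ``model`` is ``rigid``, ``similarity``, ``affine`` or ``bspline``.  For the
    linear models ``init`` (a transform of the same family or simpler) seeds
    the parameters; the B-spline stage treats ``init`` as the preceding
    stage's output — the moving image is pulled through it onto the fixed
    grid and the returned transform is ``compose(bspline, init)``.
    Transform centers default to the fixed image's world center.
    """
    check_overlap(fixed, moving, init, cfg)
    center = fixed.center()
    if model == "rigid":
        t0 = RigidTransform3D(center=center)
        if isinstance(init, RigidTransform3D):
            t0 = RigidTransform3D(init.angles.copy(), init.translation.copy(), init.center.copy())
        elif init is not None:
            raise TypeError("rigid stage accepts only a rigid initialization")
        return optimize(fixed, moving, t0, cfg)
    if model == "similarity":
        if init is None:
            t0 = SimilarityTransform3D(center=center)
        elif isinstance(init, SimilarityTransform3D):
            t0 = SimilarityTransform3D(init.angles.copy(), init.translation.copy(),
                                       init.center.copy(), init.scale)
        elif isinstance(init, RigidTransform3D):
            t0 = SimilarityTransform3D(init.angles.copy(), init.translation.copy(),
                                       init.center.copy(), 1.0)
        else:
            raise TypeError("similarity stage accepts rigid or similarity initialization")
        return optimize(fixed, moving, t0, cfg)
    if model == "affine":
        if init is None:
            t0 = AffineTransform3D(center=center)
        elif isinstance(init, (RigidTransform3D, SimilarityTransform3D)):
            t0 = AffineTransform3D(init.matrix.copy(), init.translation.copy(),
                                   init.center.copy())
        elif isinstance(init, AffineTransform3D):
            t0 = AffineTransform3D(init.matrix.copy(), init.translation.copy(),
                                   init.center.copy())
        else:
            raise TypeError("affine stage accepts rigid/similarity/affine initialization")
        return optimize(fixed, moving, t0, cfg)
    if model == "bspline":
        t0 = _default_bspline(fixed, cfg.bspline_grid_spacing_mm)
        if init is None:
            return optimize(fixed, moving, t0, cfg)
        fill = float(np.median(np.concatenate([moving.values[0].ravel(),
                                               moving.values[-1].ravel()])))
        moving_stage = resample(moving, init, fixed, scheme="linear", fill=fill)
        if cfg.moving_mask is not None:
            mask_img = VolumeImage(np.asarray(cfg.moving_mask, dtype=np.uint8),
                                   moving.spacing, moving.origin, moving.direction)
            mm = resample(mask_img, init, fixed, scheme="nearest", fill=0.0)
            cfg = cfg.with_(moving_mask=mm.values.astype(bool))
        bspline = optimize(fixed, moving_stage, t0, cfg)
        return compose(bspline, init)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# 2D rigid registration (section stacking)


def register_sections_2d(fixed2d: np.ndarray, moving2d: np.ndarray, pixel_size_mm: float,
                         cfg: RegistrationConfig, init=None):
    """2D rigid registration of one section to its aligned predecessor.

    Returns a :class:`~histomri.transforms.Rigid2D` mapping aligned-frame
    world points into the raw section (pull-back).
    """
    import SimpleITK as sitk

    from .transforms import Rigid2D

    saved = sitk.ProcessObject.GetGlobalDefaultNumberOfThreads()
    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    try:
        def img2d(arr):
            im = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(arr, float).T))
            im.SetSpacing((pixel_size_mm, pixel_size_mm))
            return im

        center = (np.asarray(fixed2d.shape, dtype=float) - 1) / 2 * pixel_size_mm
        t0 = init if init is not None else Rigid2D(center=center)
        s0 = sitk.Euler2DTransform()
        s0.SetCenter(tuple(t0.center))
        s0.SetAngle(float(t0.angle))
        s0.SetTranslation(tuple(t0.translation))
        R = sitk.ImageRegistrationMethod()
        R.SetMetricAsCorrelation()
        R.SetMetricSamplingStrategy(R.NONE)
        R.SetInterpolator(sitk.sitkLinear)
        factors = [f for f in (4, 2, 1) if min(fixed2d.shape) // f >= 8]
        R.SetShrinkFactorsPerLevel(factors)
        R.SetSmoothingSigmasPerLevel([f / 2.0 for f in factors])
        R.SetSmoothingSigmasAreSpecifiedInPhysicalUnits(False)
        R.SetOptimizerAsRegularStepGradientDescent(
            learningRate=0.5, minStep=1e-6, numberOfIterations=cfg.iterations_per_level,
            relaxationFactor=0.6, gradientMagnitudeTolerance=1e-8,
        )
        R.SetOptimizerScalesFromPhysicalShift()
        R.SetInitialTransform(s0, inPlace=True)
        R.Execute(img2d(fixed2d), img2d(moving2d))
        return Rigid2D(s0.GetAngle(), np.array(s0.GetTranslation()), np.array(s0.GetCenter()))
    finally:
        sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(saved)
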