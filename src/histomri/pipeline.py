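"""The registration pipeline: stacking, stack2ex, ex2in and stack2in.

The bottom-up path reconstructs a 3D histology volume by rigid 2D stacking
of serial sections, registers it to the ex vivo MRI (stack2ex: rigid, full
affine, then B-spline), registers the ex vivo MRI to the reference-plane-
realigned in vivo MRI (ex2in: rigid, similarity with isotropic scaling, then
B-spline), and concatenates the two results automatically (stack2in) to warp
the color histology stack onto the in vivo grid.

All 3D transforms follow the pull-back convention: a stage's transform maps
fixed-image world points into its moving image.  The histology stack is
moving in stack2ex (fixed: ex vivo MRI); the ex vivo MRI is moving in ex2in
(fixed: realigned in vivo MRI), so the concatenation ex2in-then-stack2ex
pulls histology all the way onto the in vivo grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .image import SectionStack, VolumeImage, extract_channel, resample, resample_section
from .registration import RegistrationConfig, evaluate_metric, register, register_sections_2d
from .transforms import (
    AffineTransform3D,
    BSplineTransform3D,
    CompositeTransform,
    Rigid2D,
    RigidTransform3D,
    SimilarityTransform3D,
    compose,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StackingResult",
    "StageResult",
    "Stack2InResult",
    "select_registration_channel",
    "stack_sections",
    "stack2ex",
    "ex2in",
    "stack2in",
    "stage_composites",
]

CHANNEL_NAMES = ("red", "green", "blue")


@dataclass
class PipelineConfig:
    """Per-stage registration settings.

    Stacking is mono-modal (H&E to H&E) and uses normalized correlation;
    the two volumetric steps are inter-modality and use mutual information.
    ``ex2in_affine_model`` defaults to a 7-DOF similarity (rigid + isotropic
    scale, modelling global fixation volume change); a full 12-DOF affine
    can be selected instead.
    """

    stacking: RegistrationConfig = field(default_factory=lambda: RegistrationConfig(
        metric="normalized_correlation", iterations_per_level=200))
    stack2ex: RegistrationConfig = field(default_factory=lambda: RegistrationConfig(
        metric="mutual_information"))
    ex2in: RegistrationConfig = field(default_factory=lambda: RegistrationConfig(
        metric="mutual_information"))
    ex2in_affine_model: str = "similarity"
    remove_stacking_drift: bool = False
    mask_dilation_mm: float = 2.0
    driver_channel: str = "red"

    def __post_init__(self):
        if self.ex2in_affine_model not in ("similarity", "affine"):
            raise ValueError("ex2in_affine_model must be 'similarity' or 'affine'")


@dataclass
class StackingResult:
    """A reconstructed 3D histology stack.

    ``volume`` is (nx, ny, n_sections, 3) with slice spacing set to the
    physical inter-section interval; ``per_slice_transforms`` are pull-back
    2D rigids (stack frame -> raw section), identity for the anchor
    section 0 (the reference cutting plane).
    """

    volume: np.ndarray
    per_slice_transforms: list
    driver_channel: str
    per_slice_metrics: list
    pixel_size_mm: float
    interval_mm: float
    failed_sections: list = field(default_factory=list)

    def channel_volume(self, channel) -> VolumeImage:
        i = CHANNEL_NAMES.index(channel) if isinstance(channel, str) else int(channel)
        return VolumeImage(
            self.volume[:, :, :, i],
            np.array([self.pixel_size_mm, self.pixel_size_mm, self.interval_mm]),
        )

    @property
    def driver_volume(self) -> VolumeImage:
        return self.channel_volume(self.driver_channel)


@dataclass
class StageResult:
    """One three-step registration: rigid -> affine/similarity -> elastic.

    ``composite`` maps fixed-image points to moving-image points and equals
    the elastic stage applied first, then the affine (which already refines
    the rigid): metric values are recorded per stage at full sampling.
    """

    rigid: Optional[RigidTransform3D] = None
    affine: object = None
    elastic: Optional[BSplineTransform3D] = None
    composite: object = None
    metrics: dict = field(default_factory=dict)


@dataclass
class Stack2InResult:
    """The concatenated stack2in warp and the histology warped onto in vivo."""

    composite: CompositeTransform
    warped: np.ndarray  # (nx, ny, nz, 3) on the in vivo grid
    grid: VolumeImage


def _hist_overlap_score(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Separability = 1 - Bhattacharyya overlap of normalized histograms."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 0.0
    ha, _ = np.histogram(a, bins=bins, range=(lo, hi))
    hb, _ = np.histogram(b, bins=bins, range=(lo, hi))
    pa = ha / ha.sum()
    pb = hb / hb.sum()
    return float(1.0 - np.sum(np.sqrt(pa * pb)))


def select_registration_channel(stack: SectionStack, necrotic_voi: np.ndarray,
                                viable_voi: np.ndarray, section_index: int = 0,
                                bins: int = 64):
    """Choose the color channel separating necrotic from viable tissue best.

    Scores each channel by one minus the Bhattacharyya overlap of the two
    VOIs' normalized intensity histograms on the annotated section; ties
    break toward red.  Returns ``(channel_name, scores_dict)``.
    """
    nec = np.asarray(necrotic_voi).astype(bool)
    via = np.asarray(viable_voi).astype(bool)
    if not nec.any() or not via.any():
        raise ValueError("both VOIs must be non-empty on the annotated section")
    section = stack.sections[section_index]
    scores = {}
    for ci, name in enumerate(CHANNEL_NAMES):
        chan = section[:, :, ci]
        scores[name] = _hist_overlap_score(chan[nec], chan[via], bins=bins)
    best = max(CHANNEL_NAMES, key=lambda n: scores[n])  # ties break toward red
    return best, scores


def _remove_drift(transforms: list) -> list:
    """Subtract a linear trend from accumulated translations (anchor fixed)."""
    k = np.arange(len(transforms), dtype=float)
    t = np.array([tr.translation for tr in transforms])
    out = []
    for tr, kk in zip(transforms, k):
        fit = np.empty(2)
        for ax in range(2):
            slope = np.polyfit(k, t[:, ax], 1)[0]
            fit[ax] = slope * kk
        out.append(Rigid2D(tr.angle, tr.translation - fit, tr.center))
    return out


def stack_sections(stack: SectionStack, cfg: RegistrationConfig,
                   driver_channel: str = "red",
                   remove_drift: bool = False) -> StackingResult:
    """Reconstruct a 3D volume by iterative rigid registration of sections.

    Each section is rigidly registered (2D, driver channel) to its already-
    aligned predecessor; transforms accumulate outward from the anchor
    (section 0, the reference cutting plane) and are applied to all three
    color channels.  The output slice spacing is the physical inter-section
    interval.
    """
    if len(stack) < 2:
        raise ValueError("stacking needs >= 2 sections")
    px = stack.pixel_size_mm
    driver = extract_channel(stack, driver_channel)
    ctr = (np.asarray(stack.section_shape, dtype=float) - 1) / 2 * px
    transforms = [Rigid2D(0.0, np.zeros(2), ctr)]
    metrics = [0.0]
    failed = []
    aligned_prev = driver[0]
    for i in range(1, len(stack)):
        prev = transforms[-1]
        init = Rigid2D(prev.angle, prev.translation.copy(), prev.center.copy())
        fill = float(np.median(driver[i][[0, -1], :]))  # slide background
        try:
            t_i = register_sections_2d(aligned_prev, driver[i], px, cfg, init=init)
            aligned_i = resample_section(driver[i], t_i, px, fill=fill)
            a, b = aligned_prev.ravel(), aligned_i.ravel()
            ok = a.std() > 0 and b.std() > 0
            m = -abs(float(np.corrcoef(a, b)[0, 1])) if ok else 0.0
        except Exception as exc:  # overlap / degenerate-metric failures
            logger.warning("section %d registration failed (%s); keeping previous pose",
                           i, exc)
            failed.append(i)
            t_i = Rigid2D(prev.angle, prev.translation.copy(), prev.center.copy())
            aligned_i = resample_section(driver[i], t_i, px)
            m = np.nan
        transforms.append(t_i)
        metrics.append(m)
        aligned_prev = aligned_i
    if remove_drift:
        transforms = _remove_drift(transforms)
    nx, ny = stack.section_shape
    volume = np.zeros((nx, ny, len(stack), 3), dtype=np.float32)
    for k, (sec, t_k) in enumerate(zip(stack.sections, transforms)):
        for c in range(3):
            fill = float(np.median(sec[:, :, c][[0, -1], :]))  # border background
            volume[:, :, k, c] = resample_section(sec[:, :, c], t_k, px, fill=fill)
    return StackingResult(volume, transforms, driver_channel, metrics, px,
                          stack.interval_mm, failed)


def _stage_metrics(fixed, moving, cfg, stages: dict) -> dict:
    out = {}
    for name, t in stages.items():
        try:
            out[name] = evaluate_metric(fixed, moving, t, cfg)
        except Exception as exc:
            logger.warning("metric evaluation failed for stage %s: %s", name, exc)
            out[name] = np.nan
    return out


def _com(values: np.ndarray, fg: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(fg)
    return idx.mean(axis=0) * np.asarray(spacing)


def _dilate(mask: np.ndarray, spacing, mm: float) -> np.ndarray:
    it = max(1, int(round(mm / float(np.min(spacing)))))
    return ndimage.binary_dilation(np.asarray(mask).astype(bool), iterations=it)


def _stage_configs(cfg: RegistrationConfig, fixed_grid: VolumeImage,
                   fixed_tumor_mask, moving_tumor_mask, dilation_mm: float):
    """Mask policy: linear stages see a dilated fixed mask (the tumor plus a
    margin that anchors its boundary); the elastic stage is restricted to
    tumor tissue on both sides (a loose mask lets the many B-spline DOFs
    drift in structureless background)."""
    if fixed_tumor_mask is None:
        return cfg, cfg
    lin = cfg.with_(fixed_mask=_dilate(fixed_tumor_mask, fixed_grid.spacing, dilation_mm),
                    moving_mask=None)
    ela = cfg.with_(fixed_mask=np.asarray(fixed_tumor_mask).astype(bool),
                    moving_mask=None if moving_tumor_mask is None
                    else np.asarray(moving_tumor_mask).astype(bool))
    return lin, ela


def stack2ex(stacking: StackingResult, exvivo: VolumeImage,
             cfg: RegistrationConfig,
             fixed_tumor_mask: Optional[np.ndarray] = None,
             moving_foreground: Optional[np.ndarray] = None,
             mask_dilation_mm: float = 2.0) -> StageResult:
    """Register the histology stack (moving) to the ex vivo MRI (fixed).

    Both volumes start at the reference cutting plane, which initializes the
    out-of-plane pose; the in-plane offset is initialized by aligning the
    foreground centers of mass.  Three steps: rigid, full 12-DOF affine,
    B-spline refinement.
    """
    moving = stacking.driver_volume
    if moving_foreground is None:
        # H&E sections: tissue is darker than the white slide background
        moving_foreground = np.min(stacking.volume, axis=3) < 200.0
    fixed_fg = np.asarray(fixed_tumor_mask).astype(bool) if fixed_tumor_mask is not None \
        else exvivo.values > np.percentile(exvivo.values, 75)
    cfg_lin, cfg_el = _stage_configs(cfg, exvivo, fixed_tumor_mask, moving_foreground,
                                     mask_dilation_mm)
    com_f = _com(exvivo.values, fixed_fg, exvivo.spacing)
    com_m = _com(moving.values, moving_foreground, moving.spacing)
    shift = com_m - com_f
    shift[2] = 0.0  # the shared reference plane fixes the out-of-plane start
    init = RigidTransform3D(translation=shift, center=exvivo.center())
    rigid = register(exvivo, moving, "rigid", cfg_lin, init=init)
    affine = register(exvivo, moving, "affine", cfg_lin, init=rigid)
    elastic_comp = register(exvivo, moving, "bspline", cfg_el, init=affine)
    elastic = elastic_comp.transforms[0]
    metrics = _stage_metrics(exvivo, moving, cfg_el, {
        "initial": init, "rigid": rigid, "affine": affine, "elastic": elastic_comp})
    return StageResult(rigid, affine, elastic, elastic_comp, metrics)


def ex2in(exvivo: VolumeImage, invivo_realigned: VolumeImage,
          cfg: RegistrationConfig, affine_model: str = "similarity",
          fixed_tumor_mask: Optional[np.ndarray] = None,
          moving_tumor_mask: Optional[np.ndarray] = None,
          mask_dilation_mm: float = 2.0,
          models: tuple = ("rigid", "affine", "bspline")) -> StageResult:
    """Register the ex vivo MRI (moving) to the realigned in vivo MRI (fixed).

    The in vivo volume must already be resampled into the reference-plane
    frame, which provides the initialization.  Three steps: rigid, affine
    with isotropic scaling (similarity; its scale**3 reports the global
    fixation volume change) and B-spline refinement.  ``models`` may name a
    prefix of the three steps to stop early (e.g. rigid only for
    reference-plane angulation experiments).
    """
    cfg_lin, cfg_el = _stage_configs(cfg, invivo_realigned, fixed_tumor_mask,
                                     moving_tumor_mask, mask_dilation_mm)
    rigid = affine = elastic = None
    last = None
    stages = {"initial": None}
    if "rigid" in models:
        rigid = register(invivo_realigned, exvivo, "rigid", cfg_lin, init=None)
        stages["rigid"] = last = rigid
    if "affine" in models:
        affine = register(invivo_realigned, exvivo, affine_model, cfg_lin, init=last)
        stages["affine"] = last = affine
    if "bspline" in models:
        elastic_comp = register(invivo_realigned, exvivo, "bspline", cfg_el, init=last)
        elastic = elastic_comp.transforms[0]
        stages["elastic"] = last = elastic_comp
    metrics = _stage_metrics(invivo_realigned, exvivo, cfg_el, stages)
    return StageResult(rigid, affine, elastic, last, metrics)


def stage_composites(s2e: StageResult, e2i: StageResult) -> dict:
    """Per-stage stack2in transforms (in vivo point -> stack point)."""
    return {
        "rigid": compose(e2i.rigid, s2e.rigid),
        "affine": compose(e2i.affine, s2e.affine),
        "elastic": compose(e2i.composite, s2e.composite),
    }


def stack2in(s2e: StageResult, e2i: StageResult, color_stack: StackingResult,
             invivo_grid: VolumeImage) -> Stack2InResult:
    """Concatenate stack2ex and ex2in and warp the color stack onto in vivo.

    The composite applies the ex2in result first (in vivo -> ex vivo), then
    the stack2ex result (ex vivo -> stack); each color channel is warped
    independently with linear interpolation.
    """
    composite = compose(e2i.composite, s2e.composite)
    nx, ny, nz = invivo_grid.shape
    warped = np.zeros((nx, ny, nz, 3), dtype=np.float32)
    for c in range(3):
        vol = color_stack.channel_volume(c)
        fill = float(np.median(vol.values[[0, -1], :, :]))
        warped[:, :, :, c] = resample(vol, composite, invivo_grid, "linear",
                                      fill=fill).values
    return Stack2InResult(composite, warped, invivo_grid)


def stack_landmark_positions(stacking: StackingResult, section_indices,
                             section_xy_mm) -> np.ndarray:
    """Positions of per-section annotations in the reconstructed stack.

    A point annotated at in-plane position ``w`` on raw section ``k`` appears
    in the assembled volume at ``t_k^{-1}(w)`` with z at the slice position —
    the coordinates a reader of the stacked volume would record.
    """
    out = []
    for k, w in zip(section_indices, np.asarray(section_xy_mm, dtype=float)):
        t_k = stacking.per_slice_transforms[int(k)]
        xy = t_k.inverse().apply(w)
        out.append([xy[0], xy[1], int(k) * stacking.interval_mm])
    return np.asarray(out)


def warp_mask(mask: np.ndarray, mask_grid: VolumeImage, transform,
              reference: VolumeImage) -> np.ndarray:
    """Warp a binary mask (pull-back, nearest-neighbor) onto a reference grid."""
    src = VolumeImage(np.asarray(mask, dtype=np.uint8), mask_grid.spacing,
                      mask_grid.origin, mask_grid.direction)
    out = resample(src, transform, reference, scheme="nearest", fill=0.0)
    return out.values.astype(bool)
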