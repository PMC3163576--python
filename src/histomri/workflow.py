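"""End-to-end pipeline runs on phantom data, with quantitative evaluation.

`run_pipeline` chains the bottom-up path — channel selection, stacking,
stack2ex, ex2in, stack2in — on a generated phantom and scores the result
against the phantom's ground truth: landmark RMS per registration stage
(the Table-1-style pattern), out-of-plane angulation, global and per-VOI
volume change, warped-VOI overlap, and the intensity-PDF characterization
(interquartile segmentation of the in vivo MRI from histology-confirmed
VOIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import (
    LandmarkSet,
    angulation_report,
    dice,
    estimate_pdf,
    global_volume_change,
    interquartile_segment,
    landmark_rms,
    voi_volume_mm3,
    volume_change_percent,
)
from .image import VolumeImage, resample_section
from .phantom import LABELS, Phantom
from .pipeline import (
    PipelineConfig,
    Stack2InResult,
    StackingResult,
    StageResult,
    ex2in,
    select_registration_channel,
    stack2ex,
    stack2in,
    stack_landmark_positions,
    stack_sections,
    stage_composites,
    warp_mask,
)

__all__ = ["PipelineRun", "run_pipeline", "evaluate_run", "characterize_regions"]


@dataclass
class PipelineRun:
    """Everything produced by one end-to-end phantom run."""

    phantom: Phantom
    config: PipelineConfig
    driver_channel: str
    channel_scores: dict
    stacking: StackingResult
    s2e: StageResult
    e2i: StageResult
    s2in: Stack2InResult
    summary: dict = field(default_factory=dict)
    warped_vois: dict = field(default_factory=dict)


def _annotated_section(ph: Phantom) -> int:
    """Section with the most necrotic tissue — the one worth annotating."""
    counts = [int((l == LABELS["necrotic"]).sum()) for l in ph.truth.section_labels]
    return int(np.argmax(counts))


def actual_stack_labels(ph: Phantom, stacking: StackingResult) -> np.ndarray:
    """Per-voxel region labels of the *reconstructed* stack volume.

    Applies the recovered per-slice transforms to the on-section label
    images (nearest-neighbor), mirroring how histology-drawn VOIs live in
    the stacked volume.
    """
    nx, ny = ph.cfg.section_shape
    out = np.zeros((nx, ny, len(ph.truth.section_labels)), dtype=np.int8)
    for k, (lab, t_k) in enumerate(zip(ph.truth.section_labels,
                                       stacking.per_slice_transforms)):
        out[:, :, k] = resample_section(
            lab.astype(float), t_k, stacking.pixel_size_mm, scheme="nearest"
        ).astype(np.int8)
    return out


def run_pipeline(ph: Phantom, cfg: PipelineConfig | None = None) -> PipelineRun:
    """Run stacking -> stack2ex -> ex2in -> stack2in on a phantom."""
    cfg = cfg or PipelineConfig()
    k = _annotated_section(ph)
    lab_k = ph.truth.section_labels[k]
    channel, scores = select_registration_channel(
        ph.sections, lab_k == LABELS["necrotic"], lab_k == LABELS["viable"],
        section_index=k)
    stacking = stack_sections(ph.sections, cfg.stacking, driver_channel=channel,
                              remove_drift=cfg.remove_stacking_drift)
    ex_tumor = ph.truth.labels["exvivo"] > 0
    plane_tumor = ph.truth.labels["plane"] > 0
    s2e = stack2ex(stacking, ph.exvivo, cfg.stack2ex, fixed_tumor_mask=ex_tumor,
                   mask_dilation_mm=cfg.mask_dilation_mm)
    e2i = ex2in(ph.exvivo, ph.invivo_realigned, cfg.ex2in,
                affine_model=cfg.ex2in_affine_model,
                fixed_tumor_mask=plane_tumor, moving_tumor_mask=ex_tumor,
                mask_dilation_mm=cfg.mask_dilation_mm)
    s2in = stack2in(s2e, e2i, stacking, ph.invivo_realigned)
    run = PipelineRun(ph, cfg, channel, scores, stacking, s2e, e2i, s2in)
    run.summary = evaluate_run(run)
    return run


def evaluate_run(run: PipelineRun) -> dict:
    """Score an end-to-end run against the phantom ground truth."""
    ph = run.phantom
    truth = ph.truth
    names, ks, w2d = truth.landmark_sections
    lm_stack = stack_landmark_positions(run.stacking, ks, w2d)
    _, lm_plane = truth.landmarks["plane"]
    A = LandmarkSet.from_arrays(names, lm_plane, observer="truth", image="invivo")
    B = LandmarkSet.from_arrays(names, lm_stack, observer="truth", image="stack")
    composites = stage_composites(run.s2e, run.e2i)
    rms = {"initial": landmark_rms(A, B)}
    for stage, t in composites.items():
        rms[stage] = landmark_rms(A, B, t)

    summary = {
        "driver_channel": run.driver_channel,
        "channel_scores": run.channel_scores,
        "landmark_rms_mm": rms,
        "angulation_deg": {
            "stack2ex": angulation_report(run.s2e),
            "ex2in": angulation_report(run.e2i),
        },
        "global_volume_change_percent": {
            "stack2ex": global_volume_change(run.s2e),
            "ex2in": global_volume_change(run.e2i),
        },
        "metrics": {"stack2ex": run.s2e.metrics, "ex2in": run.e2i.metrics},
    }

    # warped-VOI overlap and per-VOI Eq.-(1) volume change
    stack_labels = actual_stack_labels(ph, run.stacking)
    stack_grid = run.stacking.driver_volume
    invivo_grid = ph.invivo_realigned
    plane_labels = truth.labels["plane"]
    warped = {}
    voi_dice = {}
    voi_dv = {}
    domain = warp_mask(stack_labels > 0, stack_grid, run.s2in.composite, invivo_grid)
    for name in ("viable", "necrotic", "hemorrhagic"):
        code = LABELS[name]
        src = stack_labels == code
        w = warp_mask(src, stack_grid, run.s2in.composite, invivo_grid)
        warped[name] = w
        voi_dice[name] = dice(w, (plane_labels == code) & domain)
        v_o = voi_volume_mm3(src, stack_grid.spacing)
        v_r = voi_volume_mm3(w, invivo_grid.spacing)
        voi_dv[name] = volume_change_percent(v_o, v_r)
    summary["warped_voi_dice"] = voi_dice
    summary["voi_volume_change_percent"] = voi_dv
    summary["characterization"] = characterize_regions(
        invivo_grid, warped, plane_labels)
    run.warped_vois = warped
    return summary


def characterize_regions(invivo: VolumeImage, confirmed_vois: dict,
                         true_labels: np.ndarray, bins: int = 64) -> dict:
    """PDF-based MRI characterization from histology-confirmed VOIs.

    For each warped (histology-confirmed) VOI, estimates the in vivo
    intensity pdf and segments the tumor by its interquartile range; reports
    Dice against the true region and the pdf quartiles.  Reproduces the
    expected structure: necrotic separates from the rest; viable and
    hemorrhagic overlap and cannot be told apart by intensity alone.
    """
    tumor_domain = true_labels > 0
    out = {}
    for name, voi in confirmed_vois.items():
        if not np.any(voi):
            out[name] = {"dice": np.nan}
            continue
        pdf = estimate_pdf(invivo, voi, bins=bins)
        seg = interquartile_segment(invivo, pdf, domain_mask=tumor_domain)
        code = LABELS[name]
        out[name] = {
            "q1": pdf.q1, "q2": pdf.q2, "q3": pdf.q3,
            "dice": dice(seg, true_labels == code),
            "selected_fraction_of_voi": float(np.count_nonzero(
                seg & voi) / max(np.count_nonzero(voi), 1)),
        }
    return out


# ---------------------------------------------------------------------------
# controlled recovery experiments (shared by tests and the acceptance script)


def shrinkage_recovery_experiment(seed: int):
    """Recover the programmed global fixation shrinkage by ex2in registration.

    Generates the default phantom at ``seed`` (in vivo + ex vivo), runs the
    rigid and similarity steps of ex2in, and reports the global volume
    change from the similarity determinant (percent of the in vivo volume
    lost to fixation; programmed value is ``cfg.shrinkage_percent``).
    """
    from .phantom import PhantomConfig, generate_invivo, simulate_exvivo
    from .pipeline import ex2in
    from .registration import RegistrationConfig

    ph = simulate_exvivo(generate_invivo(PhantomConfig(seed=seed)))
    cfg = RegistrationConfig(metric="mutual_information", random_seed=seed)
    stage = ex2in(ph.exvivo, ph.invivo_realigned, cfg,
                  fixed_tumor_mask=ph.truth.labels["plane"] > 0,
                  moving_tumor_mask=ph.truth.labels["exvivo"] > 0,
                  models=("rigid", "affine"))
    return global_volume_change(stage), ph.cfg.shrinkage_percent


def angulation_recovery_experiment(tilt_deg: float, seed: int = 0):
    """Recover a synthesized out-of-plane tilt from the ex2in rigid step.

    The ex vivo phantom is generated with an exact rotation of ``tilt_deg``
    about one in-plane axis and no random deformation (the controlled
    condition for the reference-plane angulation measurement).  The tilt is
    read from the rotation component after the isotropic-scaling step:
    fixation shrinkage is part of the conditions, and a pure-rigid rotation
    fit on the half specimen is biased by the unmodeled global scale.
    """
    from .phantom import PhantomConfig, generate_invivo, simulate_exvivo
    from .pipeline import ex2in
    from .registration import RegistrationConfig

    cfg_ph = PhantomConfig(seed=seed, exvivo_rotation_deg=(tilt_deg, 0.0, 0.0),
                           deform_amplitude_mm=0.0)
    ph = simulate_exvivo(generate_invivo(cfg_ph))
    cfg = RegistrationConfig(metric="mutual_information", random_seed=seed)
    stage = ex2in(ph.exvivo, ph.invivo_realigned, cfg,
                  fixed_tumor_mask=ph.truth.labels["plane"] > 0,
                  moving_tumor_mask=ph.truth.labels["exvivo"] > 0,
                  models=("rigid", "affine"))
    return angulation_report(stage.affine)


def stacking_recovery_experiment(seed: int = 1):
    """Recover per-slice jitter on constant-content, noise-free sections.

    Returns (mean translation error in px, mean rotation error in degrees)
    over all sections versus the recorded jitter truth.
    """
    from .phantom import PhantomConfig, generate
    from .pipeline import stack_sections
    from .registration import RegistrationConfig

    cfg_ph = PhantomConfig(seed=seed, uniform_section_content=True,
                           stain_sigma=0.0, stain_background_sigma=0.0)
    ph = generate(cfg_ph)
    cfg = RegistrationConfig(metric="normalized_correlation",
                             iterations_per_level=200, random_seed=seed)
    res = stack_sections(ph.sections, cfg, driver_channel="red")
    px = cfg_ph.section_pixel_mm
    terr = [float(np.linalg.norm(r.translation - t.translation)) / px
            for r, t in zip(res.per_slice_transforms, ph.truth.stacking_transforms)]
    aerr = [abs(float(np.degrees(r.angle - t.angle)))
            for r, t in zip(res.per_slice_transforms, ph.truth.stacking_transforms)]
    return float(np.mean(terr)), float(np.mean(aerr))
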