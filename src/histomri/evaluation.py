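"""Quantitative evaluation: landmark accuracy, volume change, angulation,
and intensity-PDF tissue characterization.

Conventions
-----------
* Landmark accuracy is the root-mean-squared Euclidean distance (mm) between
  corresponding points, optionally after mapping one set through a transform.
* Global volume change of a registration step is reported from the
  determinant of its affine/similarity component as
  ``dV = 100 * (1 - det(T))`` where ``T`` is the pull-back (fixed-to-moving)
  transform: the fraction of the fixed (earlier-in-time) volume lost along
  the processing chain.  Fixation shrinkage is therefore positive
  (tissue lost), sectioning expansion negative.
* Mask-based volume change uses the direct relative formula
  ``dV = 100 * (V_R - V_O) / V_O`` with VOI volumes measured as
  voxel count x voxel volume; warped masks use nearest-neighbor resampling.
* Region PDFs are normalized histograms (64 bins by default, no kernel
  smoothing); quartiles interpolate the empirical CDF linearly within bins.
  Interquartile segmentation selects voxels with intensity in the closed
  interval [Q1, Q3].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .image import VolumeImage
from .transforms import Transform, determinant, out_of_plane_angulation_deg

__all__ = [
    "LandmarkSet",
    "VOIMask",
    "IntensityPDF",
    "landmark_rms",
    "interobserver_rms",
    "volume_change_percent",
    "voi_volume_mm3",
    "global_volume_change",
    "angulation_report",
    "estimate_pdf",
    "interquartile_segment",
    "dice",
]

VOI_LABELS = ("viable", "necrotic", "hemorrhagic")


@dataclass
class LandmarkSet:
    """Named world-coordinate points (mm), one set per observer per image."""

    points: dict
    observer: str = ""
    image: str = ""

    def __post_init__(self):
        if not self.points:
            raise ValueError("a LandmarkSet needs at least one point")
        self.points = {str(k): np.asarray(v, dtype=float).reshape(3)
                       for k, v in self.points.items()}

    @classmethod
    def from_arrays(cls, names, coords, observer: str = "", image: str = "") -> "LandmarkSet":
        coords = np.asarray(coords, dtype=float)
        return cls(dict(zip(names, coords)), observer=observer, image=image)

    def names(self) -> list:
        return sorted(self.points)

    def as_array(self, names=None) -> np.ndarray:
        return np.array([self.points[n] for n in (names or self.names())])


@dataclass
class VOIMask:
    """Binary volume-of-interest mask sharing its parent image's grid."""

    mask: np.ndarray
    label: str
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        if self.label not in VOI_LABELS:
            raise ValueError(f"label must be one of {VOI_LABELS}")
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)

    def volume_mm3(self) -> float:
        return voi_volume_mm3(self.mask, self.spacing)


def landmark_rms(a: LandmarkSet, b: LandmarkSet, t: Optional[Transform] = None) -> float:
    """RMS distance (mm) between corresponding points, mapping ``a`` through ``t``."""
    na, nb = set(a.points), set(b.points)
    if na != nb:
        missing = sorted(na.symmetric_difference(nb))
        raise ValueError(f"landmark identifier mismatch: {missing}")
    names = sorted(na)
    pa = a.as_array(names)
    pb = b.as_array(names)
    if t is not None:
        pa = t.apply(pa)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def interobserver_rms(obs1: LandmarkSet, obs2: LandmarkSet) -> float:
    """RMS distance between two observers' annotations of the same image."""
    return landmark_rms(obs1, obs2, t=None)


def volume_change_percent(v_original: float, v_registered: float) -> float:
    """Relative VOI volume change ``100 * (V_R - V_O) / V_O`` in percent."""
    if v_original <= 0:
        raise ValueError("the original VOI volume must be positive")
    return 100.0 * (v_registered - v_original) / v_original


def voi_volume_mm3(mask: np.ndarray, spacing) -> float:
    """VOI volume as voxel count times voxel volume."""
    spacing = np.asarray(spacing, dtype=float)
    return float(np.count_nonzero(mask) * np.prod(spacing))


def global_volume_change(stage) -> float:
    """Global volume change (%) from a stage's affine/similarity determinant.

    Accepts a pipeline StageResult (uses its affine component) or a transform.
    Returns ``100 * (1 - det)``: positive = volume lost from the fixed image
    to the moving image (fixation shrinkage), negative = gained (sectioning
    expansion), matching the processing-chain reading of the transforms.
    """
    t = getattr(stage, "affine", stage)
    if t is None:
        raise ValueError("stage has no affine/similarity component")
    return 100.0 * (1.0 - determinant(t))


def angulation_report(stage, plane=None) -> float:
    """Out-of-plane angulation (degrees) of a stage's rigid component.

    Measures the reference-plane positioning error: the rotation of the
    recovered rigid transform about the axes lying in the reference plane
    (in-plane rotation does not contribute).
    """
    t = getattr(stage, "rigid", stage)
    if t is None:
        raise ValueError("stage has no rigid component")
    return out_of_plane_angulation_deg(t, plane)


@dataclass
class IntensityPDF:
    """Histogram-based intensity density with interpolated quartiles."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        s = self.probabilities.sum()
        if not np.isclose(s, 1.0):
            raise ValueError("probabilities must sum to 1")

    def quantile(self, p: float) -> float:
        """Linear interpolation of the empirical CDF over the histogram."""
        cdf = np.concatenate([[0.0], np.cumsum(self.probabilities)])
        cdf[-1] = 1.0
        i = int(np.searchsorted(cdf, p, side="left"))
        i = min(max(i, 1), len(cdf) - 1)
        lo, hi = cdf[i - 1], cdf[i]
        e0, e1 = self.bin_edges[i - 1], self.bin_edges[i]
        if hi <= lo:
            return float(e0)
        return float(e0 + (p - lo) / (hi - lo) * (e1 - e0))

    @property
    def q1(self) -> float:
        return self.quantile(0.25)

    @property
    def q2(self) -> float:
        return self.quantile(0.50)

    @property
    def q3(self) -> float:
        return self.quantile(0.75)

    def max_bin_mass(self) -> float:
        return float(self.probabilities.max())


def estimate_pdf(image, mask, bins: int = 64) -> IntensityPDF:
    """Normalized intensity histogram of a masked region.

    ``image`` may be a :class:`VolumeImage` or a plain array; ``mask`` a
    boolean array (or VOIMask) on the same grid.
    """
    values = image.values if isinstance(image, VolumeImage) else np.asarray(image)
    m = mask.mask if isinstance(mask, VOIMask) else np.asarray(mask).astype(bool)
    if values.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    vals = values[m]
    if vals.size == 0:
        raise ValueError("empty mask: cannot estimate a pdf")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        # constant region: all mass at one value, quartiles equal it
        probs = np.zeros(bins)
        probs[0] = 1.0
        return IntensityPDF(np.full(bins + 1, lo), probs)
    hist, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    return IntensityPDF(edges, hist / hist.sum())


def interquartile_segment(image, pdf: IntensityPDF, domain_mask=None) -> np.ndarray:
    """Binary mask of voxels with intensity in the closed interval [Q1, Q3].

    Restricted to ``domain_mask`` when given (e.g. the tumor, excluding
    surrounding tissue).
    """
    values = image.values if isinstance(image, VolumeImage) else np.asarray(image)
    q1, q3 = pdf.q1, pdf.q3
    if q1 > q3:
        raise ValueError("invalid pdf quartiles (Q1 > Q3)")
    sel = (values >= q1) & (values <= q3)
    if domain_mask is not None:
        dm = domain_mask.mask if isinstance(domain_mask, VOIMask) else np.asarray(domain_mask)
        sel &= dm.astype(bool)
    return sel


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two binary masks."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / denom)
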