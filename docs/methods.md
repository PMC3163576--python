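# Methods

`histomri` implements a registration methodology for spatially relating 3D
tumor histology to in vivo MRI: serial H&E sections are rigidly stacked into
a 3D volume, registered to an intermediate ex vivo MRI of the fixed
specimen, the ex vivo MRI is registered to the in vivo MRI realigned to a
shared reference cutting plane, and the two transformations are
concatenated automatically so the color histology can be warped onto the in
vivo grid. This note documents the models, the synthetic test bed, the
numerical choices, and the known limits of what the phantom experiments
demonstrate.

## Coordinate and transform conventions

World coordinates are millimetres. Volumes are node-centered regular grids
(`world = origin + direction @ (spacing * index)`, 0-based indices,
orthonormal right-handed direction). All transforms are *pull-back*
(fixed-to-moving): resampling evaluates the moving image at `T(x)` for each
fixed-grid point `x`, so no hole filling is needed. Composites apply their
components first-to-last; the histology-to-in-vivo map applies the ex2in
result first (in vivo point → ex vivo point) and the stack2ex result second
(ex vivo point → stack point).

Euler angles use intrinsic rotations about x, then y, then z
(`R = Rx·Ry·Rz`), reported in that order; gimbal lock (|cos β| ≈ 0) sets
the third angle to zero. The free-form deformation is a tensor-product
cubic B-spline of control-point displacements; points without a full 4³
control support get zero displacement (identity outside support — safe
extrapolation past the tumor border, and exactly ITK's behaviour, verified
point-wise against SimpleITK in the test suite).

Out-of-plane angulation — the reference-plane positioning error — is the
angle between the plane normal and its image under the recovered rotation.
This is convention-free, equals the Euler component for a single-axis tilt,
and ignores in-plane rotation by construction.

## The reference plane and realignment

The reference cutting plane (through the tumor's longest axis,
perpendicular to the subcutaneous side) anchors all three 3D images.
`realign_to_reference_plane` resamples the in vivo volume into a new frame
whose first slice lies on the plane, with the slice normal along the plane
normal and the in-plane field of view centered on the plane point. The
returned volume *defines* this frame (identity direction, origin at the
plane corner): it is the common frame that the ex vivo scan and the
histology stack share by construction of the cut.

## Registration engine

Stage transforms are estimated with SimpleITK's registration framework
behind the package's own surface (`RegistrationConfig`, `register`,
`optimize`); the package's own numpy implementations of the metrics
(mutual information with partial-volume linear binning, normalized
correlation, mean squares) are used for all full-sampling stage
evaluations and for the acceptance guard: an optimized transform is kept
only if its full-sampling metric is no worse than its initialization's.

Defaults, chosen for the thin (20–24 slice) working volumes:

* two pyramid levels, shrink factors (2, 1), smoothing (1, 0) voxels — a
  4× coarsest level degenerates these volumes and caused divergence;
* deterministic full sampling of the (masked) fixed region — per-iteration
  random resampling destabilized the step-length control;
* RegularStep gradient descent with physical-shift parameter scales for the
  linear stages, LBFGSB for the B-spline stage (control spacing 4.8 mm,
  fixed mesh across levels);
* Mattes MI with 32 bins for the inter-modality steps, correlation for the
  mono-modal 2D stacking;
* single-threaded execution and fixed seeds: runs are bit-reproducible.

Mask policy: the rigid/affine/similarity stages use the tumor mask dilated
by 2 mm — a tight mask removes the boundary from the metric and lets the
scale drift (the boundary shell can map consistently into background,
which *raises* MI); the elastic stage uses tight fixed and moving tumor
masks — with a loose mask its many degrees of freedom drift in
structureless background.

A systematic property of MI registration worth knowing when reading the
numbers: the optimum is biased toward mappings that sample the moving
image's pure-class regions rather than its boundary transition zones. The
bias is a fraction of the transition width (point-spread plus
interpolation; here ~0.03–0.05 mm) — negligible for landmark accuracy but
cubed into several percentage points when read as a volume-change
determinant. It survives noise-free, PSF-free and symmetric-background
phantoms and is independent of grid resolution in physical units.

## The pipeline

* **Channel selection** — per color channel, the separability of the
  necrotic and viable VOI histograms on an annotated section is scored as
  one minus the Bhattacharyya overlap of 64-bin normalized histograms; ties
  break toward red. On H&E-like sections the red channel wins by
  construction of the stain colors.
* **Stacking** — each section is rigidly registered (2D, driver channel,
  correlation metric) to its already-aligned predecessor; transforms
  accumulate from the anchor (section 0, the reference cut). The stacked
  volume's slice spacing is the physical inter-section interval (80 µm).
  Sequential stacking determines per-slice poses only up to a smooth trend:
  adjacent-section content genuinely drifts (cross-sections of a 3D object
  shift and rotate with depth), and the stack follows the tissue. This
  gauge freedom — the classic "banana" effect — is absorbed later by
  stack2ex; the controlled jitter-recovery experiment therefore uses the
  generator's constant-content mode, where jitter is the only corruption.
  An optional low-order drift guard (off by default) can remove a linear
  trend in the accumulated translations.
* **stack2ex** — rigid → full 12-DOF affine → B-spline, stack moving,
  ex vivo fixed; the shared reference plane initializes the out-of-plane
  pose and foreground centers of mass the in-plane offset.
* **ex2in** — rigid → similarity (rigid + isotropic scale; the scale cubed
  is the global fixation volume change) → B-spline, ex vivo moving,
  realigned in vivo fixed; the realignment is the initialization. A config
  switch allows a full affine instead of the similarity.
* **stack2in** — the two composites concatenated; each color channel is
  warped independently (linear interpolation), masks with nearest-neighbor.

## Evaluation

* Landmark accuracy is the RMS Euclidean distance between corresponding
  points, with landmarks read in the frames an annotator would use: on the
  *reconstructed* stack (per-section annotations mapped through the
  recovered per-slice poses) and in the realigned in vivo frame. The
  "initial" value is the reference-plane-only correspondence — the state
  after realignment and stacking, before the volumetric registrations.
* Global volume change of a step is `100·(1 − det T)` for the pull-back
  affine/similarity transform: the fraction of the fixed (earlier-in-time)
  volume lost along the processing chain. Fixation shrinkage is positive,
  sectioning expansion negative. Mask-based (per-VOI) change uses the
  direct relative formula `100·(V_R − V_O)/V_O` with volumes as voxel
  count × voxel volume.
* Region characterization estimates each histology-confirmed (warped) VOI's
  in vivo intensity pdf (64-bin normalized histogram, quartiles by linear
  CDF interpolation) and segments the tumor by the closed interquartile
  interval [Q1, Q3]. Note an arithmetic ceiling: when the pdf VOI equals
  the evaluation truth, the IQR rule selects ~50 % of that VOI by
  definition, capping the Dice overlap at 2/3; values above that require
  the confirmed VOI to differ from the truth (registration error widening
  the IQR). With an accurately warped VOI the necrotic Dice therefore sits
  near 0.68 — the structural findings (necrotic separable, viable vs
  hemorrhagic not, Dice ≈ 0.26) are unaffected.

## The phantom

The generator emulates the study conditions of a subcutaneous rodent tumor
(~10 mm long axis) at desk scale: 64³ native grid at 0.2 mm; all geometry
scales through spacing. Components:

* **Tissue model** — an ellipsoid (semi-axes 5.0/3.5/3.0 mm) with a lobular
  boundary (smooth random perturbation of the implicit function), a nested
  necrotic core and hemorrhagic pockets whose realized volume fractions
  match the request exactly (quantile thresholds of the continuous model);
  a smooth unit-variance texture field models intra-region heterogeneity
  and is carried through every frame as a tissue property (real T2*-w tumor
  images are heterogeneous, and the registrations rely on internal
  contrast).
* **Contrast** — T2*-w-like: necrotic distinctly hypo-intense (45 ± 8),
  viable 150 ± 12 and hemorrhagic 135 ± 15 overlapping; ex vivo similar with
  dark agar background; a 0.1 mm Gaussian PSF; Gaussian noise (no Rician
  model — a config hook exists). H&E-like RGB sections (viable dark purple,
  necrotic pale pink, hemorrhagic red-dominant) constructed so the red
  channel maximizes necrotic/viable separability.
* **Reference plane** — through the tumor center, normal along the native
  y axis. The tumor center sits on a grid node and the realigned in-plane
  extent is odd, so realignment is an exact axis permutation: the fixed
  image suffers no interpolation loss (at acquisition resolution this loss
  is negligible; at desk scale it would dominate the volume-change
  readout).
* **Fixation** — isotropic shrinkage (13.2 % volume loss by default), a
  small rigid offset (rotation ≤ 2°, translation ≤ 0.8 mm in-plane), and a
  smooth random B-spline deformation (control spacing 4.8 mm, coefficient
  SD 0.7 mm ≈ 0.25 mm RMS displacement). The random field's global affine
  component is projected out (cubic B-splines reproduce affine fields
  exactly, so the correction is exact on the coefficients) — by the model's
  own decomposition that content belongs to the similarity — and the
  residual mean Jacobian over the specimen is folded into the similarity
  scale by a short fixed-point iteration, so the *total* programmed volume
  change equals the configured shrinkage.
* **Sectioning** — sections cut from the specimen's face (the first slice
  with ≥ 25 % of the maximal cross-section; agar above the face is not
  mounted), 30 sections at 80 µm, 0.1 mm pixels, per-slice rigid jitter
  (≤ 5 px, ≤ 3°, anchor section unjittered), and a global +1.9 % in-plane
  sectioning expansion. Per-section label images record what an annotator
  would outline on the slides.
* **Landmarks** — ten lobular extremes of the tumor boundary inside the
  sectioned band, snapped onto the implicit isosurface; truth positions are
  recorded in every frame through the exact generative maps (stack-frame z
  is quantized to the nearest section, as for a real reader).

Determinism: all randomness derives from spawned child generators of the
configured seed; repeated generation is bit-identical.

## What the phantom experiments do and do not show

The phantom is piecewise-constant with smooth texture — far simpler than
real tissue. This makes registration *harder* in one specific way (MI's
boundary bias is amplified because boundary ramps are globally consistent)
and easier in others (no stain variation, no tears or folds, no missing
sections). Consequently:

* Landmark recovery: the full chain reduces the initial RMS (0.83 mm at
  seed 1) to ~0.27 mm ≈ 1.3 working voxels, strictly decreasing through
  rigid → affine → elastic. The affine checkpoint already sits near the
  phantom's landmark floor (section-z quantization, per-slice residuals,
  boundary bias), so the elastic gain is small and mostly from ex2in,
  whose true deformation is genuinely non-affine; stack2ex's true map is
  nearly affine by construction.
* Volume-change recovery: the similarity determinant recovers the
  programmed 13.2 % loss with per-seed scatter of roughly ±2–3 percentage
  points (mean accurate), limited by the boundary-bias-cubed effect above
  and by the residual ambiguity of "global scale" in the presence of a
  smooth deformation. A tolerance tighter than that scatter is not
  achievable with this estimator at these conditions.
* Angulation: synthesized tilts are recovered within 0.3° when read from
  the rotation component of the scale-inclusive (similarity) step; a pure
  rigid fit under 13.2 % unmodeled shrinkage reads a 1.4° tilt ~0.45° low.
* Stacking: with constant-content sections, jitter is recovered to
  ~0.05 px / 0.04°; on real (evolving) content the per-slice poses are
  identifiable only up to the smooth trend discussed above.

## Degenerate inputs and numerical details

Flat (zero-variance) intensity sets and empty masks are rejected at the
metric level rather than returning silent zeros; a diverging optimizer
falls back to its initialization; sections whose 2D registration fails are
flagged and keep the previous pose. MI is computed in bits from a
partial-volume (bilinear) joint histogram over the data range; integer or
bin-center-quantized inputs reduce exactly to hard binning. The empirical
MI of finite samples is biased upward by ≈ (B−1)²/(2N ln 2); independence
checks need N ≫ B². Quartiles interpolate the histogram CDF linearly; a
constant region returns its single value for all three quartiles.

## Problem sizes

Default experiments run at the desk-scale conditions above: 64³ native
volume, 65×65×20/24 working grids at 0.2 mm, 30 sections of 128² at 0.1 mm.
A full pipeline run takes well under a minute on one CPU; the complete test
suite a few minutes.
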