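# Methods

This note documents the models, algorithms and numerical choices behind
`pelvisynth`, and what the phantom-based tests do and do not demonstrate.

## Data model

Volumes are 3D scalar lattices indexed `[x, y, z]` with physical geometry
(spacing in mm, origin, orthonormal direction matrix). Everything is
reoriented to a single right-handed LPS convention on load, so registration
and patch indexing never branch on orientation. Voxel indices are 0-based,
lattice extents half-open. NIfTI is the canonical on-disk format; DICOM
image series and DICOM RT Dose are import-only (RT Dose values are scaled
to Gy by the stored grid scaling). Background conventions: CT −1000 HU,
MRI 0, dose 0.

## Phantom cohort generator

The generator is the package's stand-in for a paired CT/MRI patient
cohort; its defaults define the study conditions for all end-to-end tests.

* **Geometry.** Default grid 96x96x60 at 2 mm isotropic — large enough for
  three-level multi-resolution registration, small enough for minutes-scale
  experiments. The body is an ellipse in cross-section (semi-axes drawn
  from 70–84 mm lateral, 52–62 mm anteroposterior), modulated by a smooth
  low-order angular perturbation, a superior-inferior taper plus a
  waist/hip bulge, and smooth end caps that close the body at about 85% of
  the axial half-extent. The caps and axial profile matter: a purely
  extruded ellipse cut at the volume edge makes superior-inferior rigid
  alignment mathematically ill-posed (any z-shift is as good as any other),
  which no registration algorithm could overcome.
* **Structures.** Two femoral-head spheres (radius 10–14 mm), a posterior
  spinal cylinder, an elliptic pelvic ring, an anterior bladder ellipsoid
  (18–26 mm), and 1–3 bowel-gas pockets placed inside the body and clear of
  bone and bladder, so the gas-override operation has unambiguous ground
  truth. Bone and bladder are mutually exclusive and subsets of the body.
* **Intensities.** CT values are drawn per tissue class from Gaussian HU
  distributions (air −1000, fat −100, muscle +40, bladder +15, bone +700;
  sd 10–50 — representative textbook values). The MRI maps the same classes
  through a *non-monotone* table (fat 800, bladder 900, muscle 400, bone
  150, air 0), then applies a smooth multiplicative bias field (a broad
  Gaussian bump, fractional amplitude 0.2) and additive Gaussian noise
  (sd 10), clipped at 0. Because bone is bright on CT but dark on MR, no
  global intensity mapping can convert one modality into the other; fusion
  must rely on spatial correspondence. This is the property that makes the
  phantom a meaningful test of atlas fusion rather than of histogram
  tricks.
* **Determinism.** A cohort is a pure function of (parameters, n, seed);
  per-case seeds are derived with `numpy.random.SeedSequence.spawn`.
* **What the phantom does not emulate.** Realistic pelvic morphology
  (meshes, organ contact surfaces), MRI physics (relaxation, DIXON
  reconstruction, distortion), metal or contrast artifacts, and realistic
  treatment beam models. Passing the end-to-end tests shows the pipeline is
  internally correct and robust to the modelled variation; it does not
  certify clinical accuracy on patient data.

### Synthetic dose

Doses are analytic spherical targets: prescription inside a target radius,
Gaussian penumbra (sigma in mm) outside, with the reference point at the
target centre. For CT-vs-sCT dose pairs the reference dose is perturbed by
the first-order radiological effect of density differences:
`D' = D * exp(-mu_w * cumsum_y (rho_sct - rho_ct) dy)` with
`mu_w = 0.005 mm^-1` (an effective 6 MV attenuation coefficient in water)
accumulated along the anteroposterior axis. This reproduces the physically
expected behaviour — HU errors matter more with depth, signed errors
partially cancel — without a beam model.

## Preprocessing

* **Bias correction** uses N4 (SimpleITK) by default, with the mean
  intensity inside the body preserved and the background fixed at exactly
  0. A log-domain polynomial estimator is available
  (`method="polynomial"`) but is not the default: on piecewise-constant
  anatomy the polynomial absorbs genuine tissue structure (the radial
  fat/muscle layout) and can *increase* intensity variation, while N4's
  histogram-sharpening formulation separates the smooth field from
  contrast.
* **Body mask**: largest connected component above −250 HU with slice-wise
  hole filling, so internal gas stays inside the body. The threshold is a
  package default; any value between fat and air works on the phantom.
* **Gas override**: voxels inside the body below −300 HU are replaced by
  the mean HU of non-gas tissue within 10 mm (a spherical neighbourhood,
  computed by mask-weighted convolution). The neighbourhood radius and
  threshold are package choices; they are set so phantom fat (−100 HU) is
  never misclassified as gas. The operation is idempotent whenever
  replacement values exceed the threshold.
* **HU → relative electron density**: piecewise-linear interpolation of a
  calibration table, clamping beyond the end points. A 5-point default
  curve (air/lung/water/muscle/dense bone) ships with the package;
  site-specific curves load from a two-column text file.

## Registration

Transform chains map fixed-space physical points into moving-space points
(the resampling convention); stages are stored in point-application order.
Displacement fields live on the fixed geometry in mm.

**MRI-to-MRI chain** (sCT synthesis): a 6-DoF rigid stage driven by the
body masks, then diffeomorphic demons on intensities (smoothing sigma 3
voxels, 3 multi-resolution levels, 50 iterations per level with an RMS
plateau stop). Atlas intensities are histogram-matched to the target
before demons, since inter-subject MR scales are arbitrary.

**Structure-guided chain** (atlas construction): rigid + fast
symmetric-forces demons (sigma 1) on signed distance maps of the combined
bone+bladder labels, then a multiscale B-spline refinement of the CT to
the MRI under a Mattes mutual-information metric. The refinement stage is
accepted only if it does not reduce the label Dice achieved by the first
two stages — a structure-guarded acceptance that keeps the chain faithful
to the anatomy it is built around (on piecewise-constant images, MI
refinement occasionally hurts).

The rigid stage needed care to be robust, and the choices are worth
recording:

* The metric is mean squared error between *signed Euclidean distance
  maps* (scipy EDT; negative inside, positive outside), not between masks:
  distance maps give smooth, long-range gradients.
* Distance maps are clamped at ±20 mm and the metric is evaluated only
  within a 12 mm band around the fixed structure boundary. Far-field
  samples carry no alignment information and, worse, large flat regions
  let a wandering transform match background against background.
* The moving map is padded with the clamp value (12 voxels per side).
  Without padding, samples that map outside the moving image are silently
  dropped from the metric, and a transform that slides the structure out
  of the field of view can *improve* its score on the shrinking overlap —
  a classic failure mode this removes by construction.
* Initialization aligns the mask centroids (moments), which lands within
  a voxel of the optimum for pure translations.

Demons "standard deviation" parameters are interpreted as the Gaussian
smoothing sigma of the displacement field in voxels. Divergence is guarded
by a sanity bound (60 mm maximum displacement) that raises rather than
returning a silently broken chain.

## Fusion

Patch dissimilarity is the mean squared intensity difference over the
cubic patch of edge `2*radius+1`, clipped at image borders (computed
exactly via zero-padded box sums divided by in-bounds patch counts).
Weights are inverse-power, `w = (d + eps)^(-gain)`: monotone in
similarity, equal weighting at gain 0, single-atlas selection as gain grows.
An exponential kernel `exp(-gain*d/var)` is available as a configuration
alternative. Numerical stability at high gain comes from log-domain
weights normalized per voxel before exponentiation. Epsilon defaults to
1e-6 times the target intensity variance inside the body (scale-free).
MRIs are z-scored inside the body before dissimilarity (default), since
inter-subject intensity scales are arbitrary. Voxels outside the target
body are set to −1000 HU rather than fused. Leave-one-out synthesis
excludes any atlas case sharing the target's id.

## Validation metrics

* **ME / MAE** over a region after stripping the superior and inferior
  3 cm of the axial extent (slice-centre rule); sign convention sCT − CT.
  Soft tissue is body minus bone (configurable).
* **Dice** `2|A∩B|/(|A|+|B|)`; **volume difference** in % of the reference
  volume (mm³).
* **3D gamma** is reference-centric: for each evaluated voxel the minimum
  generalized distance over a trilinear-refined search lattice (step =
  spacing / 3) within 3x the DTA. Offsets are scanned in order of
  increasing distance with early termination once the spatial term alone
  exceeds every running minimum; a dense no-pruning scan
  (`gamma_3d_bruteforce`) serves as the testing oracle. The evaluation
  domain is the body eroded by 15 mm (Euclidean distance thresholding)
  intersected with voxels at or above 10% of the normalization dose, which
  defaults to the reference maximum (global normalization). Unevaluated
  voxels carry −1 in the gamma map; pass rate and mean gamma are computed
  over evaluated voxels only.
* **DVH**: cumulative curves at 0.05 Gy bins; D_x by linear interpolation
  of the inverted curve, V_d by interpolation of the curve, Dmean always
  from raw voxel doses to avoid binning bias.
* **Wilcoxon signed-rank**: zeros dropped, midranks under ties. For
  n ≤ 25 the exact two-sided p-value is computed from the null
  distribution of W+ built by dynamic programming over sign assignments
  (ranks doubled to integer support, ties handled naturally); above 25 a
  normal approximation with tie correction is used. Tests cross-check the
  DP against brute-force sign-flip enumeration and against
  `scipy.stats.wilcoxon` in the tie-free case. Note the exact p-value at
  very small n is necessarily coarse (its smallest attainable value is
  `2/2^n`).

## End-to-end experiment

`run_leave_one_out` N4-corrects every MRI, synthesizes each case's sCT
from the remaining cases, and validates against the true CT: HU errors,
bone Dice (sCT thresholded at +200 HU with a morphological opening),
body Dice from re-thresholding, gamma at 3%/2 mm, 2%/2 mm and 1%/1 mm on
density-perturbed synthetic dose pairs centred on the bladder, and the
reference-point dose difference with its signed-rank p. Failures isolate
per case: a failed registration is recorded and skipped, not fatal.
Aggregates report mean ± 1 SD. The default experiment (6 cases at
96x96x60) runs in about 6 minutes on one CPU; the problem sizes were
chosen so the full suite stays in the minutes range while every stage
still does real work (multi-resolution registration, ~200k-voxel fusion,
~90k-voxel gamma evaluation).

## Known limitations

* The fusion weight kernel is a design decision; the clinical lineage of
  local weighted voting does not pin down one formula. The inverse-power
  kernel satisfies every qualitative property expected of the method
  (mean at gain 0, sharpening with gain, convex combination), and the
  kernel is swappable in configuration.
* The B-spline refinement uses Mattes mutual information rather than
  normalized mutual information (not exposed by SimpleITK); for the
  refinement-by-contract role the two are interchangeable.
* Phantom results bound internal correctness, not clinical accuracy; in
  particular bone MAE on the phantom is *lower* than published
  patient-data values because phantom bone is homogeneous.
* The dose perturbation model is first-order radiological path scaling,
  not a transport calculation; gamma results on the phantom quantify the
  pipeline's sensitivity to HU errors, not TPS-grade dosimetry.
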