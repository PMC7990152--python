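# Methods

This note records the models, conventions and numerical choices behind
`graftquant`, in the order the pipeline runs them, plus what the phantom
does and does not emulate.

## Geometry and I/O

Volumes are axis-aligned 3D scalar grids; world position of voxel
`(i, j, k)` is `origin + index · spacing` (mm).  Oblique direction
matrices are rejected outright rather than resampled — the analysis never
needs them, and refusing avoids silent misregistration.  MetaImage and
NIfTI are supported; masks are stored as 8-bit 0/1 for maximal format
compatibility.  Because CBCT units are uncalibrated, each volume carries
a `raw`/`normalized` flag, persisted in a JSON sidecar next to the file.

## Rigid alignment

A transform is 3 Euler angles (degrees, applied about the x, then y,
then z world axis) about the moving volume's geometric center, followed
by a translation in mm: `p_fixed = R (p_mov − c) + c + t`.  This is
pinned so transform files are portable; composition and exact inversion
are provided (the inverse recovers angles from the transposed matrix).

Resampling fills the reference grid from the moving volume at the
inverse-transformed position, linear for images, nearest for masks
(linear interpolation of a mask is refused).  Out-of-field voxels get the
moving volume's 1st-percentile value, a robust background estimate.

Automatic registration minimizes the mean squared intensity difference
over the fixed grid.  Both inputs are normalized first, which removes the
per-scan gain/offset that would otherwise defeat a squared-difference
metric and avoids a mutual-information implementation.  Three
deterministic stages:

1. translation initialization from robust intensity centroids;
2. capture with a restarted Nelder–Mead simplex on a smoothed,
   factor-4-decimated level (simplex restarts are the standard cure for
   simplex collapse in six dimensions);
3. precision polish with finite-difference Levenberg–Marquardt on the
   voxelwise residuals, first heavily smoothed (wide basin), then lightly
   smoothed with the full-resolution moving image sampled on a stride-2
   fixed grid — the fine-scale minimum at an eighth of the cost.

A simplex-only multiresolution scheme was tried first and could not reach
half-voxel/half-degree accuracy inside a sane budget: the MSD valley is
shallow along rotation about the screw axis, and the simplex crawls in
6D.  The LM polish solves exactly that, and every stage remains
derivative-free from the caller's perspective and fully deterministic.
The result is accepted only if its full-metric loss does not exceed the
initial one, and the final loss is always reported so callers can detect
a capture failure (e.g. an init far outside the capture range).

## Intensity normalization

Each scan is linearly mapped to mean 0 / SD 1000 (population denominator;
voxel counts are huge, so the n vs n−1 choice is numerically immaterial
but is pinned for exact tests).  The statistics are computed over the
whole field by default (a within-mask scope is available as an option).
Normalization is idempotent and exactly invariant to per-scan affine
intensity changes — the property that makes fixed thresholds (300/600 for
bone, 3000 for metal) meaningful across scans.

Order of operations is pinned: register (metric on normalized copies) →
resample the raw follow-up onto the baseline grid → normalize each scan
at native resolution → down-sample to the 160 µm working grid → segment →
carry the surface back to the native grid → measure.  Whether
normalization should precede or follow registration is not observable in
the result (the metric normalizes internally either way); the pinned
order keeps the report reproducible.

## Grid transfer

Down-sampling by an integer factor is a non-overlapping block mean
(trailing partial blocks dropped; origin shifted to the block-center
convention); non-integer factors use Gaussian pre-smoothing
(σ = 0.4 · factor voxels) and trilinear interpolation.  Up-sampling of a
segmentation interpolates the signed distance field trilinearly and
re-thresholds at zero, placing the surface with sub-voxel precision;
plain masks fall back to nearest-neighbor.

## Threshold level-set segmentation

State is a signed Euclidean distance field φ in voxel units, negative
inside (pinned so the curvature sign is unambiguous).  The speed is the
min-of-two-ramps window `F(x) = I − low` below the window midpoint and
`high − I` above it: positive strictly inside the window, zero exactly on
the thresholds, negative outside.  The update is

    φ ← φ − Δt · ( P · F · |∇φ|_upwind − w · κ · |∇φ|_central )

with Godunov upwinding for the propagation term and central differences
for mean curvature.  Numerical choices:

* **Speed normalization.**  Raw F reaches (high−low)/2 = 150 normalized
  units, which no fixed time step satisfying a CFL bound could handle;
  F is clipped to ±(high−low)/2 and divided by that half-width, so
  |F| ≤ 1.  Clipping changes no sign, hence not the zero-curvature fixed
  point.
* **Time step** Δt = 0.45/(1 + w) voxel units, validated against the
  bound 0.5/(P + w); a single curvature step is additionally clamped to
  half a voxel so discrete curvature spikes cannot overshoot.
* **Narrow band** |φ| ≤ 4 voxels, rebuilt at each reinitialization.
* **Reinitialization** every 20 iterations by the exact Euclidean
  distance transform of the sign pattern (±0.5 at voxels adjacent to the
  interface).  An EDT rebuild gives the same signed distance a fast
  sweeping scheme would, with simpler and exactly reproducible code.
* **Stopping rule.**  A per-iteration RMS(Δφ) over the band never falls
  below ~Δt in a narrow-band scheme, because band voxels keep advecting
  even when the interface is stationary.  Convergence is therefore
  declared when the *reinitialized* field stops changing between
  consecutive reinitialization cycles (RMS < 0.001), which is exactly a
  stationary voxel classification.  Iterations and final RMS are
  reported.
* **Initialization** is the thresholded window intersected with the ROI,
  opened with a 1-voxel ball (drops isolated noise voxels); the interval
  is inclusive on both ends while F is zero exactly at the thresholds, so
  boundary voxels are decided by curvature.
* **ROI confinement (pipeline only).**  Inside `run_side` the normalized
  speed is clamped to ≤ 0 outside the ROI.  Without this the front leaks
  along the in-band mandible shell, never converges, and burns runtime;
  the measured result is unchanged because the volume-of-interest rule
  intersects with the ROI regardless.  Library callers get unconfined
  evolution by default, which is what the zero-curvature equivalence
  oracle tests.

The principal correctness oracle: with w = 0 on noiseless data the
converged classification equals plain double-thresholding voxel-exactly.
With the default w = 0.6, spheres of radius ≥ 10 voxels are recovered
within 3% of their analytic volume.

## Volume of interest

Connected components are labeled on (segmentation ∧ ROI); 26-connectivity
is the default (the permissive standard for 3D foreground; 6 and 18 are
available and recorded in the report).  Size ties are broken by the
lexicographically smallest bounding-box corner and flagged.  Volume is
voxel count × voxel volume.

## Paired statistics

Per patient: side changes `V6 − V0`, percent changes `100·ΔV/V0`
(undefined when V0 = 0 — an error, since a fully resorbed *baseline*
cannot happen in this design), and the paired difference
(treated − control change).  Conventions, pinned after an explicit audit:

* Descriptive SDs and Cohen's d use the **population** (n) denominator;
  the t statistic uses the sample (n−1) denominator.  This is the only
  combination consistent with all of the trial's printed numbers
  simultaneously, and both paths are exported so the audit is a test.
* Group percent change is the mean of per-patient percents, not the
  percent of pooled volumes.
* Two intervals are reported for the mean paired difference: the
  published convention mean ± 2·SD_pop (labeled "dispersion interval, as
  published") and the conventional Student-t 95% CI — they answer
  different questions and are kept distinct.
* p values are two-sided; rounding (volumes to mm³, percents to %, d to
  2 decimals, p to 5) happens only in the report layer.

The bundled measurement table stores the published per-side volumes as
printed (integers).  Those integers are themselves rounded from sub-mm³
measurements, so a handful of derived cells (five change cells, the
treated mean change, the control mean percent, the paired-t p and the
dispersion-interval endpoints) can differ from their printed counterparts
by one unit in the last printed digit; tests assert exact agreement where
it is derivable and agreement at input quantization elsewhere.

## The phantom

`PhantomSpec` builds a mandible-angle scene on a 20 mm field of view at
160 µm (80 µm available): a 6 mm-thick mandible block with a 1.2 mm
cortical shell and an oblique lingual face, fully inside the field so
misalignment does not push bone out of frame; a 10 × 10 × 4 mm cortical
graft block on the buccal face; a 2.4 mm-diameter titanium screw through
graft into slab, tilted 8°/4° off the buccal axis.  Trabecular bone gets
a scene-fixed Gaussian random texture (correlation 0.4 mm, SD 400 raw
units).  The obliquity and the texture matter: an axis-aligned box with
an axial screw is nearly symmetric under rotation about the screw axis,
which real anatomy is not, and which would leave that rotation almost
unobservable to any intensity metric.

Acquisition model per scan: `gain · (blurred scene + noise) + offset`,
Gaussian PSF σ = 0.12 mm, i.i.d. Gaussian noise σ = 100 raw units
(≈ 0.08 · the bone–soft-tissue contrast — the level of a working-grid
scan after the native-to-working block averaging), per-scan gain/offset
defaults 1.0/0 and 1.15/150.  Modeling the noise before the gain makes a
per-scan gain/offset an exact affine map of the scan, which is what the
pipeline's intensity-invariance property states.  The follow-up scan is
sampled through the rigid misalignment (default ≈ 2°/1–1.5 mm per axis),
so registering it back should recover exactly that transform.  All
randomness is numpy PCG64 (`default_rng`) seeded per scan from the scene
seed.

Attenuation defaults (soft 0, trabecular 700, cortical 1300, metal
32000) are chosen so that after mean-0/SD-1000 normalization of the
default scene, cortical bone — and hence the graft — lands near the
middle of the fixed 300–600 window (≈ 420) with roughly symmetric noise
margins to both thresholds, i.e. the phantom emulates scans for which
those published settings are appropriate.  Metal normalizes to ≈ 14000,
far above the 3000 detection threshold.

Programmed volume change morphs the graft by thresholding a distance
transform: shrinkage keeps the voxels deepest inside the graft, growth
adds the nearest exterior voxels (restricted to soft tissue), each to the
exact target count — equivalent to choosing the sub-voxel distance offset
by bisection, with deterministic tie-breaking, and accurate to one voxel
by construction.  The slab interface is treated as fused bone, not a free
surface: resorption and apposition proceed from the free faces only,
which is both the physiological behavior for an integrated onlay graft
and what keeps the graft attached at follow-up.  Uniform distance-offset
remodeling is a modeling choice; real resorption is spatially
heterogeneous.

What the phantom does **not** emulate: beam hardening and metal streak
artifacts, scatter, realistic anatomy (teeth, canals), patient motion,
scanner-specific PSFs.  Passing phantom tests therefore demonstrates the
pipeline's numerical correctness and its robustness to blur, noise,
misalignment and intensity scale — not robustness to streak artifacts or
anatomical confounders, which the original protocol handled by manual
mask placement.

## Simulated trials

`run_trial` simulates an internal-control trial; per-side 6-month volume
fractions are drawn from truncated normals (defaults: treated 1.35 ± 0.25,
control 0.42 ± 0.30, mirroring the observed arm means and spreads).
`mode="imaging"` runs the full pipeline per side.  `mode="measurements"`
skips image synthesis and applies a 2% multiplicative measurement error
(the imaging pipeline's validated accuracy scale) to the programmed true
volumes; side exchangeability — the only thing the paired t test's
type-I error relies on — is preserved exactly, which is why the 20-trial
null calibration runs at measurement level.  `transform="truth"` feeds
each side its simulated misalignment, the analogue of the original manual
registration, and is how the 9-patient imaging trial's group-mean
recovery is validated (registration accuracy has its own dedicated
checks).  Problem sizes used by the test suite and the acceptance script
(five or two seeds per programmed fraction for end-to-end recovery, six
to ten registration trials, twenty null trials, one 9-patient imaging
trial) are chosen to give stable medians and counts at desk-scale
runtime.

## Known limitations

* Absolute volumes read systematically low on phantoms (~10–15%): the
  threshold contour sits inside the blurred bone surface because the
  lower threshold lies above the edge midpoint, and the ROI margins shave
  the attachment face.  The bias is proportional at both timepoints, so
  the trial's endpoint — percent change and its side difference —
  is recovered within a few points; absolute volumes should be read as a
  consistent operational definition, not as anatomical truth.
* Only axis-aligned geometry; no DICOM ingestion.
* The segmentation reproduces the *published semantics* (two thresholds
  plus curvature weighting); the original interactive tool's exact
  initialization and stopping rule are not public, so equivalence is
  established through the thresholding oracle, not against that software.
* MSD registration assumes the normalized intensity relationship between
  the two scans is identity; it is, by construction of the normalization,
  unless the scanned content changes drastically between sessions.
* Percent change is undefined for a zero baseline volume (does not occur
  in this design, where baseline is two weeks post-op).
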