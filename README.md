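# graftquant

Serial cone-beam CT (CBCT) volumetry of onlay mandibular bone grafts,
with the paired internal-control statistics used in randomized
split-mouth designs.

## The problem

After orthognathic surgery a cortical bone block (~10 × 10 mm) can be
fixed to the buccal surface of the mandible angle with a titanium
position screw.  Physiological resorption then removes an unpredictable
fraction of the graft within months.  Quantifying that change from serial
CBCT scans is awkward for three reasons: CBCT voxel values are not
calibrated Hounsfield units (each scan has its own gain and offset), the
two scans are never acquired in the same position (rigid registration is
needed), and the graft must be separated from the host mandible and from
metal hardware before its volume means anything.

`graftquant` implements the full measurement chain:

1. **Rigid registration** of the 6-month scan into the baseline frame
   (mean squared difference on normalized copies; centroid
   initialization, Nelder–Mead capture, Levenberg–Marquardt polish).
   A user-supplied transform file bypasses the optimizer.
2. **Intensity normalization** of each scan to mean 0 / SD 1000, which
   removes the per-scan gain and offset exactly.
3. **Masking**: metal is thresholded (default 3000 normalized units) and
   dilated; the host mandible is excluded by user-supplied geometry or a
   supplied ROI mask.
4. **Threshold level-set segmentation** on a 160 µm working grid:
   a signed distance field φ (negative inside) evolves under
   `φ ← φ − Δt (P·F·|∇φ|_upwind − w·κ·|∇φ|)`, where the speed
   `F = min(I − low, high − I)` is positive inside the intensity window
   (defaults 300/600), κ is mean curvature, and w = 0.6 smooths
   noise-induced surface speckle.  With w = 0 on noiseless data the
   result is exactly the double-threshold voxel set.
5. **Volumetry**: the graft volume-of-interest is the largest continuous
   (26-connected by default) segmented-bone component within the mask,
   converted to mm³, with the surface carried back to the 80 µm native
   grid through trilinear interpolation of φ.
6. **Paired statistics**: per patient, the treated-side and control-side
   volume changes and their difference; group means and SDs, a paired
   two-sided t test (`t = mean(d) / (SD_{n−1}(d)/√n)`), and a paired
   Cohen's *d* = mean(d) / SD_n(d).

A first-class **phantom module** simulates the whole scene — mandible
slab with cortical shell and textured trabecular interior, graft block,
oblique titanium screw, programmed resorption/apposition with exact
ground-truth volumes, rigid misalignment, blur, noise, per-scan
gain/offset — so every pipeline stage is validated against known truth.

## Worked example

```bash
python examples/trial_statistics.py
```

prints the per-patient table of the bundled trial measurements (nine
analyzed patients, one excluded for reoperation) and ends with:

```
Mean paired difference 254.2 mm^3 (population SD 108.3), t(8) = 6.64, p = 0.00016, Cohen's d = 2.35
The dispersion interval (mean +/- 2 SD_pop, the published convention) is [38, 471] mm^3; the conventional t-based 95% CI is [166, 343] mm^3.
```

The mean paired difference of ~254 mm³ says the treated grafts ended up a
quarter of a cubic centimetre ahead of their internal controls after six
months; p and *d* say that difference is large and statistically firm for
n = 9 pairs.  The imaging side is demonstrated by

```bash
python examples/simulate_and_measure.py
```

which simulates a patient side with 50% programmed resorption and prints
the measured versus true volumes — they typically agree within a few
percent points of change.

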