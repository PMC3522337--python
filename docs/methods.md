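# Methods

This note documents the models, numerical choices and limitations of the
`airtrapcad` pipeline, in the order the method runs.

## Conventions

Volumes are stored as `(slice, row, col)` arrays with slice 0 at the lung
apex, rows anterior→posterior, columns left→right, and physical spacing
`(dz, dy, dx)` in mm. All areas and volumes are computed in mm²/mm³ via the
spacing, never as voxel counts, because the two respiratory phases of one
subject may be reconstructed with different slice counts. NIfTI files are
written in canonical RAS with the spacing in the header; DICOM series are
read through GDCM with rescale slope/intercept applied, and the slice order
is flipped when the acquisition stored slices inferior→superior. Masks are
unsigned 8-bit NIfTI for interoperability.

## Lung segmentation

Segmentation is per axial slice (the 2-D feature is defined on a single
cut, and per-slice evolution keeps every step inspectable).

**Seeding.** A slice is thresholded at the air threshold (default −320 HU,
configurable), roughly midway between aerated lung (≈ −850 HU) and soft
tissue (≈ 0 HU), so a global ±50 HU calibration offset cannot move a voxel
across it. Air components touching the image border are background and are
discarded, as are components below 50 mm² (noise; two orders of magnitude
below any real lung cross-section). Each remaining component's traced
boundary, resampled to ~2 px arclength spacing, is one initial contour.

**Evolution.** The snake minimizes

    E = Σ_i [ α|x_{i+1}−x_i|² + β|x_{i+1}−2x_i+x_{i−1}|² ] − κ Σ_i edge(x_i)

where `edge = |∇(G_σ ∗ I)|²` is normalized to a slice maximum of 1, making
the external force independent of the intensity scale. The update is
semi-implicit: the internal-energy gradient (a circulant penta-diagonal
operator) is inverted exactly with a prefactored LU solve, the external
force (gradient ascent on the edge map) is explicit. A candidate step that
would raise E is retried with the step γ halved (up to 12 times); if no
decreasing step exists the contour is at a discrete minimum and evolution
stops. This makes the energy non-increasing *by construction* on any input
and the whole evolution deterministic. Convergence is declared when the
mean point displacement drops below `conv_tol`; a contour whose enclosed
area falls below 10 px² has collapsed and is reported as such
(`segment_lungs` drops collapsed contours with a warning — they are noise
or airway cross-sections too small to hold).

**Defaults** (all config-overridable): α = 0.1, β = 0.1, γ = 2.0,
κ = 2.0, σ = 2 px, `max_iter` = 500, `conv_tol` = 0.01 px. The step size
and tolerance were tuned on the analytic disk problem: with the normalized
edge map, pure internal contraction moves a far-from-boundary contour by
only ~0.05 px per iteration, so a coarser tolerance would declare
convergence before the contour ever reaches the boundary. With these
values a circle initialized 8 px outside a −850 HU disk settles within
0.15 px of the true edge, and phantom masks reach Dice ≈ 0.997.

**Airway exclusion.** The tracked trachea/bronchi lumen (dilated by one
voxel to take the rim) is subtracted from the lung mask: the features
target *parenchymal* air trapping, and the conducting airway would bias
the small-area slices near the carina. Left and right lungs are segmented
as separate contours and merged into one mask; `per_lung=True` splits the
mask at the mediastinal midline instead.

## Airway tracking and the carina

Tracking seeds in the top 10% of slices: the first slice holding at least
one body-enclosed air component of plausible lumen area (50–500 mm²) that
remains trackable for 5 consecutive slices. The persistence guard is what
distinguishes a trachea from a lung apex cap — a cap grows past 500 mm²
within a slice or two, a lumen does not — so volumes without any airway
(e.g. bare ellipsoid fields) fail tracking cleanly instead of mislabeling
lung as airway. From the seed, components are followed inferiorly by pixel
overlap between consecutive slices (robust at 3 mm slice spacing, where
centroid distances can be large); components growing beyond the lumen
range are not followed.

The carina is the most superior slice at which the tracked column holds
≥ 2 components with the following two slices also split — a single-slice
split is noise, not anatomy. Detection is independent per phase, so the
2-D feature compares each phase's own carina cut. Appending slices below
the lung base cannot change the result.

## Features

* ΔS_N = (S_insp − S_exp)/S_insp, with S the mask area (mm²) at the
  phase's carina slice.
* ΔV_N = (V_insp − V_exp)/V_insp, with V either the exact mask volume
  (step k = 1) or estimated from slices {0, k, 2k, …} (default k = 17),
  each sampled slice weighted by the number of slice thicknesses it
  represents, `min(k, n−i)·dz`. This truncated-weight scheme is exact for
  axially uniform objects and needs no interpolation; on smooth lung-like
  shapes at the default geometry the k = 17 estimate stays within ~0.015
  of the exact value. Inspiration volumes/areas of zero are degenerate
  inputs, not zeros.

Negative feature values (expiration apparently larger than inspiration)
are physiologically odd but are kept, logged and classified — the
reference patient class has a large spread (σ ≈ 0.23 for ΔS_N) and
clamping would distort the Gaussian class models.

## Classifier

Class-conditional univariate Gaussians (sample mean, sample SD with n−1,
priors empirical class frequencies or 0.5/0.5) feed the minimum-error
likelihood-ratio rule; decision thresholds solve the log-posterior
quadratic

    (1/2σ₂² − 1/2σ₁²)x² + (μ₁/σ₁² − μ₂/σ₂²)x
      + μ₂²/2σ₂² − μ₁²/2σ₁² + ln(p₁σ₂ / p₂σ₁) = 0

with the numerically stable quadratic formula plus Newton polish. Unequal
variances give up to two real roots (the between-means root, the one that
actually separates the classes, is reported first); equal variances one;
no real root means one posterior dominates everywhere and classification
falls back to direct posterior comparison. Every returned root is verified
to sit at posterior equality within 10⁻⁹ — except for ill-conditioned fits
(within-class σ of ~10⁻⁴, roots far outside the data range) where the
log-densities reach ~10⁹ and double precision bounds the verifiable gap;
such roots are kept with a warning. Ties at the boundary go to the patient
class: in a screening context a false alarm is cheaper than a miss.

Severity has no single published scale, so the report exposes only
quantities the fitted models already define: ΔV_N, its z-score
(μ_normal − ΔV_N)/σ_normal, p(patient|ΔV_N), and the residual of ΔV_N from
each class's ordinary-least-squares ΔV–ΔS line (R² = 1 − SS_res/SS_tot).

## Statistical evaluation

The class-separation test is the unequal-variance (Welch) t-test with
Satterthwaite degrees of freedom — the appropriate variant when one class
has triple the spread of the other and samples are 12 vs 25. Diagnostic
metrics use patient as positive; a metric with a zero denominator is
reported as undefined (`None`), never 0. Percentages round half away from
zero to one decimal.

## The phantom: what it emulates and what it does not

`generate_phantom_pair` renders an elliptical soft-tissue torso (0 HU) in
background air (−1000 HU), two lung ellipsoids (−850 HU at inspiration)
and a tracheal tube (−1000 HU) splitting into two main bronchi at a known
slice; expiration scales the lungs about their centroids by `(s_xy, s_xy,
s_z)` and renders them 100 HU denser, mimicking real expiratory
attenuation increase so segmentation is tested under a phase-dependent
intensity shift. Additive Gaussian noise (default σ = 20 HU, typical of
thoracic CT) is seeded and reproducible. Defaults: 96 slices of
192×192 voxels at 3×1×1 mm — an adult-sized ~29 cm z-range with 22 cm
lungs, chosen so the k = 17 subsampling sees 4–5 in-lung cuts, as it would
on a real apex-to-base scan at 3 mm slice thickness. Ground truth is
analytic: ΔS_N = 1 − s_xy², ΔV_N = 1 − s_xy²·s_z, per-slice areas and
voxel-counted volumes ride along in the metadata. The bifurcation slice
sits slightly above the lung z-centre, so the carina-cut area ratio
deviates from 1 − s_xy² by under 0.01 when s_z < 1 (exactly 0 when
s_z = 1).

The cohort simulator draws (ΔS_N, ΔV_N) pairs from class-conditional
bivariate Gaussians with the reference cohort's means and SDs
(normal: 0.3711/0.0825 and 0.4121/0.0762; patient: 0.1749/0.2341 and
0.1996/0.1981) and a within-subject feature correlation of 0.8 — the
normal class's strong area–volume coupling (R² ≈ 0.86 in the reference
data) motivates the default; the much looser patient coupling is why it is
configurable.

What passing the phantom suite does **not** show: the phantom has no
parenchymal texture, vessels, emphysema heterogeneity, cardiac motion or
scanner noise spectra; lungs are convex and the airway is a clean tube, so
real-data segmentation will be harder than the Dice ≈ 0.99 seen here. The
phantom validates the geometry and arithmetic of the pipeline, not its
clinical accuracy.

## Problem sizes

The recovery checks run the full pipeline at shrink factors 0.75/0.85/0.95
on the default 96×192×192 phantom (≈ 5 s per pair); the classifier
near-optimality check uses 10⁴ draws per class; the threshold solver is
verified against a 10⁻⁶-step grid search over 100 random model pairs plus
the two reference parameter sets. Plumbing tests use a half-size phantom
(48×96×96) with proportionally scaled anatomy.

## Known limitations

* Per-slice 2-D snakes, no 3-D surface coupling; no gradient-vector-flow
  or level-set variants, so capture range is limited to a few multiples of
  the smoothing σ (seeding from the threshold boundary makes this moot in
  practice).
* Axial acquisitions only; no oblique reformats, no multi-frame enhanced
  DICOM, no DICOM writing.
* The airway tracker handles the trachea and main bronchi, not the distal
  tree; lobe labels are out of scope.
* The classifier is univariate per feature by design (the reference
  evaluation printed per-feature thresholds); a joint 2-D Gaussian model
  is deliberately not provided.
* Evaluation on the training cohort (the default) reports apparent, not
  generalization, accuracy; `--holdout` exists but is off by default to
  mirror the reference evaluation style.
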