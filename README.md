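# airtrapcad

Computer-aided detection and severity scoring of COPD from paired
inspiration/expiration thoracic CT.

Chronic obstructive pulmonary disease traps air in the lung: downstream of
obstructed airways the parenchyma fails to empty at expiration, so the lung
shrinks less between full inspiration and full expiration than a healthy
lung does. `airtrapcad` quantifies that shrinkage from two CT volumes of
the same subject and turns it into a diagnosis and a severity report. It is
aimed at medical-image-analysis researchers who want a transparent,
fully-testable reference pipeline: every stage can be exercised against a
built-in digital thorax phantom with analytically known ground truth, so no
patient data is needed to validate the code.

## Method

1. **Segmentation** — each axial slice is thresholded at an air-density HU
   value to seed closed contours around body-enclosed air regions; each
   contour is evolved as a parametric active contour (snake) minimizing

   E = Σᵢ ( α·|xᵢ₊₁ − xᵢ|² + β·|xᵢ₊₁ − 2xᵢ + xᵢ₋₁|² ) − κ·Σᵢ |∇(G_σ ∗ I)(xᵢ)|²,

   with a semi-implicit update and step-acceptance that makes the energy
   non-increasing by construction. Rasterized contours form the lung mask;
   the conducting airway lumen is subtracted.
2. **Airway tracking** — the tracheal air column is followed from the lung
   apex slice by slice; the carina (the ridge where the trachea splits into
   the main bronchi) is the most superior slice with a durable split. It
   anchors the 2-D feature and defines the lumen to exclude.
3. **Features** — normalized area variation at the carina cut,
   ΔS_N = (S_insp − S_exp)/S_insp, and normalized total volume variation
   ΔV_N = (V_insp − V_exp)/V_insp, the latter optionally estimated from
   every 17th slice. Normalizing by the inspiration value removes subject
   size (age/height/sex) from the measurement.
4. **Classification** — per class ω₁ (normal) and ω₂ (patient) a univariate
   Gaussian N(μ, σ²) with prior p(ω) is fitted to a feature x; the
   minimum-error rule is the likelihood ratio

   l_r(x) = p(x|ω₁)/p(x|ω₂) > p(ω₂)/p(ω₁) ⟹ x ∈ ω₁,

   with the decision threshold(s) obtained in closed form from the
   log-posterior quadratic. Severity is reported as ΔV_N itself, its
   z-score against the normal class, p(patient|x), and residuals from the
   per-class least-squares ΔV–ΔS lines.
5. **Evaluation** — Welch two-sample t-tests per feature and the five
   diagnostic metrics (sensitivity, specificity, PPV, NPV, accuracy) from
   the confusion matrix with patient as the positive class.

## Worked example

```python
from airtrapcad import *

# one synthetic subject with moderate air trapping
spec = PhantomSpec(s_xy=0.92, s_z=0.92, seed=8)
vol_insp, vol_exp, truth_insp, truth_exp, meta = generate_phantom_pair(spec)
rec = extract_features(vol_insp, vol_exp)
print(f"dS_N = {rec.delta_S_N:.3f}   dV_N = {rec.delta_V_N:.3f}   "
      f"(constructed truth: {meta['true_delta_S_N']:.3f}, {meta['true_delta_V_N']:.3f})")

# reference-cohort models and the decision rule on the volume feature
cohort = generate_cohort_features(12, 25, seed=0)
rule = BayesRule.fit(cohort, feature_name="delta_V_N")
fits = fit_severity_lines(cohort)
print(f"decision threshold (volume): {rule.thresholds[0]:.3f}")
label, post = classify(rec, rule)
print(f"label = {label}   p(patient|x) = {post:.3f}")
for k, v in severity_score(rec, rule, fits).items():
    print(f"  {k}: {v:.3f}")
```

prints

```
dS_N = 0.154   dV_N = 0.219   (constructed truth: 0.154, 0.221)
decision threshold (volume): 0.360
label = patient   p(patient|x) = 0.999
  delta_V_N: 0.219
  air_trapping_z: 3.775
  posterior_patient: 0.999
  residual_normal_line: -0.072
  residual_patient_line: 0.027
```

The phantom's lungs were constructed to shrink by a factor 0.92 per axis
(ΔV_N ≈ 1 − 0.92³ ≈ 0.22, far below the healthy cohort mean of 0.41), the
pipeline recovers both features to ±0.003, and the rule fitted to a
12-normal/25-patient reference cohort flags the subject as a patient with
an air-trapping z-score of 3.8 normal-class standard deviations.

The same pipeline is available from the shell:

```bash
airtrapcad simulate phantom --s-xy 0.92 --s-z 0.92 --seed 8 --out-dir subj/
airtrapcad features --insp subj/insp.nii.gz --exp subj/exp.nii.gz --out features.csv
airtrapcad train --features cohort.csv --out model.json
airtrapcad classify --features features.csv --model model.json --out labels.csv
airtrapcad evaluate --pred labels.csv --truth features.csv --out report.json
```

(`airtrapcad run --manifest manifest.csv --out-dir out/` chains everything
over a subject table.)

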