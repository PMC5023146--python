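# v2g — two-zero-load-geometry right-ventricle mechanics

`v2g` is a desk-scale toolkit for patient-specific right-ventricle (RV)
stress/strain analysis and post-surgical outcome prediction in repaired
tetralogy of Fallot (TOF). Patients with chronic pulmonary regurgitation
undergo pulmonary valve replacement (PVR), but RV function recovers in only
some of them; the toolkit quantifies pre-operative RV morphology and wall
mechanics and asks which of those quantities predict the ejection-fraction
(EF) response.

The mechanical core is the **2G scheme**: because sarcomeres shorten during
active contraction, the zero-stress reference configuration of the ventricle
is not constant over the cardiac cycle. The cycle is therefore modeled with
*two* zero-load geometries — a larger one for the filling (diastole) phase and
a smaller one for the ejection (systole) phase — with the two isovolumic
phases skipped, so stress and strain jump at the phase transitions while the
cavity volume stays continuous. Compared with a conventional single-geometry
(1G) model this exposes end-filling and end-ejection stress/strain states and
raises the begin-ejection stress estimate substantially.

## What is inside

| Module | Content |
| --- | --- |
| `v2g.constitutive` | Modified Mooney–Rivlin strain energies, isotropic `W = c1(I1−3) + c2(I2−3) + D1[e^{D2(I1−3)}−1]` and transversely isotropic (`+ K1/(2K2)[e^{K2(I4−1)^2}−1]`), the Fung-type law `W = C/2 (e^Q −1)` in fiber coordinates, exact-incompressible Cauchy stress, stress–stretch curves, and least-squares fitting of the Mooney–Rivlin form to Fung-law targets |
| `v2g.geometry` | Contour-stack data model (inner/outer contours per short-axis slice), disk-summation ("Simpson") volumes, per-point wall thickness, circumferential / longitudinal curvature by sliding-window circle fits, equal-arc-length quarter partition, two-layer fiber fields |
| `v2g.preshrink` | Iterative pre-shrink: recover the zero-load geometry whose pressurization reproduces the imaged cavity volume (< 0.5 % volume error), shrinking the inner wall more than the outer so the muscle volume is conserved |
| `v2g.forward_model` | Incompressible thick-walled-chamber inflation (volume-equivalent to the contour stack) and the 2G / 1G cycle simulators |
| `v2g.calibrate`, `v2g.model` | Patient calibration (`TwoGeometryModel.fit()` → `TwoGeometryResults`) matching a measured (min, max) volume pair under a four-point pressure schedule (Pmin, Pdia, Pmax, Psys) |
| `v2g.cohort_stats` | Pearson correlation, paired/unpaired t-tests, random-intercept linear mixed-effects model, group summaries |
| `v2g.prediction` | Ridge-logistic outcome prediction over all 255 subsets of 8 predictors, scored by 100 rounds of 20-repeat stratified 2-fold cross-validation (AUC, Youden cutoff) |
| `v2g.data`, `v2g.synthetic` | The published 16-patient tables as checksummed CSV fixtures; synthetic ellipsoidal ventricles and synthetic cohorts |

A `v2g` command-line interface wraps the library
(`v2g curves / geom / preshrink / cycle / stats / predict / fixtures`).

## Worked example

```python
from v2g import synthetic
from v2g.geometry import stack_volume
from v2g.model import TwoGeometryModel

stack = synthetic.generate_ventricle(seed=0)    # in-vivo minimum-volume frame
v_min = stack_volume(stack, "inner")
results = TwoGeometryModel(stack, v_max=1.8 * v_min).fit()
print(results.summary())
```

```
Two-geometry ventricle model results
====================================================
target volumes (cm^3): min 139.59  max 251.26
pressures (kPa): Pmin 0.3  Pdia 1.3  Pmax 8.7  Psys 2.7

phase     shrink-rate  stiffness-factor  vol-err(lo)  vol-err(hi)
diastole      0.0527           0.5329      0.000%      0.000%
systole       0.1142           0.4818      0.014%      0.014%

landmark states:
       p_kpa  vol_cm3  stress_p1_kpa  strain_p1
state
BF       0.3    139.6           1.02     0.0457
EF       1.3    251.3          7.726     0.2637
BE       8.7    251.2          55.05     0.3532
EE       2.7    139.6          9.773     0.1077

max landmark volume error: 0.014%
```

The pre-shrink found a 5.3 % diastolic and 11.4 % systolic shrink rate (the
systolic reference is smaller, consistent with a 10–15 % sarcomere
shortening); both calibrated chambers reproduce the target volume pair to
better than 0.1 %. Stress and strain peak at begin-ejection (BE) and are
discontinuous across the skipped isovolumic transitions — note that EF and BE
share the same cavity volume but not the same stress.

On the cohort side, the packaged tables reproduce the published analysis
directly:

```python
from v2g import data, cohort_stats, prediction

t6 = data.cohort_table()
print(cohort_stats.pearson_corr(t6["dEF"], t6["Stress"]))
# (-0.6084, 0.0124)        EF change falls as begin-ejection stress rises

X = data.predictor_matrix()
r = prediction.repeated_cv(X, (X["group"] == 2).astype(int),
                           subset=["C-cur", "V", "StressE-F"],
                           cfg=prediction.CVConfig(base_seed=17))
print(round(r.auc_mean, 3))  # 0.859 — the best three-predictor combination
```

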