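# virtualstroke

Voxel-wise stroke tissue-outcome prediction and virtual treatment-arm
comparison on a fully synthetic multiparametric-MRI cohort.

## The problem

Small neuroprotection trials in acute ischemic stroke compare follow-up
infarct volumes between two arms, but lesion volumes are tiny on average
and wildly skewed (SD larger than the mean), so a real effect can drown
in between-patient variance. A *virtual comparator* design attacks this:
train one tissue-outcome model per treatment arm on baseline DWI/PWI
voxel features, then predict **both** counterfactual outcomes for every
patient. Each patient becomes their own control and a paired test
compares the two predicted volumes.

Trial MRI is not publicly available, so this package pairs the complete
analysis chain with a synthetic cohort generator whose ground truth
(hemodynamics, ischemic core, tissue fate, and an optional arm effect
`tau`) is known exactly — every stage of the pipeline is testable against
truth, and the design itself can be calibrated: with `tau = 0` the paired
test should reject at its nominal level over replicate cohorts.

## What is implemented

* **Synthetic cohort** — ellipsoidal head phantom; two-arm cohorts
  (default 27 + 25 patients) with skewed lesion sizes (core ~4-5 ml,
  SD > mean), cores nested in hypoperfusion, forward-modelled DWI
  (b = 0/1000) and DSC-perfusion series with a gamma-variate AIF, and a
  per-voxel logistic tissue-fate mechanism with protective log-odds
  shift `tau` in one arm.
* **Perfusion/DWI analysis** — ADC = ln(S₀/S₁₀₀₀)/Δb; block-circulant
  SVD deconvolution (zero-padded to 2N, singular values < λ·σ_max
  truncated, λ = 0.15) giving CBF = max k(t), Tmax = argmax k(t),
  CBV = ∫C/∫AIF, MTT = CBV/CBF; contralateral normalization (rCBF, rCBV
  as ratios; dMTT, dTmax as differences).
* **Segmentation** — brain/CSF by ADC threshold; ischemic core by
  26-connected volume growing under ADC < 550×10⁻⁶ mm²/s; hypoperfusion
  at dTmax > 6 s; tissue-at-risk as the exact set difference; exact
  anisotropic Euclidean distance-to-core map.
* **Features and models** — a 12-feature voxel table per patient
  (tissue probability, region, distance-to-core, ADC, rCBF, rCBV, dMTT,
  dTmax, age, sex, NIHSS, onset-to-treatment); stratified under-sampled
  training sets (all lesion voxels + equal non-lesion sample); two
  arm-specific 100-tree random forests evaluated patient-level
  leave-one-out, predicting both virtual lesions per patient.
* **Statistics** — paired t-test on the volume pairs, Dice vs. the true
  lesion, Bland–Altman agreement with mean ± 2·SD limits, four subgroup
  contrasts, and a Monte-Carlo null/power calibration harness.

## Worked example

```python
from virtualstroke import CohortConfig, simulate_virtual_trial

config = CohortConfig(
    n_theophylline=8, n_placebo=8,
    shape=(24, 24, 16), spacing=(3.0, 3.0, 4.0),
)
result = simulate_virtual_trial(config, seed=7)
print(result.report_text())
```

prints

```
Virtual treatment comparison over 16 patients (0 failed)
  predicted volume, virtual theophylline: 7.92 ml (SD 8.00)
  predicted volume, virtual placebo:      7.85 ml (SD 8.12)
  paired t-test: t = 0.746, p = 0.467
  mean Dice vs truth: theophylline arm 0.869, placebo arm 0.798
  Bland-Altman: mean diff 0.07 ml, limits [-0.63, 0.77] ml
  subgroup tissue_at_risk_present: flagged (group < 2)
  subgroup cortical_vs_lacunar: n = 12/4, t = 0.302, p = 0.767
  subgroup large_vessel_occlusion: n = 9/7, t = 0.336, p = 0.742
  subgroup recanalization: n = 3/13, t = -1.626, p = 0.126
```

Sixteen synthetic patients were generated under the null (`tau = 0`),
processed to maps/masks/features, and both arm forests predicted each
patient's lesion: the two virtual volume means are nearly identical and
the paired test correctly finds no arm difference, while Dice 0.80-0.87
against the true follow-up lesions shows the models did learn the
tissue-fate mechanism. With a protective effect, e.g.
`CohortConfig(..., fate=TissueFateParams(tau=4.0))`, the same pipeline
returns a significant paired difference.

The command line mirrors the library (`generate`, `maps`, `segment`,
`features`, `trial`, `stats`, `all`):

```bash
virtualstroke all --outdir run1 --seed 7
virtualstroke stats --outdir run1 --seed 7   # re-run one stage from cache
```

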