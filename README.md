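# semstory

Analysis tools for studying **semantic control during story generation**:
how the brain's dynamics differ when people ideate ordinary (OR), creative
(CR) or random (RA) stories from a cued triplet of target words, with the
ideation window (silent story conception) as the analysed epoch.

The package implements, end to end and on parcellated BOLD signals:

- **Behavioural text metrics.** Per story, *semantic distance*
  `SD = (1/|φ_t|) Σ_i (1/|φ_nt|) Σ_j (1 − cos(w_i, w_j))` between target
  words `φ_t` and non-target content words `φ_nt` (a novelty proxy), and
  *surprise* `δ = (1/|φ_t|) Σ_i −ln P(t_i | C(t_i))`, the mean
  negative log-likelihood a masked language model assigns to the targets in
  context (an appropriateness proxy); plus the MSE-based stimulus triplet
  selection (similarity ideal 0, normalised frequency ideal 0.5).
- **Signal cleaning** in a fixed order — linear detrend, low-pass 0.09 Hz,
  high-pass 0.008 Hz (order-5 zero-phase Butterworth), OLS confound
  regression — and ideation-window extraction.
- **Inter-subject correlation (ISC)** per ROI and condition, matched by
  target-word triplet, with circular-shift permutation nulls and
  sign-flipping condition contrasts.
- **Group-level searchlight MVPA**: RBF-SVM (C = 1) classification between
  condition pairs and OLS regression of the text metrics, 5 × 2
  cross-validation split by whole trials, permuted-label baselines, the
  5 × 2 cv F-test (F(10, 5)) and an exact permutation p, with
  Benjamini–Hochberg FDR.
- **Connectome harmonic decomposition (CHD)**: template vertex connectome
  from a region tract matrix plus a 10 mm local rule, eigenmodes of the
  symmetric normalised graph Laplacian `Δ_G = D^{-1/2}(D − A)D^{-1/2}`,
  signal projection `ω_k(t) = ⟨F_t, φ_k⟩`, and sliding-window harmonic
  energy spectra (window 4 %, step 2 % of the basis).
- **Network dynamics**: Fisher-z (arctanh) functional connectivity within
  and between the DMN, salience and frontoparietal-control networks, and
  temporal irreversibility `R(τ) = (C_f(τ) − C_r(τ))∘²` from forward vs
  time-reversed lagged correlations (lags 1–15, short/long clusters 1–7 and
  8–15).
- **A synthetic-data generator** that plants each of these effects
  (triplet-locked shared time courses, condition patterns, network
  covariance, lagged directed couplings) with known ground truth, so every
  stage is testable without any external download.

## Worked example

```python
import numpy as np
from semstory import ExperimentDesign, PlantedEffects, make_bold_experiment
from semstory.isc import isc_permutation_null
from semstory.mvpa import ClassifierConfig, group_searchlight_classify

design = ExperimentDesign(n_subjects=6, n_conditions=2, trials_per_condition=4,
                          ideation_volumes=30, n_rois=8, seed=0,
                          counterbalance=False)
amp = np.zeros(8); amp[2] = 3.0          # shared time course at ROI 2
strength = np.zeros(8); strength[5] = 2.0  # condition pattern at ROI 5
effects = PlantedEffects(shared_component_amplitude=amp,
                         condition_pattern_strength=strength)
ds = make_bold_experiment(design, effects, ideation_only=True)

isc = isc_permutation_null(ds, "OR", n_iter=2000, seed=0)
print("ISC at planted ROI:", round(isc.isc[2], 3), "p =", round(isc.p_values[2], 4))

perf = group_searchlight_classify(ds, "OR", "CR",
                                  config=ClassifierConfig(n_label_permutations=19, seed=0))
row = perf.table.set_index("unit").loc["ROI005"]
print("decoding accuracy at planted ROI:", round(row["score"], 3),
      "performance:", round(row["performance"], 3), "p =", row["p"])
```

prints

```
ISC at planted ROI: 0.912 p = 0.0005
decoding accuracy at planted ROI: 0.842 performance: 0.35 p = 0.05
```

The planted shared component produces near-ceiling inter-subject
correlation at ROI 2 with a circular-shift permutation p of 1/2001 (no
null sample reached the observed value), and the planted condition pattern
at ROI 5 is decoded at 84 % accuracy, 35 points above the permuted-label
baseline, at the smallest p the 19-permutation null allows (1/20).

There is also a CLI over the same pipeline:

```bash
semstory all --seed 1 --out run/
```

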