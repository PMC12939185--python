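# scatteromics

Multimodal quantitative-ultrasound (QUS) envelope-statistics imaging and
machine learning for tissue characterization, with a built-in scatterer
phantom simulator.

## The problem

The amplitude distribution of ultrasound backscatter encodes tissue
microstructure. Fully developed speckle (many random scatterers per
resolution cell) has a Rayleigh envelope; sparse or heterogeneous scatterer
populations — as in fibrotic liver, where the variance of scattering
cross-sections grows — produce heavier-tailed *pre-Rayleigh* statistics.
Hepatic steatosis pushes the statistics back toward Rayleigh by packing the
resolution cell with fat-infiltrated hepatocytes, which confounds any single
envelope-statistics parameter. The *scatteromics* approach combats this by
combining several envelope models and feeding a small, interpretable
first-order feature set into standard classifiers, instead of a
high-dimensional radiomics pipeline.

The pipeline implemented here:

1. **Parametric imaging** — beamformed RF → Hilbert envelope → sliding-window
   maps of the Nakagami shape `m` (moment estimator,
   `m = E[I]² / Var[I]`, `I = A²`), the homodyned-K clustering parameter `α`
   and coherent-to-diffuse ratio `k` (X/U log-moment estimator:
   `U = E[log I] − log E[I]`, `X = E[I log I]/E[I] − E[log I]`, inverted
   through the model's forward map), and the histogram Shannon entropy `H`.
   Window sides are 3, 5 and 1 pulse lengths with 50% overlap.
2. **Feature extraction** — 13 first-order statistics (mean, median, mode,
   variance, SD, excess kurtosis, skewness, min, max, Q3, Q1, IQR, range)
   per map over a region of interest: 52 features per subject.
3. **Selection** — Z-score normalization, L1-penalized logistic regression
   (λ by inner cross-validated deviance), and Spearman pruning: of any pair
   with |ρ| > 0.8, the feature with the smaller raw dynamic range is dropped.
4. **Modeling** — SVM, random forest and LDA in 30 × stratified 5-fold
   cross-validation (150 cycles) with per-fold selection, Youden-index
   thresholds, retention probabilities, and an exported best model per
   family.
5. **Evaluation** — AUROC with Hanley–McNeil 95% CI, the full
   confusion-derived panel (sensitivity, specificity, F1, LR±, PPV, NPV,
   balanced accuracy), ten-bin calibration curves, Brier scores, and one-way
   ANOVA for parameter-versus-stage comparisons.

Because no patient data ship with the package, a first-class phantom module
simulates point-scatterer RF frames (Poisson scatterer counts, Gaussian
amplitudes, Gaussian-modulated sinusoid pulse) and generates labeled cohorts
whose class-mean windowed statistics are calibrated against published liver
fibrosis values (e.g. fibrosis-free `m ≈ 0.82` vs early-fibrosis
`m ≈ 0.73`). Every estimator is tested against these generative oracles.

## Worked example

```python
import numpy as np
import scatteromics as sc
from scatteromics.modeling import CVConfig, repeated_cv
from scatteromics.pipeline import cohort_feature_table, single_parameter_aurocs

spec = sc.default_phantom_spec(n_subjects_per_class=30, seed=11)
table, truth = cohort_feature_table(spec)          # 60 subjects x 52 features
config = CVConfig(n_repeats=5, svm_kernels=("linear", "rbf"),
                  svm_c=(0.1, 1.0, 10.0), rf_trees=(100, 250), rf_min_leaf=(1, 5))
result = repeated_cv(table, config, seed=21)

print({k: round(v, 3) for k, v in single_parameter_aurocs(table).items()})
for kind in ("svm", "rf", "lda"):
    print(kind, round(float(np.median(result.cycle_aurocs(kind))), 3))
print(result.retention_counts.sort_values(ascending=False).head(3).to_dict())
```

prints

```
{'m': 0.746, 'alpha': 0.761, 'k': 0.669, 'H': 0.723}
svm 1.0
rf 1.0
lda 1.0
{'m_iqr': 24.0, 'm_kurtosis': 18.0, 'H_kurtosis': 18.0}
```

Each single envelope parameter used alone separates the two phantom classes
only weakly (AUROC ≤ 0.77, because the simulated steatosis shifts both
classes toward Rayleigh), while the multimodal feature models discriminate
essentially perfectly across the 25 validation cycles. The most frequently
retained feature is the within-ROI IQR of the Nakagami map — a dispersion
feature that tracks the patchy heterogeneity of the fibrotic class rather
than its (confounded) mean brightness.

A command-line interface mirrors the stages:

```sh
scatteromics simulate --out cohort/ --seed 1
scatteromics features --cohort cohort/ --out features.csv
scatteromics select   --features features.csv --out selection.json
scatteromics train    --features features.csv --out models/ --repeats 5
```

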