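# Methods

This note documents the models, estimators, simulator design and the
numerical choices behind them, including the places where a convention had
to be fixed.

## Envelope-statistics models and estimators

**Nakagami.** The envelope amplitude `A` follows a Nakagami distribution
with shape `m` and scale `Ω = E[A²]`; equivalently the intensity `I = A²`
is gamma with shape `m` and mean `Ω`. The moment estimator is
`m̂ = (mean I)² / var I` with the population (1/n) variance and
`Ω̂ = mean I`. `m = 1` is Rayleigh; `m < 1` pre-Rayleigh. Inputs need at
least 10 finite samples and nonzero intensity variance.

**Homodyned K.** The complex echo is `ε + X + iY` with mixing variable
`z ~ Gamma(α, 1)` and `X, Y | z ~ N(0, σ²z)`. The coherent amplitude is
`ε = k σ √(2α)`, so `k² = ε² / (2σ²α)` is exactly the coherent-to-total-
diffuse power ratio; `k = 0` reduces to the K distribution and `k = 0`
with large `α` approaches Rayleigh. The sampler and the estimator share
this single convention, so estimator-recovery tests are meaningful.

The X/U estimator computes two scale-invariant intensity statistics,

    U = mean(log I) − log(mean I)
    X = mean(I·log I)/mean(I) − mean(log I)

and inverts the population map `(α, k) → (U, X)`. The forward map is
computed semi-analytically: conditional on `z`, `I/(2σ²) = z·G` with
`G ~ Gamma(1+J, 1)`, `J ~ Poisson(αk²/z)` (the Poisson-mixture form of the
noncentral chi-square with two degrees of freedom). The `z`-expectations of
`log z` and `z log z` are digamma closed forms; the Poisson expectations
`E ψ(1+J)` and `E (1+J)ψ(2+J)` are tabulated once on a log grid (truncated
series below `t = 10⁴`, asymptotics above) and splined; the remaining
`z`-integral uses a 200-node Gauss–Legendre rule in `log z`. At `k = 0`
the closed forms `U = ψ(α) − γ − log α` and `X = 1 + 1/α` are exact and
serve as an internal oracle for the quadrature (agreement ~1e−8).

**Inversion.** The forward map is evaluated on a 60 × 46 grid over
`α ∈ [0.1, 100]` (log-spaced) × `k ∈ [0, 3]`, fitted with bicubic splines,
and inverted by a KD-tree-seeded damped Newton iteration with analytic
spline Jacobians, clipped to the grid bounds (clipping sets a boundary
flag). Because `(U, X)` depend on `k` only through `k²`, the Jacobian is
singular along `k = 0` and raw inversion turns noise of size `δ` into
spurious `k ≈ √δ`. The estimator therefore first tests the K-distribution
submodel: it computes the delta-method sampling covariance of `(Û, X̂)`
from the sample (U and X are smooth functions of the moment triple
`mean I, mean log I, mean I log I`) and, if the Mahalanobis distance to the
`k = 0` curve lies inside the χ²(1 dof) 99% region, returns the constrained
`(α, k = 0)` fit. This removes the square-root noise pathology at `k = 0`
without biasing clearly coherent samples; the flip side, documented here,
is that small true `k` (≲ 0.2 at `α ≳ 4`) is statistically
indistinguishable from a pure K distribution at these sample sizes and is
reported as `k = 0`.

**Entropy.** Shannon entropy in bits of the equal-width amplitude
histogram between the sample min and max; default 40 bins (configurable —
the bin count is not standardized in the field, and with 40 bins
`H ≤ log2 40 ≈ 5.32`). A constant sample has `H = 0` by definition.

## Parametric imaging

Envelopes are per-scan-line analytic-signal magnitudes. Window sides are
physical squares of 3 (Nakagami), 5 (homodyned K) and 1 (entropy) pulse
lengths, converted per axis: axial side = `round(mult · L / Δz)` with
`Δz = c/(2 fs)` (pulse-echo depth per RF sample), lateral side =
`round(mult · L / pitch)`. Steps are `ceil(side/2)` (50% overlap); map
dimensions are `floor((dim − side)/step) + 1`. The pulse length `L` is the
spatial FWHM of the one-way transmitted pulse (`c · FWHM_t`), taken from
frame metadata (the simulator writes its ground truth; real data would
supply the transducer specification — no autocorrelation measurement is
attempted). Windows with fewer than 10 samples are rejected at
construction; windows whose estimator fails (constant envelope, too few
positive samples) yield NaN cells rather than exceptions. Map cells carry
their window-center coordinates so ROI masks drawn on the image grid can
be resampled by center-in-mask lookup.

With the default acquisition (3.5 MHz center frequency, 12 MHz sampling,
0.6 fractional bandwidth, 0.3 mm line pitch) the windows are 30×6, 50×11
and 10×2 samples. Estimates on such windows are correlated-sample moment
estimates: for fully developed speckle the windowed mean of `m̂` lands
near 1.05 rather than exactly 1 (small-sample ratio bias), which the
phantom calibration absorbs.

## The scatterer phantom

One frame is a 2-D Poisson point-scatterer field: per (sample, line) pixel
a Poisson count with rate `density / (pulse extent × beam width)` and a
compound Gaussian amplitude (`√count · N(0,1)`), optionally smoothed
laterally by a Gaussian beam (default FWHM 2 lines), convolved axially with
a Gaussian-modulated sinusoid. `density` is scatterers per resolution cell
(pulse extent in RF samples × 2 lines): ≳10 gives Rayleigh speckle, <1
pre-Rayleigh. Optional periodically spaced scatterers add a coherent
component; optional white noise is off by default (no acquisition noise
model is asserted). Frames carry the acquisition metadata of a 3.5 MHz
convex-probe system sampled at 12 MHz.

**Cohorts.** A cohort class specifies a target class-mean windowed `m`
(and optionally `k`), a between-subject SD of mean `m`, and a patchiness
parameter. Calibration is a bisection on log-density against the windowed
`m`-map mean (monotone in density), run once per class on fixed evaluation
seeds and cached; if a `k` target is given, a second bisection searches the
coherent amplitude and density is re-solved, falling back to the
diffuse-only solution if the coherent lattice would degrade the `m` target
by more than 10%. Per-subject densities are lognormal around the calibrated
value with a spread chosen via the calibration's local slope
`dm/d log₁₀ density` to reproduce the class's between-subject SD.
Patchiness multiplies the density field blockwise (64 × 8-sample blocks,
lognormal with per-class log₁₀ SD) — emulating spatial heterogeneity of
fibrotic tissue. A configurable fraction of each class (default 0.6,
matching the mixed-steatosis composition of published fibrosis cohorts)
receives a 3× density increase, the steatosis confounder that shifts
statistics toward Rayleigh.

The default two-class cohort is calibrated to published fibrosis-stage map
statistics: a fibrosis-free-like class (`m` target 0.82, subject SD 0.13,
patch SD 0.08) versus an early-fibrosis-like class (`m` target 0.73,
subject SD 0.06, patch SD 0.35). The coherent-lattice `k` targets are off
by default: within sliding windows a periodic lattice registers as
structured variance rather than HK coherence, so windowed `k` saturates
near 0.1 and cannot reach the published ≈0.44 without destroying the `m`
calibration; the default classes are therefore diffuse-only, consistent
with the published finding that `k` does not separate fibrosis stages.

**What the phantom does and does not emulate.** It reproduces the
envelope-statistics physics that the method exploits (density-driven
pre-Rayleigh→Rayleigh shifts, steatosis confounding, heterogeneity) under
idealized conditions: no attenuation, no depth-dependent focusing, no scan
conversion, linear propagation, rectangular geometry. Passing tests
demonstrate that the pipeline recovers known generative structure; they do
not establish clinical performance on patient data.

## Selection and modeling protocol

Z-score parameters come from the training fold only; constant features are
excluded and flagged, and non-finite feature values (e.g. the skewness of
an all-collapsed `k` map, flagged invalid by the feature extractor) are
mean-imputed after standardization. The LASSO is L1-penalized logistic
regression (the outcome is binary) over 50 log-spaced penalties
`λ ∈ [1e−4, 10]` with inner stratified 5-fold deviance selection
(`C = 1/(nλ)` in scikit-learn's parameterization); if the chosen penalty
zeroes every coefficient the penalty is relaxed along the grid until one
feature survives. Correlation pruning processes retained pairs in
descending |ρ| (Spearman) order and, strictly above 0.8, drops the member
with the smaller raw (pre-normalization) training dynamic range; ties in
range drop the later column — fully deterministic.

The repeated-CV protocol is 30 × stratified 5-fold (150 cycles) at the
subject level, with selection re-fit inside every training fold.
Hyperparameters are chosen by inner 5-fold misclassification loss: SVM over
{linear, RBF, cubic polynomial} kernels × 5 log-spaced box constraints in
[0.1, 10]; random forest over {100, 250, 500, 1000} trees × minimum leaf
sizes {1, 5, 10, 20}; LDA has no grid and exports its discriminant
coefficients as feature weights. SVM probabilities come from a monotone
logistic (Platt) link fitted on inner-CV decision scores; forests use vote
fractions; LDA its posterior. The operating threshold maximizes the Youden
index over midpoints of sorted unique validation scores (ties take the
lowest threshold; constant scores are flagged degenerate). The exported
model per family is the one from the cycle with the highest validation
accuracy at its threshold, with AUROC breaking accuracy ties and earlier
cycles breaking exact ties. Determinism: every random draw descends from
one seed through a seed sequence, so a fixed seed reproduces all 150
cycles bit-identically.

The phantom pipeline checks in the test suite and the acceptance script run
a reduced protocol — 60 subjects, 5 repeats × 5 folds, SVM {linear, RBF} ×
C {0.1, 1, 10}, forest {100, 250} trees × leaf {1, 5} — grids chosen within
the same ranges to keep a full end-to-end run at desk scale. The null-
cohort check pools cycle AUROCs over the three classifier families and
takes the median; the separated-cohort check takes the best family's median
AUROC, mirroring how the best-performing model is reported. A caveat worth
knowing: on a single null cohort of this size the median cycle AUROC is
itself a noisy quantity — per-fold selection tracks whatever chance
feature-label associations the finite cohort happens to contain, so
individual cohort draws scatter substantially around 0.5 even though the
procedure is unbiased (verified against pure-noise feature tables, where no
systematic optimism appears).

## Evaluation

AUROC is pairwise concordance (ties one half), identical to the normalized
Mann–Whitney U; the 95% CI uses the Hanley–McNeil asymptotic variance (the
method is recorded in the report so a resampling CI can be swapped in).
The panel metrics follow the standard definitions; zero denominators are
flagged (LR+ at perfect specificity is reported infinite). `metrics_from_
rates` reproduces derived quantities from printed primary rates, matching
how published tables compute LR±, balanced accuracy and F1 from rounded
percentages. Calibration uses ten equal-width bins on [0, 1]; empty bins
are kept and flagged. One-way ANOVA is the classical between/within mean-
square F (scipy), applied to per-subject ROI means of each map; no
multiple-testing correction, matching per-parameter reporting. Report JSON
is timestamp-free and key-sorted so reruns are byte-identical.

## Known limitations

* The homodyned-K `k` parameter is weakly identified near `k = 0` from the
  (U, X) statistics; the submodel test makes this explicit rather than
  noisy.
* Entropy values depend on the window sample count; with 1-pulse-length
  windows (20 samples) `H` is far below its 40-bin ceiling, so absolute
  entropy values are not comparable to systems with other window/bin
  choices.
* Phantom calibration targets class means of `m` (and optionally `k`); `α`
  and `H` class statistics follow from the physics rather than being
  matched, and the coherent-lattice mechanism cannot reproduce large
  windowed `k`.
* The lateral window size convention on a convex probe (physical square in
  mm) is a package choice; systems deriving lateral extent differently will
  produce different map grids.
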