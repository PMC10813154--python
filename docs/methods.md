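# Methods

## Signal model and preprocessing

Input records are multi-lead ECG blocks: an ordered map of lead name →
samples in mV, a sampling rate fs (reference 1000 Hz) and a diagnostic
class out of eight (BBB, CardMyo, HC, M, MH, MI, VHD, Dis). The
canonical lead order is the 12 conventional leads (I, II, III, aVr,
aVl, aVf, V1–V6) followed by the 3 Frank orthogonal leads (Vx, Vy,
Vz); every downstream column layout uses this order. Records with a
subset of leads are accepted and flagged; per-lead analyses simply
skip missing leads, the ensemble analysis requires the full set.

Each lead is normalised by division by its total energy,
y(n) = x(n) / Σₖ x²(k), and then de-meaned. This energy-division form
is the package default (`normalization_mode="energy"`); the
conventional unit-energy scaling y = x/√(Σx²) is available as
`"unit_energy"`. The two differ only by a positive per-record scale
factor, which affects the scale-sensitive features (En, LogEn, ShaEn)
but none of the scale-invariant ones; the z-score applied to the final
matrix removes per-column scale anyway, so the choice is largely
cosmetic downstream. De-meaning is applied after the normalisation; the
opposite order is one flag away in the code and differs only in the
scale factor. Windows are non-overlapping 1-s segments
(`window_s = 1.0`); a trailing remainder shorter than one window is
discarded so all windows have equal length.

## Octave-band decomposition

A critically decimated discrete wavelet filter bank (Symlet7, depth
S = 3, symmetric boundary extension) splits each window into S+1 = 4
sub-bands. With the normalised angular frequency π ↔ fs/2, band m = 0
occupies [0, π/2^S] and band m ≥ 1 occupies [π/2^(S−m+1), π/2^(S−m)];
frequency rises with m, and the intervals tile (0, fs/2] exactly
(asserted with rational arithmetic). At fs = 1000 Hz this gives
0–62.5, 62.5–125, 125–250 and 250–500 Hz.

Features need full-rate sub-band series of the window length. The
default strategy (`resample="reconstruct"`) inverts the DWT keeping
only the coefficients of one level at a time, which is exactly
length-preserving and makes the bands sum back to the input window to
< 1e−8 (orthogonal wavelet). A second strategy
(`resample="coef_interp"`) cubic-interpolates each decimated
coefficient sequence up to the window length; it is provided for
sensitivity checks, since band-limited reconstruction is the
reproducible, self-consistent default. Cross-band energy leakage is
confined to band edges; the energy partition holds to within 1% on
broadband windows.

## The 10 non-linear features

All hyperparameters live in `FeatureParams`; none of the published
descriptions of this analysis style pin them, so the defaults follow
the standard literature choices and every one is configurable. The
canonical feature order is (ApEn, CorrDim, DFA, En, H, EH, K, LogEn,
ELay, ShaEn).

- **ApEn** — Pincus approximate entropy, embedding m = 2, tolerance
  r = 0.2 × SD of the segment, Chebyshev distance, self-matches
  included: ApEn = Φ^m(r) − Φ^(m+1)(r). A constant segment returns
  exactly 0.
- **CorrDim** — Grassberger–Procaccia correlation dimension on a 2-d
  delay embedding (delay 1, Theiler offset 1): least-squares slope of
  log C(l) vs log l over 20 log-spaced radii between the 2nd and 50th
  percentile of the pairwise distances. The scaling region is the
  usual compromise: small enough to avoid attractor-size saturation,
  large enough for pair statistics. A sine embedded at quarter-period
  delay measures ≈ 1 (closed curve); i.i.d. noise approaches 2.
- **DFA** — first-order detrended fluctuation analysis over 12
  log-spaced box sizes from 4 to N/4; the exponent α (slope of
  log F(n) vs log n) is returned, since one scalar per window is
  required. White noise gives α ≈ 0.5, random walks ≈ 1.5.
- **En, LogEn, ShaEn** — Σ|x|², Σ log₂|x|², and −Σ|x|² log₂|x|²
  respectively, the entropies in the unnormalised wavelet-entropy
  style with an eps = 1e−12 floor inside the logarithms. A normalised
  ShaEn mode (probabilities p = |x|²/Σ|x|²) is available and coincides
  with the default at unit energy.
- **H** — Higuchi fractal dimension, kmax = 10, slope of ln L(k) vs
  ln(1/k) of the averaged curve lengths. Affine-invariant; lines give
  1, white noise ≈ 2.
- **K** — Katz fractal dimension with unit abscissa spacing,
  K = log₁₀(n′)/(log₁₀(n′) + log₁₀(d/L)); straight lines give exactly
  1 because d = L collapses the formula.
- **EH** — generalized Hurst exponent of order q = 2 over delays
  τ = 2…19, computed on the cumulative sum of the de-meaned segment
  (the segment is treated as the increments of a walk, the R/S-style
  convention): the slope of log K_q(τ) vs log τ divided by q. Under
  this convention white noise measures ≈ 0.5 and strong trends
  approach 1; applying the moment ratio to the raw segment instead
  would send white noise to 0, which is not the regime convention the
  rest of the feature set uses.
- **ELay** — largest Lyapunov exponent per sample via the Rosenstein
  nearest-neighbour divergence method (embedding 5, delay 1, Theiler
  window of one mean period from the dominant Fourier component,
  divergence tracked for 10 steps, slope fitted below the saturation
  level of half the mean inter-point distance). The analytic map form
  λ = ⟨ln|f′|⟩ requires the system's derivative and is therefore used
  only as a test oracle (logistic map at r = 4: λ = ln 2); measured
  signals always go through the data-driven estimator.

Degenerate inputs never produce NaN: constant segments return the
sentinel vector (0, 0, 0, En, 1, 0.5, 1, LogEn, 0, ShaEn), and any
non-finite intermediate is replaced by the feature's sentinel.
Features are pure functions of (segment, params) — no global RNG.

## Compression and matrix layout

Each (lead, feature, sub-band) series of per-window values is
compressed by Avg, Std, P95, Var, Med and Kur, in that order. Std and
Var use sample (n−1) denominators; the 95th percentile interpolates
linearly between order statistics; kurtosis uses the non-excess
convention (Gaussian → 3, biased moment estimator), matching the
common numerical-environment defaults for this kind of pipeline.
Kurtosis of a constant series is reported as the sentinel 0. Columns
are named `lead__feature__m<subband>__stat` and ordered lead-major,
then feature, then sub-band, then statistic: 240 columns per lead,
3600 for the full 15-lead record, and each original feature spans
6 × 4 × 15 = 360 columns of a full analysis.

The matrix is z-scored per column. The default scope is **global**
(all rows), mirroring the extraction pipeline this framework models,
which normalises before classification; this leaks test-row statistics
into training under LOOCV, so the leakage-safe `per_fold` scope (fit
on training rows only) is implemented and exposed. Constant columns
are set to 0 and flagged rather than dropped, keeping the column
layout invariant.

## Individual-feature screening

All unordered pairs of the 8 groups give 28 binary comparisons. The
canonical naming order (VHD, M, MI, MH, HC, Dis, CardMyo, BBB) puts
the rarer class first, and the first-named group is the positive
class; this is what makes the "Recall 0% at high accuracy" pattern
visible when a minority class is swamped. Normality is gated by a
Kolmogorov–Smirnov test of each standardised sample against the
standard normal and homoscedasticity by Levene's test (samples < 3 are
treated as assumption-failed); group differences are screened with the
two-sided Mann–Whitney test — exact null distribution when
n_a·n_b ≤ 400 with no ties, normal approximation with tie correction
otherwise — at α = 0.05 with no multiple-testing correction by
default (Benjamini–Hochberg is available via `mtc="bh"`).

The single-feature "XROC" classifier is leave-one-out over the pooled
samples. Its published internals are not reproduced anywhere
accessible; the default rule is nearest training-fold class mean
(consistent with the description of an averaging construction that is
sensitive to outliers), with a training-fold Youden-optimal ROC
threshold as the alternative. When a fold empties a size-1 class, the
fold predicts the remaining class. Best-per-comparison rows are picked
by accuracy, then recall, then lexicographic column name — the
tie-break is a package convention chosen for determinism.

## Combined-feature classification

The registry holds 19 scikit-learn configurations: AdaBoost, BaggC,
DeTreeC (max_depth 5), ExTreeC (300 estimators), GauNB, GauPro
(1.0·RBF(1.0)), GradBoost, KNN, LinDis, LinSVC, LogReg (lbfgs),
LogRegCV (cv 3), MLP (α=1, max_iter 1000), OvsR (one-vs-rest over
logistic regression, random_state 0), RF (max_depth 5, 300 estimators,
max_features 1), SGD (max_iter 100, tol 1e−3), SGDCMod
(modified-Huber loss), SVC (gamma auto) — plus QDA (shrunk eigen
solver, so per-class covariances stay defined on wide matrices)
filling the 19th slot as the package's own registry completion; QDA
results should be read as such, not as a reference configuration. One global seed governs every stochastic
classifier, and the run manifest records library versions.

Evaluation is leave-one-out per (comparison × lead set × classifier)
cell, lead sets being each single lead plus the all-lead "ensemble"
concatenation (3600 columns). AUC uses the classifier's decision
function when exposed, predicted probabilities second, hard labels
last, and the source is recorded per cell — hard-label AUC is a
degenerate two-point ROC and must be distinguishable in reports.
Multi-class (all-vs-all) aggregation: micro accuracy, class-size
weighted precision/recall/F1, multi-class Cohen's kappa and MCC,
one-vs-rest weighted AUC, macro CSI and Gmean over classes.

## Metrics

The binary metrics are computed from TP/TN/FP/FN as listed in the
README. Two deliberate conventions: MCC is reported on its true
mathematical range [−1, 1] (descriptions of this metric as spanning
[0, 1] understate the formula's range), and Specificity inside Gmean
is TN/(TN+FP) by default with the variant TN/(FN+TN) available as
`specificity_mode="as_printed"` for comparison with sources using that
form — the two coincide exactly when FN = FP. Zero-denominator
ratios are reported as explicit `None` sentinels with the convention
Recall = 0 when TP = 0 and FN > 0. The rank-based AUC (ties counted
half) is algebraically identical to trapezoidal ROC integration,
which the tests verify against an independent implementation.

## Synthetic cohorts

The generator emulates the reference cohort geometry: 15 leads, 10 s,
1000 Hz, 8 classes. Each record derives from a single sum-of-Gaussians
beat-train source (P, Q, R, S, T waves on a normalised beat phase;
heart rate 70 ± 5 bpm between records) projected onto the leads by
fixed gains (negative for aVr, V1, Vz) plus 0.02 mV per-lead Gaussian
noise. Class morphologies deform the healthy template: ST elevation
and reduced R for MI; QRS widened ~2.8× for BBB; global attenuation
for CardMyo; T inversion for M; tall R for MH; prominent P for VHD;
RR jitter raised from 3% to 25% for Dis. The default cohort is
balanced; `table3_spec(scale)` reproduces the reference cohort's
9:15:75:3:4:362:4:11 class imbalance scaled down (floored at 2 so
LOOCV stays defined), which is the preset used to exercise the
minority-swamping pathology.

What the synthetic cohorts do **not** emulate: real vectorcardiographic
lead geometry (all leads are scaled copies of one source plus noise),
baseline wander, muscle/powerline artifacts, beat-to-beat morphology
variability within a record, and the physiological heterogeneity of
real diagnostic classes. Passing the end-to-end tests therefore shows
that the pipeline's mathematics and plumbing are correct and that it
can recover known morphological differences at realistic SNR — it
does not certify clinical discrimination performance, which depends on
real data these cohorts intentionally do not replay.

## Problem sizes and numerical choices

The test suite runs desk-scale problems chosen as the smallest sizes
at which each property is stable: structural checks on a 5-record
full-lead cohort; screening calibration on 12v12 Gaussian matrices
(10 permutations × 240 columns); the imbalance pathology on the scaled
imbalanced preset restricted to one lead; end-to-end discrimination on
7v7 single-lead cohorts over the full 19-classifier grid. Feature
estimators are exercised at n = 1000–4000 where their known limits
(DFA 0.5/1.5, Higuchi 1/2, Hurst 0.5, Lyapunov ln 2) have comfortably
converged. Logarithm floors use eps = 1e−12; all slope fits are
ordinary least squares in log-log coordinates; ties and tie-breaks
are deterministic throughout (stable sorts, lexicographic final keys).

## Known limitations

- The energy-division normalisation makes the pre-z-score feature
  scales depend on record length; use `unit_energy` when comparing
  raw feature values across records of different duration.
- Reference values published for real-data analyses of this style are
  not digit-for-digit reproducible without the original records and
  their unpinned feature hyperparameters; this package reproduces the
  method and its qualitative behaviour, with every hyperparameter
  pinned and configurable.
- The global z-score default intentionally reproduces a leakage-prone
  published procedure; per-fold scoping is provided and should be
  preferred for new analyses.
- No wavelet-family selection, feature selection or class rebalancing
  is implemented; the registry is fixed at the 19 configurations.
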