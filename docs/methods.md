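# Methods

## The transform

The core primitive is a 5-level decimating filter bank (Mallat pyramid)
with the 8-tap Daubechies-4 pair: the scaling filter `h(n)` is hard-coded
from the standard tabulated values normalized to `Σh = √2`, and the
wavelet filter is its quadrature mirror `g(n) = (−1)ⁿ h(L−1−n)`. Boundary
handling defaults to **periodic extension**, which makes the transform
exactly orthogonal: coefficient counts halve exactly per level
(2048 → 1024/512/256/128/64 + 64), Parseval holds to round-off, and the
synthesis bank is the transpose of the analysis bank, giving perfect
reconstruction below 1e-10 max-abs error. A symmetric-extension mode is
available for comparability with common toolboxes; it is only
approximately energy-preserving and has no reconstruction path.

Phase convention: approximation coefficient `k` of one analysis step is
`Σₙ h(n)·x((2k−3+n) mod N)` — the convention used by standard periodized
DWT implementations, fixed so that coefficient-level comparisons against
an independent reference are meaningful at 1e-8 rather than only up to a
shift.

Signals whose length is not a multiple of `2^levels` (e.g. 2500-sample
10 s trials at 250 Hz) are right-padded by periodic repetition to the next
multiple; the pad length is recorded and energies are computed on the
padded coefficients. This keeps one code path and biases both classes
identically; it is a small, documented bias rather than a hidden one.

Nominal band edges are the dyadic halvings of the sampling rate: Di covers
`[fs/2^(i+1), fs/2^i)` and A5 covers `[0, fs/2^6)`. Reported range strings
truncate (not round) edges to two decimals — at 250 Hz: D1 62.50–125,
D2 31.25–62.50, D3 15.62–31.25, D4 7.81–15.62, D5 3.90–7.81, A5 0–3.90 Hz.

## Features

Relative wavelet energy per band = sum of squared band coefficients over
total coefficient energy. The six fractions sum to one per (epoch,
channel) and are invariant to amplitude rescaling, so per-channel gain
differences drop out by construction. One matrix per band (epochs ×
channels) keeps the bands separable downstream; D1 is computed and
reported but excluded from classification by default as a noise band.
A zero-energy channel raises an error naming the epoch and channel —
never a silent NaN.

## Selection

Fisher's discriminant ratio uses the canonical form
`(m₁−m₂)²/(σ₁²+σ₂²)` with population class variances; it is invariant to
affine feature rescaling and zero exactly when class means coincide. An
`as_printed` variant `|m₁−m₂|/|σ₁²−σ₂²|` is provided strictly for
side-by-side comparison with a formulation occasionally seen in the
applied literature; it is not scale-invariant and never the default. When
a denominator is exactly zero while means differ, it is floored at 1e-12
and the feature flagged.

"Above the median" keeps the top `⌈p/2⌉` features ranked by score
descending with ties broken by ascending original index — deterministic,
and identical to the strict reading whenever scores are distinct.

PCA is computed by SVD of the centered kept-column matrix (centering is a
no-op after z-scoring on the same split but matters in fold-wise mode);
eigenvalues use the 1/(N−1) normalization, which cannot affect the
variance-fraction rule. `m` is the smallest count whose cumulative
eigenvalue fraction reaches the target (default 0.95); component signs are
fixed so each column's largest-magnitude entry is positive. The
m-dimensional component scores are the classifier input; selection is
fitted independently per sub-band.

## Evaluation

Fold assignment is a seeded shuffle followed by round-robin within each
class (stratified; fold sizes and per-class counts differ by at most one).
Confusion counts are pooled over the 10 held-out folds so every instance
is tested exactly once; per-fold metrics are retained. Class 1 (the task
condition) is the positive class. Metrics are computed from the pooled
table: accuracy / sensitivity / specificity / precision as percentages,
Cohen's kappa with `P_e = Σ_c pred-marginal_c · true-marginal_c`, and AUC
as the rank statistic (ties half) over held-out decision scores — the SVM
decision function, class-1 posterior for naive Bayes and the MLP, and the
neighbor-vote fraction for KNN. A metric with a zero denominator is
reported as missing with a reason, never coerced to 0.

Hyperparameters not otherwise determined: KNN uses Euclidean distance;
SVM-RBF `C = 1`, `γ = 1/(m·Var)` ("scale"); the MLP has one hidden layer
of 5 logistic units, ≤1000 iterations, seeded initialization (the fixed
iteration budget means sklearn's convergence warning is expected and
suppressed in the harness); naive Bayes is Gaussian with per-class
variances. All are exposed through `ClassifierSpec`. Classifier *training*
is delegated to scikit-learn; folds, confusion bookkeeping and all metrics
are implemented here and tested against brute-force oracles.

Two leakage modes: `foldwise` (default) fits z-scoring, FDR and PCA on the
nine training folds only; `paper_global` fits them once on all data before
CV, reproducing the optimistic procedure implied when studies standardize
and select before cross-validating. The report echoes the mode, FDR
variant, boundary mode, all seeds and all hyperparameters, so no run is
ambiguous about its choices.

## Synthetic data

Each channel is `Σ_band w(band, class) · s_band(t) + λ·pink(t)`, scaled by
a per-channel gain drawn in `[1−jitter, 1+jitter]`. `s_band` is a sum of
K = 40 random-phase sinusoids with frequencies uniform strictly inside the
band (2 % of the bandwidth clear of each dyadic edge, limiting leakage
through the finite filter transition bands), normalized to unit sample
variance, so a band's expected energy share is analytically
`w²/Σw²` when `λ = 0`. Pink noise is white noise spectrally shaped by
`1/√f` with the DC bin zeroed, normalized to unit variance. Every epoch
draws from a substream keyed by (master seed, class, epoch index), so the
dataset is bit-reproducible and an epoch's content never depends on how
many others are generated.

Defaults are the study conditions used by the tests and the acceptance
script: 280 epochs per class, 8 channels, 250 Hz, 2048-sample epochs
(≈8.2 s, a power of two so the pyramid needs no padding), task class
weights {A5: 1.6, D5: 1.3, others 1.0} vs baseline all 1.0, pink level
0.5, gain jitter 0.05, seed 42 — a low-frequency power shift of the kind
cognitive-task EEG shows, at an effect size large enough to be cleanly
recoverable. Eight channels keep the default runs fast; the 128-channel
montage is exercised where layout matters.

What the generator does **not** emulate: evoked transients, artifacts
(blinks, drift), non-stationarity, inter-subject variability, or any
channel covariance structure (channels are independent draws). Passing
tests therefore demonstrate that the pipeline recovers band-power
contrasts under clean, stationary conditions and stays at chance on null
data — not that it attains any particular accuracy on real recordings.

## Numerical and design notes

- Population (not sample) standard deviation in z-scoring; immaterial at
  the default sizes and idempotent by construction.
- Histogram diagnostics use Freedman–Diaconis bins floored at 10; the
  class-overlap diagnostic is the folded rank AUC (0.5 = overlap,
  1 = separation), invariant under monotone transforms.
- Degenerate inputs raise: odd-length periodic analysis, zero-energy
  epochs, single-class score/selection inputs, rank-0 PCA input,
  zero-variance features map to 0 with a warning naming them.
- EDF support is read-only via MNE; a minimal classic-EDF (16-bit) writer
  exists so round trips can be tested without external files. Marker
  segmentation crops pairs to the shortest segment (or a configured fixed
  length) and counts dropped/unpaired segments.
- Problem sizes in the test suite and acceptance script (8 channels,
  ≤280 epochs per class, 100-signal transform checks) were chosen as the
  package's own desk-scale defaults; all scale linearly upward through
  configuration.

## Known limitations

- Only binary classification; subject identity is not modeled, so
  subject-wise evaluation is not exercised on realistic grouped data.
- Symmetric boundary mode has no synthesis path and relaxes energy tests.
- The `as_printed` FDR variant is for comparison only and can invert
  rankings under rescaling; reports always name the variant used.
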