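# Methods

This document records the package's modelling choices, parameters and
default problem sizes. Everything here is a design decision of the package
itself; all quantities are reproducible from a single seed.

## Data model

A **recording** is six equal-length 1 Hz activity-count series from one
sensor location (axis 1–3, steps, inclinometer, vector magnitude), stored as
an 8-column CSV (`Date, Time, Axis 1..3, Steps, Inclinometer, Vector
Magnitude`). Counts are non-negative and finite; timestamps must advance in
strict 1 s steps (gaps raise an error rather than being resampled). A
participant wears two sensors (hip and ankle), contributing 12 series.

**Label tracks** are minute-aligned, half-open `[start, end)` intervals of
intended jogging, either self-reported (`diary`) or visually corrected
against the signals (`golden`). Touching intervals merge; overlaps are an
error. Jogging is the positive class (label 1).

## Segmentation

Two stock window specifications: 60 s length with no overlap, and 180 s
length with 120 s overlap (60 s shift). Windows are aligned to whole
minutes from the recording start and never span midnight. A window is
labeled jogging only if fully inside a labeled interval, non-jogging only if
fully outside; border windows are excluded from feature matrices (they still
enter prediction timelines). Only participant-days containing at least one
labeled jogging interval are used, which bounds the class imbalance.

## Feature extraction

Per window and per original series (n = window length in samples):

* **14 basic statistics** — min, max, range, mean, harmonic mean, geometric
  mean (0 if any value ≤ 0), mode (smallest on ties), standard deviation
  (ddof = 1), variance, skewness (m3/s³) and kurtosis (m4/s⁴,
  non-excess; 0 on zero-variance windows), snr = mean/std (0 on zero
  variance), energy and energy/n. Energy defaults to Σx² (signal-processing
  convention); the plain-sum variant is available as `energy="printed"`.
* **h histogram counts** — equal-width bins with h from the Sturges rule
  `h = ceil(log2 n + 1)`: 7 bins at n = 60, 9 at n = 180. Bin edges are
  global per series, fitted **on the training split only**; a degenerate
  (constant) range is widened by ±0.5. At transform time, values outside
  the global range count into the terminal bins.
* **14 percentiles** — quartiles, median, IQR and the 5/10/20/30/40/60/70/
  80/90/95 levels, linear interpolation.
* **8 autocorrelation features** — at lags {1, 2, 4, 30} for n = 60 and
  {1, 2, 4, 90} for n = 180: the classical statistic
  `Σ(x_i − x̄)(x_{i+τ} − x̄) / ((n − τ)·s²)` with the unbiased variance, and
  the Pearson correlation of the window with its lagged copy. Zero-variance
  windows yield 0. An alternative power-of-two lag generator
  (`{n/2} ∪ {2^i ≤ n/2}`) is provided but not the default.
* **5 curve-fit coefficients** — least-squares linear (c1, c0) and quadratic
  (c2, c1, c0) fits over abscissa 0..n−1.

That is 48 features per series at n = 60 (50 at n = 180). Across 12 series
plus one hip–ankle vector-magnitude correlation and three gender features
(male/female indicators and a Weight-of-Evidence encoding with additive
smoothing 0.5 per cell, fitted on training data; unseen categories map
to 0): **580** columns at 60 s, **604** at 180 s.

### Derived series

For each series retained by the importance screen (below), three derived
blocks are added:

* **delta** (window mean minus each value): histogram + percentiles, h + 14
  features — the other families are redundant on a per-window centering;
* **first derivative** (consecutive differences, length n − 1): basic
  statistics + histogram + percentiles + curve fits, 14 + h + 14 + 5;
* **FFT-derived**: per-component frequency (k/n Hz), amplitude (2|X_k|/n)
  and magnitude (|X_k|²) of the real-input DFT with DC excluded; 13
  distribution statistics of each of the three series plus the
  amplitude-weighted spectral centroid, 3·13 + 1 = 40 features.

With 10 retained series at 60 s: 480 original + 4 shared + 210 delta + 400
derivative + 400 frequency-domain = **1494** columns (**1554** at 180 s).
A **baseline** feature set — the first five power-spectrum coefficients
(k = 1..5) per retained series — is available for comparison.

## Feature selection (drift-aware)

1. **Series screen** — a 1000-tree extremely-randomized ensemble
   (`max_features="sqrt"`) is fit on the 580-column training matrix;
   features are grouped by parent series and a series whose average
   importance is more than 3× below the best series is discarded with all
   its features. On the synthetic cohorts the inclinometer series (uniform
   noise by construction) are always discarded; depending on how strongly
   the ensemble concentrates importance, the low-count steps series may
   fall below the cutoff as well.
2. **Drift sensitivity** — an artificial origin-classification task (does a
   row come from training or validation?) is fit with the same ensemble;
   its importances estimate how unstable each feature is across splits.
3. **Percentile grid screen** — all 81 combinations of importance and drift
   percentile thresholds (10..90) are scored with a logistic-regression
   wrapper on validation accuracy; a feature must have importance at or
   above the importance cut AND drift at or below the drift cut. Ties
   prefer fewer features, then a stricter drift threshold.
4. **Diversified forward-backward (DFB) wrapper** — survivors, ranked by
   importance, are greedily added on strict validation-accuracy
   improvement; a failed addition permanently blacklists the feature.
   Backward removal passes alternate with forward passes until a fixed
   point or a budget of 2000 evaluated feature sets. The empty set scores
   as the majority-class validation accuracy.

Runs can be restricted per sensor location (`ankle`, `hip`, `all`) — single-
location runs exclude the gender and cross-sensor columns — and a `union`
variant pools the best ankle and hip sets.

## Classification

Four algorithms: logistic regression (library defaults, max_iter = 1000),
random forest and extremely randomized trees (1000 trees,
`max_features="sqrt"`), and an RBF-kernel SVM standardized to training
statistics, with (C, γ) tuned on the validation split over
C ∈ {0.1, 1, 10} × γ ∈ {10⁻², 10⁻³, 10⁻⁴, 10⁻⁵} (ties prefer smaller C,
then smaller γ). Metrics: accuracy, AUC (from continuous scores), precision,
recall, specificity and F1, with jogging positive.

**Balanced evaluation**: each split is under-sampled per participant (all
jogging windows kept, an equal number of that participant's non-jogging
windows drawn), the model trained and evaluated on balanced sets, repeated
100 times (50 in the acceptance script) and averaged; the SVM is re-tuned
per repetition.

## From windows to periods

With a 60 s shift, every interior minute block is covered by up to three
windows (for 180 s windows); its label is the majority vote, ties and
uncovered blocks falling to non-jogging. Maximal jogging runs become
periods, then:

* **Rule 1** removes periods of ≤ 3 minutes;
* **Rule 2** = rule 1, then merges neighbours with a pause ≤ 5 minutes;
* **Rule 3** = rule 2, then merges neighbours whose pause is at most the sum
  of their current durations, cascading to a fixed point.

The **matching ratio** compares two period lists at minute resolution:
`matched / (matched + missed + other)` — the period-level analogue of
TP/(TP+FN+FP). Rules are applied to *both* the predicted and the reference
lists before matching.

## Synthetic cohorts

The generator reproduces the statistical structure the pipeline depends on,
not gait mechanics. Jogging counts follow
`gain · (base + amplitude·|sin(2πft)|) + noise` (truncated at zero,
f = 1.4 Hz), so short-lag autocorrelation is high inside bouts; the vector
magnitude is recomputed from the axes; steps are Poisson (2.8 Hz cadence
while jogging); the inclinometer is uniform noise. Bout durations are
lognormal with mean ≈ 20 minutes (clipped to 1–90); each day holds 1–2
bouts plus occasional ≤ 3-minute bursts (rule 1's work) and 1–4-minute
intra-bout pauses that stay labeled jogging but carry light-activity signal
(rule 2's work). Split-level gain multipliers (train 1.0, validation 1.25,
test 1.15) emulate concept drift; diaries corrupt golden boundaries with
rounded N(0, 2)-minute offsets. Every participant has an independent RNG
stream keyed by the master seed and a stable hash of the participant id.

## Default problem sizes

* Stock cohort: 14/13/12 participants (train/validation/test) with
  near-balanced genders in train/validation and an imbalanced test split;
  one 12-hour recording day per participant, giving a windowed jogging
  ratio of a few percent (≈ 0.04 at seed 0).
* The test suite's end-to-end fixture and the acceptance script use a
  **desk-scale** variant — 4-hour days with exactly one bout — chosen so a
  full pipeline run (including the two 1000-tree ensembles and the 81-combo
  grid screen) completes in under two minutes on one CPU. Only the problem
  size differs from the stock configuration; no thresholds, tolerances or
  generator parameters change with scale.
* Wrapper budget: 2000 feature-set evaluations; grid screen: exactly 81
  combinations; balanced evaluation: 100 repetitions by default.
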