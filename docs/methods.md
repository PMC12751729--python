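# Methods

This note records the model implemented by `scdeeg`, its parameters, what
the synthetic generator does and does not capture, and the numerical
choices that affect results.

## Study design being modeled

Two groups of older adults with subjective cognitive decline, distinguished
by amyloid status: 24 amyloid-positive (A+) and 82 amyloid-negative (A−)
subjects. Each contributes a resting-state, eyes-closed EEG (19 channels,
10–20 montage with legacy temporal labels T3/T4/T5/T6, ≥ 180 s at 250 Hz by
default) plus demographics (age, sex, education, APOE4 carrier status) and
percentile-scaled cognitive scores. The analysis asks whether spectral and
network EEG features separate the groups after adjusting for age, whether
they track cognition, and whether a classifier can detect amyloid status.

## Synthetic EEG generator (`scdeeg.synthetic`)

Signals are assembled in the frequency domain (one rfft spectrum per
channel, single inverse FFT per channel):

- **1/f background**, amplitude ∝ f^(−1/2) in the amplitude spectrum
  (power slope −1), band-limited to 0.75–60 Hz, unit-RMS by Parseval and
  scaled to `background_rms` (default 5 µV).
- **Narrowband band sources** per channel for delta/theta/alpha/beta/gamma
  with default RMS {3.7, 3.0, 6.1, 3.6, 0.9} µV — an eyes-closed-like,
  alpha-dominant profile. Group effects are multiplicative on the A+ RMS:
  delta ×1.08, theta ×1.06, alpha ×0.93.
- **Lagged shared sources** per configured channel pair and band: a common
  narrowband source is mixed into both channels, the second receiving a
  circular delay (phase ramp exp(−2πi f mΔ/fs), default 12 ms). Mixing is
  RMS-preserving: sqrt(1−g²)·own + g·shared with coupling strength g.
  Alpha coupling: A+ 0.38 vs A− 0.52 over a posterior/long-range pair set;
  delta coupling: A+ 0.32 vs A− 0.22. The lag makes the coupling visible to
  the weighted phase-lag index (wPLI); zero-lag mixing would not be.
- **Between-subject variability**: lognormal amplitude jitter (sd 0.3 in
  log space) per band and subject; Gaussian jitter of coupling strength
  (sd 0.15, clipped to [0, 0.95]); white sensor noise (1 µV RMS).
- **Latent severity**: per subject, severity ~ N(1, 0.8²) for A+ and
  N(0, 0.8²) for A−. It adds gain·severity to the delta/theta log-
  amplitudes and subtracts from alpha (gain 0.15), and generates cognitive
  percentile scores as 65 − 12·severity + N(0, 9²), clipped to [0, 100].
  This gives the expected negative association between low-frequency power
  and cognition without hard-coding feature–score correlations.
- **Covariates**: ages N(73.42, 5.64²) for A+ vs N(69.82, 6.05²) for A−;
  APOE4 carrier probability 0.50 vs 0.11; education N(12, 4²) truncated at
  [6, 22]; sex balanced.
- **Artifacts**: Poisson transients (default 2/min) as Hann-windowed bumps
  of ±400 µV on random channel subsets, with a ground-truth `artifact_log`.

Randomness: every subject/purpose gets a child seed via
`np.random.SeedSequence([master, *keys])` reduced mod 2³¹, so cohorts are
bit-for-bit reproducible from one integer and derived seeds stay < 2³¹.

### Generator realism and limits

The generator reproduces: alpha-dominant eyes-closed spectra with a 1/f
background; group shifts in low-frequency power and alpha connectivity of
realistic effect size (ANCOVA partial η² ≈ 0.04–0.10); cognition–EEG
covariance through a shared latent; realistic covariate distributions; and
amplitude artifacts. It does **not** model: non-stationarity (alpha
blocking, drowsiness), volume conduction with realistic lead fields (mixing
is between named channel pairs only), muscle/ocular artifact morphology,
reference effects, or individual alpha-peak frequency differences. It is a
test harness for the pipeline's statistical behavior, not a biophysical
simulator.

## Preprocessing (`scdeeg.preprocess`)

4th-order Butterworth band-pass 1–55 Hz applied forward–backward
(`sosfiltfilt`, zero phase; the effective order is doubled).
Non-overlapping 2-s epochs; epochs whose peak-to-peak amplitude exceeds
150 µV on any channel are rejected; 60 clean epochs are selected uniformly
at random without replacement (seeded) and kept in temporal order. A
subject with fewer than 60 clean epochs raises `InsufficientEpochsError`
and is skipped by the pipeline (≥ 4 usable subjects per group required).
This amplitude-criterion cleaning is deliberately simpler than clinical
pipelines (ASR/ICA/visual review) — a scope decision, adequate for
synthetic data whose artifacts are amplitude transients.

## Spectral features (`scdeeg.spectral`)

Welch PSD with one Hamming-windowed modified periodogram per 2-s epoch (no
sub-segmentation or overlap), averaged over the 60 epochs; 0.5 Hz bins
resolve every band edge exactly. Verified bit-for-bit against
`scipy.signal.welch` with the same window. Relative band power =
100 · band power / total power over 1–55 Hz, with bands delta [1, 4),
theta [4, 8), alpha [8, 12), beta [12, 30), gamma [30, 55] (top edge
closed, so the five bands partition the analysis range and sum to exactly
100 per location). Locations: 19 channels plus "Global" (channel mean) →
100 spectral features.

## Connectivity (`scdeeg.connectivity`)

wPLI(f) = |E[Im S_xy(f)]| / E[|Im S_xy(f)|] with the expectation over the
60 epochs, 0/0 := 0; per-band value is the unweighted mean over the band's
bins. The estimator discards the real part of the cross-spectrum, making it
insensitive to instantaneous (zero-lag, volume-conduction-like) mixing.
Note: the finite-sample null with 60 epochs is ≈ 0.1–0.2, not 0.

## Network metrics (`scdeeg.network`)

Each band's wPLI matrix is proportionally thresholded at p ∈ {0.05, …,
0.35} (7 steps): keep the floor(p·171 + 0.5) largest off-diagonal weights
(round half away from zero; stable sort for ties; retained weights are NOT
binarized). Per thresholded graph: Onnela weighted clustering coefficient
(weights normalized by the matrix max, C_i = Σ(ŵ_ij ŵ_jh ŵ_hi)^(1/3 each)
/ k_i(k_i−1), zero for degree < 2), node strength (row sum), and global
efficiency (mean inverse Dijkstra path length with lengths 1/w,
disconnected pairs contributing 0). Metrics are averaged across the 7
thresholds; locations again 19 channels + Global → 5 bands × (20 CC +
20 NS + 1 E) = 205 network features. 100 + 205 + age = 306 classifier
features.

## Statistics (`scdeeg.stats`)

- Normality screen: |skewness| < 2 and |excess kurtosis| < 7.
- Two-group: pooled-variance t; Cohen's d with pooled SD, **positive when
  the A− mean exceeds the A+ mean** (A+ is passed first); 95% CI
  d ± 1.96·sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2))).
- Paired: t on pre − post; d = mean(diff)/sd(diff).
- Categorical: Pearson chi-square without continuity correction.
- Feature contrasts: ANCOVA y ~ intercept + group + age via full-vs-reduced
  least squares; partial η² = SS_group / (SS_group + SS_residual).
- Associations: age-adjusted partial Pearson correlation (residualize both
  variables on age); p from t = r·sqrt((n−3)/(1−r²)); percentile bootstrap
  95% CI over 5000 seeded subject-level resamples (vectorized closed-form
  single-covariate residualization).
- No multiplicity correction by default; Benjamini–Hochberg helper opt-in.

## Classification (`scdeeg.classify`, `scdeeg.boost`)

Discrete AdaBoost over depth-1 threshold stumps, 50 rounds, learning rate
1.0, no tuning. Implemented on numpy with a presort/cumsum stump search —
this keeps wrapper feature selection tractable and, because the ensemble is
additive over single-feature stumps, makes Shapley attributions exact:
φ_j(x) = Σ_{stumps on j} a_t (h_t(x) − mean_background h_t), with
base + Σφ = margin to machine precision.

Evaluation: stratified 10-fold CV; z-scoring fit on the training part of
each fold (a `global_scaling` option switches to global scaling for
comparability with studies that scale before CV, accepting the small
leak); Borderline-SMOTE (variant 1, k = 5) applied to training folds only,
raising the minority (A+) count to the majority count; metrics reported
per-fold (mean ± sd) and from pooled confusion counts. Feature selection is
greedy sequential forward selection (≤ 20 features) maximizing CV accuracy
(ties → MCC → column order), with two tractability options beyond plain
SFS: `prescreen` (restrict candidates to the top-N by |t|; default 50) and
`patience` (stop after N non-improving steps; default 3). Pass `None` for
both to recover the pure wrapper. Nested per-fold selection is available
(`cv_evaluate(..., nested_sfs=...)`) and is what the noise-floor check
uses; non-nested selection on the full table is optimistic and is flagged
as such. Significance: label-permutation p = (1 + #{perm ≥ obs}) / (B + 1)
on pooled metrics.

## Numerical choices that matter

- Round-half-away-from-zero (`floor(x + 0.5)`) for threshold edge counts —
  Python's banker's rounding would keep 4 instead of 5 edges at ties like
  0.3·15.
- Exact symmetrization (W + Wᵀ)/2 and zero diagonal of wPLI matrices
  before thresholding, so stable-sort tie-breaking is well defined.
- One-sided PSD doubling skips DC and Nyquist; window power normalization
  fs·Σw² (modified periodogram).
- Filter cutoffs are validated against Nyquist; filtering errors rather
  than silently aliasing.
- Z-scoring floors the SD at 1e-12 and warns on constant columns.
- All stochastic steps (epoch selection, SMOTE, CV shuffling, bootstrap,
  permutations, simulation) take explicit integer seeds; derived seeds are
  `SeedSequence([master, *keys]) % 2³¹`.
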