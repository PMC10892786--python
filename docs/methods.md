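# Methods

This note documents the models, parameter choices and numerical conventions
behind `somnoboost`, and what the synthetic-data experiments do and do not
demonstrate.

## Staging model

The unit of analysis is the 30-s epoch (3000 samples at 100 Hz). Stages use
the five-class AASM-style alphabet {W, N1, N2, SWS, REM}, encoded internally
as integers 0–4 in that order; R&K labels N3 and N4 are merged into SWS.
Epochs scored "?" or MOVEMENT are dropped together with their signal rather
than imputed. Leading and trailing wake runs are truncated to at most a
configurable `wake_buffer` (default 30 min = 60 epochs) around the first and
last non-wake epoch — long pre-sleep wake otherwise dominates the class
balance without adding staging information. If a recording and its hypnogram
disagree in length, both are truncated to the shorter with a warning rather
than rejected; length mismatches of one epoch are routine in practice.

## Preprocessing

Order of operations: band-pass → segment → normalise → sub-band decompose.

* **Band-pass** 0.5–49.5 Hz, hamming-window FIR. The tap count follows a
  transition-bandwidth rule, `numtaps ≈ 3.3·fs/max(low, 0.5 Hz)` rounded up
  to odd, so the lower skirt is as sharp as the lower edge requires
  (661 taps for 0.5 Hz at 100 Hz). Filters are applied zero-phase: the
  odd-length linear-phase kernel is convolved in "same" mode (exact
  group-delay compensation), with odd-reflection padding at the ends to
  suppress edge transients — epoch-aligned transients such as spindles and
  K-complexes are not displaced in time.
* **Segmentation** into non-overlapping 30-s windows; a trailing remainder
  shorter than one epoch is dropped.
* **Normalisation** is a per-recording z-score (pooled mean/sd over the
  recording's retained epochs). Per-recording rather than per-epoch, because
  its purpose is cross-subject amplitude equalisation; per-epoch scaling
  would erase the within-night amplitude contrast (e.g. high-amplitude SWS)
  that carries staging information.
* **Sub-bands**: δ 0.5–4, θ 4–8, α 9–11, σ 12–15, β1 14–20, β2 20–30,
  γ1 30–40, γ2 40–49.5, K-complex 0.5–1 Hz. α is narrowed to the adult
  posterior rhythm, β split at 20 Hz (wake vs REM fast activity), γ split at
  40 Hz. Both 13–20 and 14–20 Hz are in circulation as the lower β split;
  14–20 is used here, and the band table is configurable. The K-complex band
  deliberately overlaps δ.

## Features (52 per epoch)

Whole-epoch features use population (1/M) moment conventions; kurtosis is
non-excess (Gaussian ≈ 3). The zero-crossing rate counts strict sign changes
(consecutive-sample product < 0) over M−1 steps; exact zeros do not count.
Hjorth mobility/complexity use first differences in sample units. Per band,
three features: energy Σ|x|² of the filtered signal, spectral power
(trapezoidal integral of the Welch density over the band), and peak-to-peak
amplitude of the filtered signal.

Spectral estimation is Welch with 4-s hamming segments and 50 % overlap
(0.25 Hz resolution, 14 averaged segments per epoch) in density scaling;
the single "total power" feature integrates 0.5–49.5 Hz. Band powers come
from the PSD integral rather than filtered-signal variance — the two agree
within filter leakage, and the PSD route is cheaper and deterministic.

Parameters the literature leaves open are set to conventional defaults, all
overridable: histogram entropy 10 equal-width bins over [min, max];
permutation entropy order 3, delay 1 (ties broken by temporal order);
SVD entropy 10×1 delay embedding; sample entropy m = 2, r = 0.2·sd
(Chebyshev distance, self-matches excluded; if no templates match, the
Richman–Moorman bound −ln(2/((n−m−1)(n−m))) is returned with a warning so
matrices stay finite); Lempel–Ziv binarises at the median (x ≥ med → 1) and
counts LZ76 exhaustive-history words; max–min distance uses 1-s
(100-sample) windows and sums √(Δx²+Δy²) over them; Higuchi k_max = 10;
DFA uses linear detrending over 12 log-spaced window sizes in [4, n/4];
Hurst is the rescaled-range slope over log-spaced chunk sizes in [10, n/2].
All entropies are in nats. The Petrosian dimension uses the standard form
log M / (log M + log(M/(M+0.4K))) with K = sign changes of the first
difference, which correctly gives 1 for monotone signals.

The O(n²) sample-entropy template count and the LZ76 parse are
numba-compiled; the test suite checks both against plain brute-force Python
oracles, exactly for the combinatorial quantities and to 1e-8 relative for
floating ones.

## Feature shifting

Each non-age column gains lag-1 and lead-1 copies: 3 × 51 + 1 = 154 columns.
Shifting is grouped by recording; terminal epochs replicate the recording's
own boundary row rather than zero-filling or borrowing from the adjacent
subject — replication avoids artificial discontinuities and cross-subject
leakage. Because sleep stages persist across epochs, the neighbours' feature
values are informative context for the current epoch.

## Classifier and evaluation

XGBoost with a 5-class softmax objective and multiclass logloss as the
tracked metric does the tree construction; `tree_method="hist"`, one thread,
seeded. Stock hyperparameters for the untuned experiment: learning rate 0.1,
depth 3, 100 estimators, no regularisation beyond λ = 1 — the library
defaults — with the booster selectable between `gbtree` and `dart` (dart
extras at their defaults).

Evaluation is stratified 10-fold CV over pooled epochs of all subjects
(subject-independent pooling; a per-subject split would measure a different,
harder generalisation problem and is available separately). Per fold:
oversample the training rows with replacement up to the majority-class count
(seeded; duplication, not synthesis — synthetic interpolation is a stronger
assumption than the data warrant), train, predict the untouched test fold.
Reported per fold: accuracy, weighted-by-support F1/precision/recall
(weighted averaging chosen because imbalanced data then give
accuracy ≈ F1 ≈ precision ≈ recall, the behaviour the protocol expects),
Cohen's κ, a 5×5 confusion matrix in W,N1,N2,SWS,REM order, one-vs-rest ROC
AUC per stage from softprob outputs, and optional per-round logloss/error
curves. The CV mean is the arithmetic mean of fold values, reported at full
precision and rounded to 3 decimals. One experiment seed fans out (via
`SeedSequence`) into separate fold, balancing, training and PSO streams.

## PSO hyperparameter search

Particles live in a continuous box; integer dimensions are rounded and
categorical dimensions mapped by index on a [0, n) axis only at evaluation
time. Velocities start at zero, personal bests at the initial positions;
updates use fresh r1, r2 ~ U(0,1) per particle and dimension; positions are
clamped to the box and velocities to half the dimension range (prevents
divergence). Meta-parameters default to the constriction-equivalent
ω = 0.7298, c1 = c2 = 1.49618, swarm 20, 30 iterations; the stopping
criterion is the iteration budget. Fitness is mean inner stratified 3-fold
CV accuracy of the decoded configuration. A failed fitness evaluation scores
−∞ and the run continues. The default search space spans both boosters,
learning rate 0.01–0.5, depth 3–12, 100–800 estimators, child weight 1–10,
γ 0–5, subsample/colsample 0.5–1, α 0–2, λ 0.5–4, and the dart extras; a
documented `compact_xgb_space()` (gbtree only, ≤ 300 estimators, depth ≤ 8)
is what the examples, tests and acceptance script use, together with small
swarms (5–8 particles, 3–5 iterations), so desk-scale runs finish in
minutes on one CPU.

## Synthetic generator

Hypnograms are Markov chains over the five stages with a sticky default
transition matrix (diagonal 0.80–0.90, physiologically ordered off-diagonal
structure: W→N1, N1→N2, N2→SWS, REM cycling), started in wake. Signals are,
per epoch, a sum of random-phase sinusoids at band-centre frequencies
(±6 % jitter) with stage-specific amplitudes — W {α 20, β1 10 µV},
N1 {θ 15}, N2 {θ 8 + two 1-s 13.5 Hz spindle bursts of 15 µV + one 0.7 Hz
biphasic 40 µV K-complex pulse}, SWS {δ 40}, REM {θ 10, β2 8} — on a
1/f (exponent 1) background of 5 µV RMS. The `hard` preset scales the
stage-specific amplitudes by 0.4 and doubles the background. Subject age is
drawn uniformly from 20–60 years; phase is not continuous across epochs.

What passing on this generator shows: the pipeline's plumbing is correct
end to end, the features recover the spectral structure that defines the
stages, shifting exploits stage persistence, and tuning does not hurt. What
it does not show: performance on real EEG. Real recordings have artifacts,
non-stationary amplitude drift, ambiguous transitional epochs, scorer
disagreement, and far weaker class separability — accuracy figures from the
synthetic presets (≈ 0.99 on `easy`) are a plumbing check, not a clinical
claim.

## Problem sizes

The acceptance-style tests run the full study at 5 subjects × 400 epochs
(2000 epochs, ≈ 45 s feature extraction); the acceptance script uses
4 × 300 epochs per preset and a 5-particle × 3-iteration swarm over the
compact space. These sizes were chosen so a complete run takes minutes on a
single CPU while leaving every stage of the method exercised at full
fidelity (no feature, fold or balancing step is simplified at small n).

## Known limitations

* EDF writing supports exactly one 16-bit signal plus an EDF+ annotation
  file — enough for fixtures and single-channel work, not a general EDF
  writer. Metadata (age/sex/id) travels in a JSON sidecar.
* Non-100 Hz inputs are accepted (all windows scale with the rate) but the
  canonical feature set was designed around 100 Hz; resampling is out of
  scope.
* No artifact rejection (ICA, EOG regression) and no feature selection;
  the full 154-column matrix goes to the classifier.
* The histogram (Shannon) entropy is deliberately amplitude-sensitive;
  permutation/spectral/SVD entropies, LZC and the fractal dimensions are
  scale-invariant, and the tests pin down which is which.
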