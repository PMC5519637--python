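# Methods

## Problem and data model

The package classifies single ECG beats into six morphology classes —
atrial premature (A), left bundle branch block (L), normal (N), paced
(P), right bundle branch block (R) and premature ventricular (V) — from
one lead (by default the lead named MLII, falling back to channel 0 with
a warning when it is absent).  R-peak locations and beat type symbols
are taken from existing annotations; the package performs no R-peak
detection.  Annotation symbols outside the six-class map are dropped
before segmentation.  The paced symbol is `'/'` on disk and is written
`P` as a class label; the map is user-overridable because annotation
dialects vary.

Because the standard Python WFDB reader is not a dependency of this
package, `wavebeat.io` implements the subset of the WFDB conventions the
pipeline needs natively: `.hea` header parsing, signal formats 16
(little-endian int16) and 212 (packed 12-bit pairs), and the MIT binary
annotation stream, plus a plain-text annotation table for human-readable
fixtures.  Digital values are converted to millivolts with the header's
gain/baseline; writing uses format 16 at gain 200, so a write/read round
trip is exact to 1/400 mV.

## Segmentation

Windows span `t1` = 0.25 s before and `t2` = 0.45 s after the R-peak —
long enough to cover P, QRS and T at typical resting rates (60–80 bpm).
Offsets convert to samples by half-to-even rounding of `t·fs`, giving
90 + 162 = 252 samples at 360 Hz.  Windows are half-open
`[r − pre, r + post)` with all indices 0-based.  Beats whose window
would cross a record boundary are dropped and counted, not padded:
padding would inject artificial discontinuities into the wavelet
coefficients.

## Wavelet features

Each window is decomposed level by level with `pywt.dwt` (default
wavelet `bior6.8`, symmetric half-point extension), to 8 levels.  Detail
level *j* nominally covers [fs/2^(j+1), fs/2^j]; the level-8
approximation (0–0.70 Hz at 360 Hz) carries baseline drift and is
excluded.  The raw feature vector concatenates cD1…cD8 in that order.

Under the symmetric extension each stage maps *m* samples to
`floor((m + filter_len − 1)/2)` coefficients; for 252 samples and the
18-tap `bior6.8` filters this yields per-level lengths
134, 75, 46, 31, 24, 20, 18, 17 — 365 raw features.  Other extension
modes realize other lengths, so no stage of the pipeline hard-codes the
raw dimension; it is read from the data and logged.  A decomposition
depth is accepted only while every stage still sees at least
`filter_len` samples; beyond that a depth error reports the maximum
feasible level.  Reconstruction inverts the per-level walk and trims
each inverse step to the recorded input length, recovering the segment
to ~1e−12.

Note that 8 levels on a 252-sample window is far beyond
`log2(252/17) ≈ 3.9`, the depth at which boundary extension stops
dominating the coefficients; the deep levels are retained deliberately
because their few coefficients summarize the sub-3 Hz morphology, and
the classifier treats them as features, not as a faithful spectral
estimate.

## PCA

The component basis is fitted with scikit-learn's full-SVD PCA on the
training rows only.  Features are centered but not variance-scaled:
wavelet coefficients of one lead share physical units, and per-feature
rescaling would inflate the near-empty deep-level coefficients.  The
component count is either fixed (default 12) or chosen as the smallest
*k* whose cumulative explained-variance ("contributory ratio") reaches a
threshold.  In cross-validation the basis is refitted per fold; a pooled
fit would leak test-set statistics into training.  A sweep utility
evaluates any list of component counts (default: evens 2–50).

## One-vs-one SVM

One binary soft-margin classifier per unordered class pair (15 for six
classes), each trained only on that pair's samples with an RBF kernel
K(x, y) = exp(−γ‖x−y‖²), C = 10, γ = 0.1.  The binary solver is
scikit-learn's SVC used as a black-box maximum-margin contract; the
voting layer is implemented in `wavebeat.ovo_svm`: every hyperplane
casts exactly one vote, totals are n(n−1)/2, and the argmax wins.

Tie-breaking (deterministic, in order): exactly two tied classes → the
winner of their direct pairwise hyperplane; three or more → the tied
class with the largest sum of signed decision margins over its own
hyperplanes; exact margin ties → the earliest class in the model's
sorted class order.

Reduced features are standardized per dimension with training-fold
statistics by default — a fixed γ is only meaningful on a normalized
scale — and the flag can be disabled to feed raw projections.

## Metrics

Per class H, TP is the confusion-matrix diagonal cell, FN the rest of
H's row, FP the rest of H's column, TN everything else.  SEN, SPE and
ACC are computed per class and micro-averaged by pooling the counts over
classes before dividing.  A zero denominator yields NaN (an explicit
"undefined" marker), which happens when a rare class misses a test
fold; across-fold means and SDs skip undefined values and report how
many folds were skipped.  Reports format percentages at two decimals;
internal values keep full precision.

## Cross-validation

*Beat-based*: each class's beats are shuffled with the seed and dealt
round-robin to k test folds, so per-fold class counts are within one of
proportional.  *Record-based*: records are shuffled and dealt to k
disjoint test groups, and no record appears on both sides of a fold; an
explicit fold→test-record assignment can be supplied instead (the
bundled `mitdb_record_folds.json` carries the standard 48-record
division, in which rare-class records serve as test data in more than
one fold).  When a class is entirely absent from some fold's training
records a warning names the fold and class.

Per fold, strictly training-side fitting: wavelet features are
deterministic per beat and shared, but the PCA basis, the feature
scaler and all pairwise SVMs see training beats only.  This is asserted
by a test that perturbs test-fold features and checks the fitted fold
state is bit-identical.  Fixed (data, config, seed) reproduce the CV
result exactly.  Seeds are mandatory in the library API; the CLI
defaults to 20170720 purely as a reproducibility anchor.

## Synthetic generator

Each beat is a sum of Gaussian bumps (one per named wave), on a
millivolt scale, with base morphology P(0.15 mV, −0.16 s, σ 0.022 s),
Q(−0.10, −0.026, 0.009), R(1.20, 0, 0.012), S(−0.25, 0.030, 0.011),
T(0.35, 0.22, 0.055).  Class templates: V widens the R complex ×3,
drops P and Q and inverts T; L and R widen the complex and add a
secondary lobe 45 ms after (L) or before (R) the R-peak; A reduces and
delays the P wave and shortens the preceding RR interval ×0.7; paced
beats place a narrow 4 ms spike at the annotation point followed by a
wide slurred complex, with no P wave.  The secondary L/R lobes are kept
below the main R bump so the annotated sample remains the local maximum
of every class's beat — the generator's own ground-truth invariant.

Each record is one synthetic subject: every wave's amplitude, centre and
width is perturbed multiplicatively by (1 + τ·z), z ~ N(0,1), once per
record, with τ = `between_subject_sd` (default 0.2).  Beats within a
record share the subject's morphology.  Beat spacing is N(0.8 s,
0.05 s) — 75 bpm, the middle of the typical resting range — clipped at
0.4 s; R-peaks are snapped to the sample grid before rendering.  White
noise (default 0.03 mV) and a sinusoidal baseline wander (0.05 mV at
0.3 Hz, random phase) are added.  Class labels are i.i.d. from the
configured proportions, default 70 % N with the remainder split evenly —
the heavy imbalance this problem is known for.  All randomness derives
from one seed; record *i* uses substream (seed, *i*).

What the generator does *not* emulate: rhythm-level phenomena
(bigeminy, runs, compensatory pauses beyond the A-beat gap), waveform
asymmetry (real T waves are skewed), electrode artefacts, muscle noise,
or within-record morphology drift.  Synthetic results therefore show
that the pipeline's machinery is correct and that subject-grouped
evaluation is strictly harder under subject-level variation; they do not
certify clinical performance on real recordings.

## Study conditions for the control experiment

The shipped control experiment uses 20 records × 150 beats, τ = 0.3,
noise 0.05 mV, 10-fold CV, k = 12 components — small enough to run in
seconds on one core while still exhibiting the qualitative contrast of
interest: near-ceiling accuracy under beat-based folding and a several-
point accuracy drop (driven mostly by A/N confusion, the two most
similar templates) under record-based folding.  The acceptance script
reports micro SEN/SPE/ACC for both schemes and the accuracy gap at these
sizes.

## Numerical choices and degenerate inputs

- Offset rounding is half-to-even (`round`), making window lengths
  reproducible across platforms.
- Wavelet feasibility requires every stage input ≥ filter length; the
  error message states the deepest feasible level.
- PCA refuses non-finite inputs and fewer than two rows; projection and
  prediction validate dimensions explicitly.
- Standard-deviation scaling guards σ = 0 dimensions by substituting 1.
- Vote resolution never falls through: the final fallback is the
  earliest class in sorted order.
- Undefined rates propagate as NaN and are excluded (and counted) in
  aggregation, never silently zeroed.

## Known limitations

- The WFDB subset reads single-segment records with formats 16/212
  only; multi-frequency and multi-segment layouts are out of scope.
- The raw feature dimension depends on the boundary-extension
  convention; results are comparable only within one convention.
- Record-based fold generation balances record counts, not beat counts,
  so test-fold sizes vary when records differ in length.
- The one-vs-one model stores n(n−1)/2 kernels; training cost grows
  quadratically in the class count (benign at n = 6).
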