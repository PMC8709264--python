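# Methods

## Problem and model

The package classifies individual heartbeats from a single ECG lead into the
five AAMI EC57 super-classes — N (normal, including bundle-branch-block
beats), S (supraventricular ectopic), V (ventricular ectopic), F (fusion of
ventricular and normal), Q (unclassifiable or paced) — and compares two
schemes built from the same learner:

1. **Baseline**: one 5-class random forest.
2. **Two-phase composite**: a binary forest over {N, A} (A = any abnormal
   beat) cascaded with a 4-class forest over {S, V, F, Q} that is invoked
   only on beats the first stage flags abnormal. By construction the
   composite outputs N exactly when the binary stage does, so collapsing its
   predictions back to {N, A} reproduces the binary stage's confusion matrix
   identically — a property the test suite asserts rather than assumes.

The cascade mirrors how cardiologists read strips (establish the normal
morphology first, then subtype the deviations) and lets each stage optimize a
simpler decision problem.

## Preprocessing

All signals are brought to a **360 Hz working rate** by Fourier (sinc)
resampling (`scipy.signal.resample`); annotation indices are mapped through
`round(index * target/source)` (half away from zero). Baseline wander is
removed by the standard two-median-filter construction: a 200 ms median
filter followed by a 600 ms median filter estimates the baseline, which is
subtracted from the raw signal. Widths convert to odd sample counts
(200 ms → 73, 600 ms → 217 at 360 Hz; even counts are bumped by one so the
median is symmetric) and edges use reflect padding, which avoids spikes in
the baseline estimate near the record boundaries. Amplitudes are then
min-max scaled **per record** onto [0, 1]; a constant record maps to all
zeros. Per-record (rather than per-beat) scaling is the assumed convention;
it preserves relative beat-to-beat amplitude, which is itself a class cue.

Each annotated beat becomes a 600 ms window of **exactly 216 samples — 108
before and 108 after the R-peak** (0.6 s × 360 Hz = 216 with no rounding).
Beats within 108 samples of either edge are dropped with a logged count.

For unannotated signals (e.g. 128 Hz patch recordings) a Pan-Tompkins-style
detector supplies R-peaks: differentiate, square, integrate over a 150 ms
moving window, threshold at `max(0.03 * peak, 2.5 * median)` of the feature
signal, enforce a 200 ms refractory period, and snap each detection to the
local signal maximum within ±50 ms. The low fractional-peak term matters
because wide ventricular complexes carry an order of magnitude less
derivative energy than narrow normal QRS spikes; with a larger factor the
detector systematically misses V and F beats. The detector is validated
against the generator's planted peak locations (±25 ms) rather than against
clinical data.

## Datasets

The 15-symbol MIT-BIH annotation alphabet maps totally onto the five classes
(N,L,R → N; A,a,J,S,e,j → S; V,E → V; F → F; /,f,Q → Q). The interpatient
split is the fixed 22-record training / 22-record test partition with the
four pacemaker-dominated records (102, 104, 107, 217) excluded; supplementary
record pools are split by alternating assignment over the sorted id list
(first id → train). Training and test record sets are verified disjoint for
every assembled dataset pair. The two-phase views are derived from the
5-class dataset by relabeling (N stays N, everything else becomes A; size
preserved) and by filtering (abnormal beats only, subtype labels kept), so
beat counts are conserved exactly.

## Classifier

The feature vector is the raw 216-sample normalized window — no engineered
features, since the windows are already amplitude- and position-normalized.
Forests are bagged ensembles of **220** fully grown trees with sqrt(216) ≈ 14
features considered per split (`sklearn.ensemble.RandomForestClassifier`).
Training draws **10 independently seeded candidate ensembles** and keeps the
one with the best out-of-bag accuracy (ties keep the earliest candidate);
`candidate_count=1` disables the selection. Vote ties at prediction time
break by the fixed label order N < S < V < F < Q (< A), making every
prediction path deterministic given (data, seed). No class weighting or
resampling is applied; imbalance is addressed only through dataset
composition. Model training refuses any dataset tagged as the test split.

## Metrics

Per-class metrics come from the one-vs-rest reduction of the K×K confusion
matrix (rows = truth): TP is the diagonal entry, FN the rest of the row, FP
the rest of the column, TN the remainder. Accuracy = (TP+TN)/total,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), each ×100 and rounded to
3 decimals (half away from zero). "Per-class accuracy" is deliberately the
one-vs-rest accuracy, which can exceed the class's sensitivity — the only
reading consistent with published interpatient tables. Overall metrics are
**macro (unweighted) means** across classes. A 0/0 ratio (class absent or
never predicted) reports 0 with a logged warning. Normalized confusion
matrices divide each row by its row sum and round to 3 decimals; an all-zero
row stays zero.

## Synthetic cohort generator

Each record is a sum of per-beat templates (Gaussian bumps for P/QRS/T),
two slow sinusoids of baseline wander (0.12–0.35 Hz), and white noise.
Class morphology: N has the full P-QRS-T complex (R amplitude 1.0, width
σ = 12 ms); S is premature (preceding RR shortened to 0.65×) with a nearly
absent P wave; V has a wide (σ = 35 ms), taller QRS, no P, and an inverted T;
F is the arithmetic midpoint of the N and V templates — by design the hardest
class, matching its clinical definition as a fusion beat; Q is a band-limited
noise burst with a narrow apex spike. Annotation symbols are drawn uniformly
from each class's full symbol group so label mapping is exercised end to end.
RR intervals are Gaussian (default mean 0.8 s, 5% SD, floor 0.35 s).

Defaults (8 records × 60 s, 360 Hz, class mix 0.70/0.10/0.10/0.05/0.05,
baseline wander amplitude 0.2, noise SD 0.02) describe a low-noise,
large-margin regime: a plausible heart rate, class proportions imbalanced in
the direction of real beat data but with enough minority beats to train on,
and noise an order of magnitude below the R amplitude. Per-record streams
derive from `SeedSequence([master_seed, record_index])`, so a cohort can grow
without perturbing existing records.

What the generator does **not** emulate: real rhythm context (bigeminy, AF
episodes), electrode-motion artefacts, inter-patient morphology variability
beyond the random streams, and the annotation noise of human labellers.
Passing tests therefore demonstrate that the pipeline machinery is correct
and that the cascade behaves as specified — not that the reported synthetic
accuracies transfer to clinical recordings. On the default cohort both
models are near-perfect; the noise sweep (SD 0.02 → 0.3 → 1.0) shows the
expected monotone degradation and is where the two schemes separate.

## Problem sizes and numerical choices

The end-to-end experiment used by the acceptance script runs 14 records ×
120 s (~2200 beats, ~1100 per split) with the full 220-tree / 10-candidate
configuration; the noise sweep uses 6 records × 60 s with 80 trees and a
single candidate, sizes at which the comparison is stable and the whole run
completes in well under a minute. Rounding is half-away-from-zero
throughout. Degenerate inputs are defined, not errors, wherever a convention
exists (constant record → zeros; empty beat list → empty predictions;
all-zero confusion row → zero row), and are errors where silence would hide a
bug (record shorter than the 600 ms kernel, non-216-sample windows, training
on a single class or on the test split).

## Known limitations

* WFDB support covers header + signal formats 212/16 + MIT annotations —
  enough for MIT-BIH-style records; other formats raise a clear error.
* The full published MIT-BIH tables require the database itself (an external
  download) and their exact evaluation subsets are ambiguous; this package
  evaluates all models on one consistent interpatient test set.
* The candidate-selection reading of the training procedure ("best of 10 by
  out-of-bag accuracy") is one interpretation of an under-specified ensemble
  initialization; it is switchable via `candidate_count`.
* Per-record normalization is an assumption; per-beat normalization is a
  plausible alternative the package does not currently implement.
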