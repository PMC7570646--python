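# Methods

## The system model

`adaptfuse` models an assisted-living monitoring setup in which four sensors
of different physical principle observe the same person: surface EMG of the
lower limbs (**B**, 200 Hz), pressure-sensing shoe insoles (**C**, 100 Hz), a
chest-worn triaxial accelerometer (**D**, 100 Hz) and a video camera (**E**,
25 Hz).  The subject performs twelve elementary reversible activities of
daily living, coded `1a/1b` … `6a/6b` (squat/rise, sit/stand, reach
forward/return, reach up/return, bend/straighten, right/left step).

Every sensor (or sensor combination) has an empirical *reliability*
`R_s(A)` — the percentage of repetitions of activity `A` it recognizes
correctly — tabulated per activity and per volunteer.  Two such tables ship
with the package (resources `"table3"`, per activity, and `"table4"`, per
volunteer, each with a matching dispersion table).  The aggregate `ALL`
column is stored as published and never recomputed, because the underlying
per-volunteer repetition counts (19–46 per activity) are not recoverable.

Fusion is performed at the decision level.  Each sensor emits, once per
decision tick, a probability-ordered list of activities `{(A_i, p_i)}`.  The
fused score of activity `A` is

    f(A) = Σ_k  W_k · p_{A,k},

and the decision is the argmax (exact ties broken by canonical activity code
and flagged).  The weights derive from three factors per sensor `k`:

* cost `H_k > 0`, activity-independent and constant in time (hardware,
  installation, maintenance, user acceptance); default 1 for all sensors —
  extreme values defeat the adaptation and are advised against;
* reliability `R_k(A)`, read from the single-sensor rows of the reliability
  table on the printed percent scale (the scale cancels in normalization);
* penalty `L(n) = n^(−p)` with rank `n` from a competition ranking
  ("1, 2, 2, 4") of the active sensors by `R_k(A)`; the exponent `p` is
  confined to (0.1, 10).  Small `p` flattens the ranking (genuinely
  multimodal blending); large `p` approaches a winner-take-all switch to the
  single most reliable sensor.  Default `p = 1`.

Contribution and weight: `C_k = H_k · R_k(A) · L(n_k)`, `W_k = C_k / Σ C`.

Multi-sensor rows of the table are used for *sensor-set selection*, not for
the weight formula: for a given activity the candidate sets are ranked into
a hierarchy of tie groups (exact equality of the printed one-decimal
percentages at the default `tie_tol = 0`), and a consistency rule picks the
new working set from the top group — keeping the previous set when it is a
member, otherwise the member sharing the most sensors with it, remaining
ties resolved by canonical order (fewest sensors, then alphabetically).

## Stability-constrained adaptation

Re-weighting after a recognition closes a feedback loop: the new weights
could overturn the decision they were computed from.  The modulator
therefore moves the weight vector from its current value `W₁` toward the
target `W₂ = m(A)` only as far as the fused decision is unchanged.  The path
is the straight segment `(1−t)·W₁ + t·W₂`, which stays normalized for free;
the admissible limit is found by bisection on `t ∈ [0, 1]` (tolerance
`tol = 1e−3` on `t`, iteration cap 32).  Because every activity's fused
score is linear in `t`, the region where the incumbent activity wins is an
interval containing `t = 0`, so the flip point is unique and bisection is
exact up to `tol`; the test suite checks it against a dense grid search.

Two adaptation policies close the loop:

* **conservative** — the target weights confirm the currently detected
  activity (the system expects a stable status);
* **predictive** — the target weights prepare for the most probable *next*
  activity, looked up in a habits database: first-order transition counts
  over the twelve codes, learned from past activity sequences, persisted as
  counts, row-normalized on demand.  Prediction is a single step (argmax of
  the current row; overall most frequent source on an empty row; the current
  activity itself on an empty database, which makes the predictive step
  collapse to the conservative one).  Habit updates during simulation happen
  on detected-activity changes.

Sensor availability is part of the state: an unavailable sensor's weight is
exactly 0, the remainder renormalizes immediately, and the candidate pool
for set selection shrinks to the available sensors.  Availability changes
declared with a scenario segment take effect on the following decision tick.
All streams are assumed resampled to a common decision tick (nominally
1 Hz); the native sensor rates matter only to the upstream feature
extraction, which this package replaces with synthetic generators.

## Classification pipeline

Per-repetition feature vectors have fixed lengths (B 320, C 240, D 120,
E 320); multi-sensor vectors concatenate members in canonical order B, C, D,
E, so lengths are additive (BC 560, BCE 880, BCDE 1000).  Classification is
plain k-NN with the Manhattan (L1) metric, train:test = 1:3 stratified by
activity, `k = 3` by default (exposed as configuration; no value is canon).
The class vote fractions among the k nearest neighbours double as the
probability list passed to fusion.  Tie handling is fully specified for
reproducibility: equal distances resolve by dataset order (stable sort);
labels with equal vote counts are ordered by their nearest neighbour's
distance, so a three-way tie at `k = 3` falls back to the 1-NN decision.
The latter choice matters: breaking vote ties by a fixed label order instead
injects a systematic bias toward early activity codes (measured correlation
≈ −0.9 between class recognition rate and code position, ~7 points of
spread), which would corrupt any calibration of the synthetic pipeline.
No feature scaling is applied before the distance; the generators emit
features on a common scale, standing in for the normalization that real
feature extraction performs upstream.

## Synthetic data: what it emulates, what it does not

No recording of the original experiment is publicly available, so all
dynamic inputs are synthetic with explicitly configured statistics:

* **Sequences** replay scripted scenarios (e.g. the "searching on the
  shelf" compound action: 4a, 4b, 3a, 3b, 5a, 5b, 1a, 1b) or sample a
  habits chain.
* **Streams** emulate per-sensor classifiers whose top-1 correctness per
  activity matches a confusion model — by default the single-sensor rows of
  the packaged table divided by 100.  Errors spread uniformly over the 11
  wrong activities (maximum entropy; the true per-set confusion matrices are
  not available, and the spread is pluggable).  The emitted list puts 0.8
  (`sharpness`) on the drawn top activity and the remainder uniformly
  elsewhere, so fusion always has non-degenerate second choices.
* **Feature vectors** place each activity's prototype on its own coordinate
  block as a seeded random ±1 sign pattern, zero elsewhere, plus iid
  Gaussian noise.  All prototype pairs are then exactly equidistant in L1,
  so class difficulty is uniform by construction and the test-set
  recognition rate is a monotone function of the noise scale.
  `calibrate_noise` inverts that function by bisection (deterministic under
  a fixed seed) to hit a configured recognition rate.

Consequences for interpretation: passing tests show that the fusion,
adaptation and evaluation machinery behaves correctly under controlled
statistics.  They do not show that real EMG/pressure/accelerometer/video
features are separable at any particular rate, that real errors are
uniformly confused, or that real class difficulties are equal — the
published tables are *inputs* here, not reproduced measurements.

## Evaluation statistics

`evaluate_recognition` pools `(subject, truth, predicted)` triples:
per-activity correctness `R_s_a` (pooled over subjects), per-subject
correctness `R_s_V` (pooled over activities), overall `R_s_ALL`, each with a
dispersion `U` defined as the *weighted population standard deviation* of
the grouped correctness values, weights proportional to repetition counts.
The population form is used because groups can be tiny (a sample-variance
correction is unstable at n = 1); `U = 0` whenever all grouped values agree.
`U_s_ALL` is the dispersion of per-subject overall correctness.

## Numerical choices and degenerate inputs

* Probability lists must be non-increasing and sum to 1 within 1e−9;
  weight vectors are validated to sum to 1 within 1e−6 before bisection.
* All-zero contribution vectors, empty pools/datasets/prediction lists, and
  a fully unavailable sensor park raise explicit errors
  (`ValidationError` / `ConfigurationError`); the CLI maps input errors to
  exit code 2 and configuration errors to 3.
* Hierarchy grouping anchors the tie tolerance at the group leader
  (greedy); with `tie_tol = 0` this reduces to exact equality of printed
  values.
* A training stratum too small to split lands wholly in the training set
  with a warning.
* Every stochastic component takes a `numpy` seed; simulations and
  generators are bit-reproducible given one.

## Problem sizes used in the checks

The randomized verifications run at: 500 random fusion instances for the
stability invariant and its 1000-point grid-search cross-check; 1000 random
contribution vectors for normalization; 1000 items per activity cell
(250 train / 750 test per class), averaged over 4 independent cohorts, for
the recovery of a configured 93% recognition rate within ±3 points.  These
sizes keep the full verification under a few minutes on one CPU while
leaving the statistical checks comfortably powered.

## Known limitations

* The habits model is first-order; multi-step prediction trees are out of
  scope.
* The published per-volunteer/per-activity repetition counts are unknown,
  so the `ALL` columns of the packaged tables cannot be independently
  re-derived.
* Predictive adaptation is only as good as the habits database; an
  unexpected activity costs at most one tick of suboptimal weighting, upper
  bounded by the second-best sensor's error for that activity (worst case
  in the packaged table: 5.9% for the pressure+video pair on activity 4b).
* Feature-level fusion, raw-signal processing, alarm generation and any
  real-sensor drivers are intentionally absent.
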