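# Methods

## The problem

Activity classifiers for wearable inertial sensors face a tension between
*generalisation* (serving users absent from the training sample) and
*personalisation* (serving the known users as well as possible). This
package implements the five approaches that span that trade-off — PIM,
PSM, and three ensemble-of-PSM variants — together with the preprocessing,
features, and evaluation protocols needed to compare them on any
long-format labelled 6-axis recording set, and a synthetic generator that
makes the comparison runnable end-to-end in seconds.

## Pipeline

**Timestamp repair.** Some corpora carry a constant timestamp per trial
(a spreadsheet-export artefact). When more than 50 % of inter-arrival
times are non-positive, timestamps are regenerated as t₀ + i/fs from the
nominal rate. The 50 % majority rule is this package's detection
heuristic; a healthy recording never triggers it.

**Natural trials.** A recording is split whenever the activity label
changes or the inter-arrival time *strictly exceeds* 1.5 s. Trials are the
atomic cross-validation grouping unit: because adjacent 50 %-overlapping
windows share raw samples, splitting *windows* across train/test leaks;
splitting *trials* cannot.

**Batching.** Each natural trial is cut into non-overlapping 15 s batches,
guaranteeing at least two trials per user and activity for the
leave-trials-out protocol. A trailing remainder is kept iff it is at least
one window (3 s) long; a shorter batch would contribute zero instances.

**Gravity/body separation.** A zero-phase (forward–backward) elliptic IIR
low-pass isolates the gravity component of each accelerometer axis;
defaults are order 3, 0.3 Hz cutoff, 0.01 dB passband ripple, 60 dB
stopband attenuation. These are conventional values for posture/motion
separation, recorded in the configuration so results are reproducible; all
four are tunable. The body component is defined as the residual
(accel − gravity), making the decomposition exact by construction — an
invariant the tests check to 1e−12 — rather than relying on a separately
designed high-pass.

**Windows and features.** 3 s windows, 50 % overlap, starting at 0 within
each trial; trailing partial windows are dropped, so the count is
⌊(L − w)/step⌋ + 1. Window starts are mapped to sample indices by rounding
k·step·fs, which keeps that closed form valid at rates where the step is a
fractional number of samples (e.g. 25 Hz). Features per window (56 total,
fixed canonical order):

| block | signals | features |
|---|---|---|
| moments (36) | gyro, body, gravity × 3 axes | mean, sd, Fisher skew, excess kurtosis |
| spectral (12) | gyro, body × 3 axes | normalised spectral power entropy, peak-power frequency |
| SMA (2) | gyro, body | mean over samples of \|x\|+\|y\|+\|z\| |
| correlations (6) | gyro, body | pairwise Pearson axis correlations |

Spectral estimates use the one-sided periodogram of the raw
(non-detrended) window with the DC bin excluded from both the entropy and
the argmax; entropy is normalised by log(#bins) so it lies in [0, 1].
Degenerate windows map skew, kurtosis, correlations, entropy and peak
frequency to 0 instead of NaN; a relative power floor (1e−18 of the
signal's mean square) keeps FFT round-off leakage from turning a constant
window into a "spectrum". Gravity acceleration contributes only moments:
it is a near-DC posture signal whose spectrum and axis couplings are
uninformative.

**Standardisation.** (x − x̄)/s with x̄ and s (population sd) estimated on
the training rows of each split only, and refit inside every fold;
constant features get s := 1 so they map to 0.

## Models

All classifiers sit behind a score contract: class inventory = sorted
distinct training labels, per-row scores non-negative and summing to 1.
The reference hyperparameters are logistic ridge regression C = 0.98, kNN
k = 2 with distance-weighted voting, RBF-SVM γ = 0.001 / C = 316, and
gradient boosted trees with learning rate 0.02 and 750 trees. The
estimators themselves are scikit-learn; the package contributes the
ensemble logic around them.

For an unknown user, an EPSM aligns each member's scores into the global
class inventory (activities missing from a member's training data get
exactly 0 — a user who never performed an activity is assumed never to
perform it), takes the weighted mean, and predicts the argmax, ties
resolving to the first class in sorted order for determinism. Weighting
schemes:

* **uniform** (EPSM): wᵤ = 1/n.
* **kappa** (WEPSM): wᵤ ∝ mean over other members v of κ(PSMᵤ on v's
  data), excluding the test user; negative means are clipped to 0 before
  normalising (an anti-correlated member should not vote), and an all-zero
  vector falls back to uniform. The pairwise κ matrix is computed on the
  members' full (fold-standardised) training data.
* **baseline** (WEPSMbf): wᵤ ∝ 1/(d̄ᵤ + 1e−8) where d̄ᵤ is the mean
  Euclidean distance between the member's and the test user's baseline
  feature vectors (one random standing window and one random sitting
  window each, drawn with a seeded RNG, standardised with the training
  fold's parameters). Users without baseline rows receive the mean raw
  weight of the others; inverse distance is used so posturally closer
  users vote more.

For a *known* user every ensemble variant simply dispatches to that user's
PSM, so subject-dependent ensemble results equal the PSM results exactly —
an identity the tests assert bitwise.

## Evaluation protocols

κ is the standard Cohen definition (p_o − p_e)/(1 − p_e) with
p_e = Σ_c p_true(c)·p_pred(c); the degenerate case p_e = 1 is defined as
κ = 0 so pathological single-class folds cannot abort a batch run.
Accuracy, error rate (= 1 − accuracy) and the support-weighted F-score are
reported alongside.

Leave-trials-out folds are built by shuffling (seeded) the trials within
each (user, activity) stratum and dealing them round-robin to k folds —
the stratification keeps every class represented on the training side.
k = n (number of users) for both the pooled subject-dependent PIM CV and
each user's own PSM CV. Subject-independent PIM and ensembles use
leave-one-user-out; subject-independent PSM trains on one user and tests
on the other n − 1, reported per test user as the mean over its n − 1
donor models (the per-pair table, from which a per-donor median view can
be derived, is exposed separately). Subject-dependent PIM per-user scores
are computed from each user's pooled out-of-fold predictions. Rank tables
use average ranks on ties; summary tables report mean ± SE across users
with the sample sd (n − 1), SE = 0 for single-user cells. A paired-t
helper is provided for user-paired approach contrasts; model-based
analyses (GLMMs, estimated marginal means) are deliberately left to
external statistical tools, which is why results are exported long-format.

## Synthetic data

Each user × activity gets a dominant frequency and amplitude drawn
log-normally around the activity's population value (log-sd 0.25·hetero_sd
for frequency, 0.40·hetero_sd for amplitudes) and a posture vector rotated
about a random axis by an angle ~ N(0, 0.5·hetero_sd rad). Signals are
gravity·posture + per-axis phased sinusoids (+ white noise, sd 0.3) for
the accelerometer, and independent phased sinusoids for the gyroscope;
g = 9.81 signal units. The six default activities comprise two static
postures (standing, sitting — differing only in gravity direction, which
gives WEPSMbf its baseline windows) and four periodic motions with base
frequencies at multiples of 1/3 Hz, i.e. exactly on the DFT bins of a 3 s
window, close enough together that between-user spread makes one user's
walking resemble another's stair climbing.

The default population is 8 users × 6 activities × 3 trials of 45 s at
50 Hz with a 2 s inter-trial gap: 9 batches and 81 windows per user and
activity, 3,888 windows in total — big enough for stable κ estimates,
small enough that a full five-approach comparison runs in well under a
minute per seed. Presets: `homogeneous` (hetero_sd = 0, users
exchangeable) and `heterogeneous` (hetero_sd = 1).

What the generator does *not* emulate: non-stationarity within a trial,
harmonics and gait asymmetry, label noise, sensor drift and calibration
error, class imbalance, or realistic inter-feature correlation structure.
Passing tests therefore demonstrate that the algorithms and protocols
behave as specified under controlled heterogeneity — not that any
particular κ level would be attained on a real corpus.

### What the synthetic benchmark shows — and a capacity caveat

Under heterogeneity, person-specific models dominate for known users
(subject-dependent PSM ≫ PIM), a single transferred PSM is the worst
choice for an unseen user, and ensembles of PSMs recover much of that gap
— these orderings are asserted over multiple seeds in the acceptance
tests. The relative position of PIM and the ensembles for unseen users,
however, depends on the pooled learner's capacity relative to the
population's modality: when each activity class is a union of well
separated user-specific clusters, a pooled linear model (and even a pooled
kNN) can be outperformed by the ensemble, which acts as a mixture of
per-user experts. On real corpora pooled models tend to win for unseen
users; reproducing that regime in this generator requires moderate
heterogeneity, and at the heterogeneous preset's spread the ensemble
advantage can reappear. The acceptance suite documents the orderings that
are stable under the preset conditions.

## Numerical choices and degenerate inputs

* Argmax ties → lexicographically first class (determinism).
* Empty recordings split into zero trials; trials shorter than one window
  yield zero windows; a stratum with a single trial is a protocol error
  naming the user and activity.
* The zero-phase filter needs ~3× the filter's effective impulse length;
  shorter trials raise a preprocessing error naming the trial.
* All randomness (population draws, fold shuffles, baseline-window
  selection) flows from explicit seeds; an experiment's single seed fans
  out deterministically to per-stage seeds.

## Known limitations

* The 56-feature inventory is the package's documented reading of the
  standard HAR feature families it implements; alternative inventories can
  be configured but no feature selection is provided.
* Subject-independent PSM evaluation trains n(n−1) models and the κ-weight
  matrix is O(n²) in members; fine for tens of users, not thousands.
* No resampling to a common rate: datasets are analysed at their native
  sampling frequency.
* Units are never converted; features are unit-bearing, which is why
  standardisation is mandatory before classification and baseline
  distances.
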