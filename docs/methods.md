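# Methods

## Overview

`semgpipe` studies how well six hand actions — hand open (HO), hand close
(HC), wrist extension (WE), wrist flexion (WF), wrist pronation (WP) and
wrist supination (WS) — can be classified from just two surface-EMG
electrodes on the forearm: a *medial* electrode over the flexor carpi
radialis and a *lateral* electrode over the extensor carpi radialis.  The
pipeline has five stages: synthetic session generation, envelope signal
processing, time-domain feature extraction, cross-validated classification,
and an exhaustive feature-combination sweep with plateau analysis.

## Acquisition protocol and the synthetic-session model

A session is one continuous two-channel recording sampled at 1111 Hz:
~8 s of initial rest, then ten cued 1 s holds of a single action separated
by 4 s of rest, closed by 2 s of trailing rest (an artifact choice: the
cued protocol leaves the post-hold rest unspecified, and 2 s guarantees
the final 2 s analysis window fits inside the recording).  Five sessions
per action give 50 repetitions of each action per participant — 300
segments in a full 6-action set.

The raw signal is emulated, not physiological: zero-mean Gaussian noise
band-pass shaped to 20–450 Hz (the usual surface-EMG carrier band),
multiplied by a time-varying amplitude.  At rest the amplitude is the
baseline RMS (12 µV by default); during each hold it rises to the
channel's action-specific gain following a unimodal burst profile — a
triangular peak sharpened as tri^1.5 with 100 ms cosine-smoothed feet.
A peaked (rather than flat-topped) profile was a deliberate choice: it
makes the instant of peak activity well defined, so peak-centred
segmentation has an unambiguous ground truth.  With a plateau-shaped
burst, stochastic amplitude modulation moves the envelope argmax
arbitrarily within the plateau and "the burst centre" stops being
meaningful.  No motor-unit action potentials, conduction velocity or
electrode geometry are modelled.

Stochastic structure on top of the deterministic profile:

* a slow (<2 Hz) multiplicative modulation at ±10% relative depth,
* a faster 2–5 Hz within-burst modulation whose depth grows as the
  channels decouple (up to ±30%),
* per-channel burst-onset jitter up to ±30 ms, again only for weakly
  coupled actions,
* an antisymmetric medial/lateral burst-centre lag up to 120 ms for
  uncoupled or antagonistic actions (the medial channel peaks early, the
  lateral late), and
* the combined modulation clipped to [0.75, 1.25] so the envelope argmax
  stays near the burst centre.

The two channels' modulations are mixed from shared and independent
components so that their correlation equals the signature's
`cross_corr` (negative values use an anticorrelated shared component).

### Action signatures

Per-action channel gains (µV RMS at burst peak, medial/lateral):
HO 130/152, HC 194/191, WE 102/256, WF 214/128, WP 152/137, WS 78/104;
baseline 12 µV.  These were calibrated once so that the 5 Hz envelope's
per-channel mean and peak voltages land near the activation levels
observed in real two-electrode recordings of these actions — in
particular the physiologically expected asymmetries: wrist extension
drives the lateral (extensor) channel far harder than the medial, wrist
flexion the reverse, and the grasp actions (HO, HC) activate both
channels at comparable levels (gains within ~20% across channels).
Coupling targets are +0.95 (HO), +0.05 (HC), +0.25 (WE), −0.45 (WF),
−0.05 (WP), −0.35 (WS).

A known limitation: because every hold is cue-locked and both channels
share the same burst timing, realized *segment-level* envelope
correlations are compressed upward — HO sits near +0.99 but nominally
uncoupled actions realize ≈ +0.8 rather than ≈ 0.  The generator
reproduces the *ordering* of cross-channel coupling, not its absolute
values; tests assert only the ordering.

### Seeding

All randomness flows from a master seed.  Per-session seeds are derived
by a fixed rule — a `numpy` `SeedSequence` keyed on (master seed, CRC-32
of the participant id, CRC-32 of the action label, session index) — so a
participant's data are a pure function of (protocol, signatures,
participant id, master seed), and any session can be regenerated in
isolation.

## Signal processing

Per repetition: locate peak activity, cut a window, rectify, filter.

* **Envelope filter**: 3rd-order low-pass Butterworth at 5 Hz.
  Zero-phase (forward–backward, `sosfiltfilt`) by default, so envelope
  peaks are not delayed and peak-centring is meaningful; the magnitude
  response is squared by the two passes.  A causal single-pass mode is
  available for real-time emulation.
* **Peak search**: on the whole-recording rectified-filtered envelopes,
  the argmax of the *summed* two-channel envelope within
  [cue − 0.5 s, cue + 1 s + 1 s]; the asymmetric window prevents
  capturing an adjacent repetition.  Ties break to the earliest sample.
* **Window**: peak ± 1 s (2222 samples at 1111 Hz); a window that would
  overrun the recording is shifted inward with a logged warning rather
  than padded — no fabricated samples.  The emitted segment is rectified
  then filtered *within* the window; tiny negative Butterworth
  undershoot is clipped to zero so envelope samples are non-negative.
* **Channel correlation**: Pearson r between the two filtered channels
  of a segment; r ≤ 0.5 is flagged "low".  Correlations are computed
  per-segment and averaged, not over concatenated recordings.

On simulator ground truth, every emitted segment centres the true burst
within 150 ms (observed maximum ≈ 130 ms over a full participant).

## Features

Six statistics per channel over the 2 s envelope samples V_i, twelve per
segment: mean, maximum and minimum absolute voltage; sample standard
deviation (n−1 denominator); skewness g1 = m3/m2^{3/2}; and Pearson
(non-excess) kurtosis m4/m2², where m_k are population central moments.
The non-excess kurtosis convention (Gaussian → 3) was fixed because
envelope kurtosis values in this setting fall in the 5–10 range, which
only makes sense on the Pearson scale.  A channel with (numerically)
zero variance reports skew = kurt = 0 with a logged warning instead of
failing, so degenerate inputs do not abort a 4095-subset sweep.

Features are fed to the classifiers **raw** — no calibration,
standardization or scaling anywhere.

## Classification

* **KNN**: k = 5, Euclidean distance (ties follow scikit-learn's
  deterministic distance-ordered behaviour).
* **LDA**: scikit-learn's SVD solver, which handles singular
  within-class covariance on small feature subsets without an explicit
  ridge term.
* **SVM**: RBF kernel, one-vs-one multiclass, `gamma="scale"`
  (1/(d·Var(X))) and C = 100.  Both choices compensate for the
  deliberately unscaled features: the kernel width must adapt to raw µV
  magnitudes, and with C = 1 the margin penalty dominates and the SVM
  underfits badly (≈0.89 overall accuracy on the reference synthetic
  participant versus ≈0.97 at C = 100, and worst of the three
  algorithms — implausible for a maximum-margin classifier on
  well-separated data).  All hyperparameters are overridable through
  `ClassifierSpec`.

Performance is measured by stratified 5-fold cross-validation, shuffled
under the spec seed; each sample is predicted exactly once while held
out and all folds accumulate into one 6×6 confusion matrix.
Session-grouped folds are available (`group_by_session=True`) to guard
against within-session leakage but are not the default, since plain
stratified folding is the conventional baseline.  Note that segments
from one session share slow modulations, so stratified-fold accuracies
are optimistic relative to session-grouped ones — a property the
synthetic data shares with real repeated-session recordings.

## Evaluation

Per-action one-vs-rest counts give precision TP/(TP+FP), sensitivity
TP/(TP+FN), action-specific accuracy (TP+TN)/total and F1; overall
accuracy is trace/total.  Zero-denominator precision or sensitivity is
reported as 0 with a warning (this occurs routinely for 1-feature
models that never predict some action).

The sweep evaluates every subset of the 12 features (C(12,k) per size k,
4095 total) for each algorithm; each subset's fold-shuffling seed derives
from (sweep seed, algorithm, subset), making results independent of
evaluation order and of which other subsets run.  Optional seeded
subset-subsampling exists for quick runs and is off by default.

Plateau onset is the smallest k whose mean-metric relative change from
k−1, |m_k − m_{k−1}|/m_{k−1}, is within 5%; the absolute difference is
used so a small *decrease* also counts as plateaued.  The accuracy-vs-k
curve is summarised by a least-squares fit acc = a + b·ln k.
Cross-participant aggregation reports, per (algorithm, k), the mean ± SD
across participants and the participant min–max range; the SD over
feature subsets within a participant is kept separate from the SD across
participants, and both are labelled.

## Problem sizes and defaults

The package's reference experiment is one simulated participant (300
segments) swept over all 4095 subsets × 3 algorithms × 5 folds, which
completes in a few minutes on a single core; the test suite uses a
50-subsets-per-size reduction of the same sweep, and the cross-
participant aggregation tests use small protocols (2 sessions, 5 reps)
for speed.  Headline numbers from synthetic data are labelled as such in
reports and should not be read as estimates of human-subject accuracy:
the generator's class separations are idealised, within-session
correlation inflates stratified-CV accuracy, and electrode-placement
variability, fatigue and crosstalk are absent.

## Numerical choices

* CSVs written by the pipeline carry 9 significant digits (feature-table
  CSVs use full 17-digit precision and a round-trip parser so re-reads
  are bit-exact).
* Argmax ties in peak search break to the earliest sample; KNN
  prediction ties follow the library's deterministic ordering.
* The plateau detector requires strictly positive metric values.
* Statistical tests floor the standard error of a per-k subset mean by
  its binomial cross-validation noise sqrt(p(1−p)/n)/√m, which matters
  at k = 12 where only one subset exists and the empirical
  between-subset spread is identically zero.
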