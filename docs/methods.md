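# Methods

## Problem setting

Semi-structured clinical interviews (negative-symptom assessments) are
recorded on two lapel microphones, a webcam and a depth camera.  The
pipeline turns these recordings into eleven per-subject feature tables — four
verbal (LIWC, Diction, LDA, Doc2Vec), three nonverbal-speech
(conversational, OpenSMILE, DisVoice), three facial (Affectiva, OpenFace,
Opsis) and one body-movement set — and learns to predict diagnosis group
(SCZ / MDD / HC) and binarized symptom severity.  Verbal and acoustic
descriptor *computation* (ASR, LIWC word counts, OpenSMILE LLDs, facial
toolkits) is outside this package's scope: those streams enter as numeric
tables or framewise series.  The bespoke steps — speech-activity decoding,
conversational and kinematic feature extraction, stream compositing, label
binarization, and the calibrated late-fusion ensemble — are implemented and
tested here.

## Synthetic cohort generator

Real recordings cannot be shared, so `cohort.generate_cohort` emulates the
study.  The generative model is deliberately minimal:

* **Latent severity.** Each subject carries one latent severity
  `s ~ Normal(mu_dx, 1)` with `mu = 0 / 3.3 / 3.5` for HC / MDD / SCZ.  The
  within-group SD is 1 by construction; the patient-control spacing of
  roughly 3.4 SD was chosen so that a strong behavioral effect can support
  high downstream accuracy (with a narrower spacing, the shared factor would
  cap patient-vs-control balanced accuracy well below what the recovery
  experiments require, no matter how large the per-feature effect).
* **Clinical scores.** Each scale is `group median + loading * (s - mu_dx)
  + noise`, clipped to its legal range (NSA-Total in [16, 96], BPRS ≥ 18).
  Group medians are the published cohort values (NSA-Total
  41 / 40.5 / 29; BACS composite −1.6 / 0.1 / 0.0; BPRS-Total 32 / 32 / 20
  for SCZ / MDD / HC), so binarization thresholds land where they should.
  A single shared factor cannot jointly reproduce the MDD profile (severe
  negative symptoms, near-normal cognition) through one loading per scale,
  which is why medians are anchored per diagnosis and `s` only drives
  within-group variation and the behavioral features.
* **Feature effects.** `effect_size` is the approximate Cohen's d of the
  patient-control separation per modality (scalar or keyed by feature set /
  modality group / diagnosis; default 0.8, a moderate-to-large effect in
  line with the group differences such cohorts report).  Informative
  features (default half of each table) shift by `d * s / 3.4` along a
  diagnosis signature: SCZ shifts all informative features positively, MDD
  half positively and half negatively.  Distinct signatures are what make
  MDD-vs-SCZ discrimination possible at all; with a common signature the two
  patient groups would be statistically identical.  `effect_size = 0` gives
  an exact null.
* **Raw signals.** Turn taking is an alternating-renewal process with
  log-normal turn and pause durations (positive, right-skewed, two
  parameters); severity lengthens response latency and shortens participant
  turns.  Overlapping floor changes occur with probability 0.1 per
  transition and brief interjections at 1/min; both are disabled cleanly
  when the overlap probability is 0.  Energy envelopes are two-level
  (−30 / −5 dB) plus Gaussian noise (default SD 2.5 dB).  Skeletons are a
  seated base posture plus low-frequency sway and band-limited jitter whose
  amplitude decays exponentially in severity, plus Poisson spike artifacts
  that exercise the median filter.  Facial and windowed-acoustic streams are
  Gaussian with per-subject random offsets, so the subject-level effect size
  is controlled rather than washed out by frame averaging.
* **Studies and sessions.** MDD subjects sit in cross-sectional study B;
  SCZ and HC split between studies A and B in the published proportions
  (54/103 and 26/75), with study-A subjects contributing up to three
  sessions and an optional study-level mean offset available for
  domain-shift experiments.
* **Scale.** Default interviews last 120 s at 100 Hz (audio), 30 Hz
  (skeleton) and 15 Hz (facial); windowed acoustic streams (988 descriptors
  per 100 ms window) are composited and then discarded rather than stored.
  These sizes keep a full 228-subject cohort generatable in seconds while
  leaving every extractor with realistic inputs.

Determinism: every stage draws from a seed stream keyed by (config seed,
stage, record), so identical configs produce bit-identical bundles and
results do not depend on which feature sets are requested.

What the generator does **not** emulate: real acoustic content (no
waveforms or text), inter-modality correlations beyond the single latent
factor, missing recordings, session-to-session drift, medication effects,
or the heavy-tailed and bounded distributions of real toolkit outputs.
Passing recovery tests therefore establishes that the pipeline is unbiased,
leak-free and sensitive to injected signal — not that real-data accuracies
are reproduced.

## Speech-activity decoding

Per channel, a two-state diagonal-Gaussian HMM is fitted to the framewise
log-energy (EM capped at 50 iterations, fixed seed, state means initialized
at the lower/upper energy quartiles) and the Viterbi path is decoded; the
higher-mean state is "speaking".  If the two fitted means differ by less
than 3 pooled SDs the envelope carries no speech/silence contrast (silence
only, or constant input) and the decoder returns all zeros with a warning.
Masks are cleaned by 1-D morphological closing with a flat, centered
(odd-width) structuring element, default 0.5 s; the sequence is treated as
embedded in silence (zero padding).  Channels are decoded independently;
no overlap-aware multi-speaker model is attempted.

## Conversational features

The turn-taking literature names these events without fixing them; the
definitions here are explicit parameters (`ConversationConfig`): segments
merge into turns across gaps < 1.0 s; an interjection is a segment < 1.0 s;
an interruption is a participant turn onset while the interviewer channel is
active, successful iff the interviewer goes silent within a 2.0 s grace
window; response time is the interviewer-offset-to-participant-onset gap
with overlapping (negative) latencies counted as 0; a natural turn is a
floor change with no overlap.  All per-minute rates and the speaking rate
(words per second) use the full interview duration as denominator — the
natural reading of "per minute"/"per second" and the only one that is
well-defined when a subject barely speaks.  A subject with no speech at all
yields zeroed duration features and a degeneracy flag rather than NaNs.
The implementation is verified feature-by-feature against an independent
brute-force frame/segment enumerator on hundreds of random masks.

## Body-movement features

Skeletons are despiked with a centered running median over 1 s (edges:
shrinking window).  Linear speed is the inter-frame Euclidean displacement
over the frame interval (m/s — the per-second convention was chosen over
per-frame displacement and is configurable via the time axis).  The six arm
angles are defined at the shoulder (toward shoulder-center vs toward
elbow), elbow (toward shoulder vs toward wrist) and wrist (toward elbow vs
toward hand) via the arccos of the normalized dot product, clipped to
[0, π]; a zero-length segment keeps the previous frame's angle and warns.
Angular *speed* is the magnitude of the angle's first difference over the
frame interval, keeping speed means non-negative and time-reversal
invariant; angular acceleration (the first difference of that speed) stays
signed.  All statistics use the population (÷N) convention.  The 64
features are ordered 20 joints × (LinSpeed mean, STD), then 6 angles ×
(AngSpeed mean, STD), then 6 angles × (AngAcc mean, STD).  The kinematic
map is rigid-motion invariant; the per-coordinate median filter is not
exactly so, which is why the invariance guarantee applies to the feature
map itself.

## Stream summarization

Moments are population moments; skewness and excess kurtosis of a
zero-variance stream are defined as 0 (deterministic, no NaN propagation;
excess-kurtosis convention, configurable at the call site by adding 3).
Threshold fractions (share of frames above 10 on 0-100 expression scales)
are computed on raw streams only — deltas are signed and a fixed positive
threshold would be meaningless there.  Binary action-unit classification
streams are summarized by their mean only; all other streams get the full
six statistics on both raw and delta series.  The 4-statistic compositing
of windowed acoustic descriptors (max, min, mean, STD) yields 4·d features,
3952 for the standard 988-descriptor configuration.

## Label binarization

`Above` iff score ≥ threshold (equality is Above).  The registry carries the
clinically anchored cutoffs — NSA-Total 39.75; BPRS-Total 24 and 32;
PANSS-Total 38 and 52; PANSS-FSNS 9.5 and 14.5 — and a polarity flag: for
the BACS composite Z-score severity runs downward, so a deficit is score
*below* −1 (mild) or −2 (severe).  Scales without published cutoffs use the
median rule: the observed training value minimizing the class imbalance,
ties broken toward the median, recomputed inside each training fold so no
test information leaks into the threshold.

## Ensemble and calibration

Hyperparameters are standard library defaults in the spirit of the original
design (no tuning): linear-kernel SVM C=1, logistic regression C=1,
gradient boosting 100 stages of depth 3, AdaBoost 50 stages, random forest
100 trees; all seeds fixed.  SVM "probabilities" are a logistic link on the
decision values — the min/max/threshold calibration downstream is the
pipeline's own correction, so a second (Platt) calibration layer would be
redundant.  z-scoring uses training statistics only (zero-variance features
dropped); SMOTE (synthetic minority points as convex combinations of
k=5 minority neighbours, k shrinking with the class) runs after z-scoring
and strictly inside training folds, including the internal-calibration
folds.  Internal calibration CV is leave-one-out by default with a
stratified k-fold fast mode for larger samples.  The calibration map
anchors the geometric-mean-optimal threshold at 0.5 and interpolates
linearly to 0 and 1 at the observed probability extremes (the anchor-at-0.5
shape is a design choice; candidates are midpoints of consecutive distinct
out-of-fold probabilities, ties to the smallest).  Fusion averages
calibrated scores with a ≥ 0.5 decision — equivalent to a weighted vote —
with a strict-majority mode behind a flag since the two descriptions of the
combination step differ.  Multiclass tasks are decomposed one-vs-rest with
fused per-class scores and argmax, ties broken in the fixed order SCZ, MDD,
HC.

## Evaluation

Positive-class conventions (required for SEN/SPE to be well-defined): the
patient class in patient-vs-control contrasts, MDD in MDD-vs-SCZ, `Above`
(or deficit, for BACS) in severity tasks.  BAC = (SEN+SPE)/2 for binary
tasks; multiclass BAC is the mean of per-class recalls (the published
three-way row follows this convention too — its printed BAC is not
(SEN+SPE)/2 of its macro pair).  AUPRC is step-wise average precision, not
trapezoidal.  Cross-study splits reproduce the four session schemes
(A1+B→A2, A1+B→A3, A1→B, B→A1); when the training sessions contain earlier
visits of test subjects, the harness evaluates subject-by-subject with the
held-out subject's own records removed from the training side, preserving
strict subject confinement (audited per fold in the tests).

## Problem sizes and numerical choices in the checks

Recovery experiments run at desk scale as the package's own standard
configuration: null calibration on 60 subjects (full five-classifier
ensemble, one 30-feature verbal table, 10-fold internal calibration),
strong-effect recovery on 60 subjects with two verbal tables, and the
dose-response sweep over effect sizes 0/1/2 × 10 seeds with a
logistic-only ensemble — the sweep audits the generator's monotone signal,
for which the single-classifier ordering is an adequate and far cheaper
proxy.  The 95% binomial band around 0.5 for n=60 is [0.374, 0.626].

## Known limitations

* The event thresholds of the conversational features (merge 1.0 s,
  interjection 1.0 s, grace 2.0 s) are conventions, not estimates; results
  on real data would depend on them.
* The HMM decoder assumes a bimodal log-energy per channel; cross-talk
  between microphones is not modeled.
* The generator's single-latent-factor-plus-signature structure is the
  simplest model making scores and features jointly informative; real
  inter-modality dependence is richer.
* No hyperparameter search, no regression (continuous-score) mode, no
  neural models — by design.
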