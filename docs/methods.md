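# Methods

This note documents the models, numerical choices and limitations behind
`vitalfield`: what the synthetic cohort emulates, how labels arise, what the
classifiers are asked to learn, and what the secure field simulation does and
does not model.

## The synthetic cohort

The generator emulates the statistical structure of a bedside-monitor corpus of
53 subjects recorded for 8 minutes at 1 Hz — 481 samples per subject inclusive
of both endpoints, 25,493 rows in total. Four channels are produced: heart rate
(HR, bpm), peripheral oxygen saturation (SpO2, %), respiratory rate (RESP,
breaths/min) and pulse rate (bpm). The pooled targets are:

* HR bimodal with modes near 80 and 100 bpm;
* SpO2 concentrated just below 100 %;
* RESP peaking at 18 breaths/min;
* Pearson correlations corr(HR, Pulse) ≈ 0.97, corr(RESP, HR) ≈ 0.13,
  corr(SpO2, RESP) ≈ −0.30.

### Construction

Within a subject, three latent standard-normal AR(1) processes (coefficient
0.95, stationary unit variance) drive HR, RESP and SpO2. Their innovations are
drawn jointly Gaussian (a Gaussian copula), so monotone channel transforms
preserve the requested latent correlation. Per subject:

* **Context.** altitude ~ U[0, 3000] m, temperature ~ U[−10, 45] °C,
  activity ~ U[0, 1], age ~ DiscreteUniform[18, 45], gender ~ Bernoulli(0.5);
  all constant over the 8-minute record.
* **HR.** The activity level selects the heart-rate regime: subjects with
  activity > 0.5 occupy the exerted component (mean 100 bpm, sd 6), the rest
  the resting component (mean 80 bpm, sd 6), with a small within-regime slope
  (6 bpm per unit activity, centred per regime half). Uniform activity makes
  the two regimes equally likely, which is what produces the pooled
  equal-weight bimodal histogram. Each regime path is the Gaussian quantile
  transform of the smoothed latent through its component.
* **RESP.** 18 + 1.0·(activity − 0.5) + 1.2·z. The narrow spread keeps the
  resting respiratory ceiling (20 breaths/min) more than two standard
  deviations away, so resting physiology is almost never mislabeled.
* **SpO2.** min(100, 97.5 + 1.0·z − d), with d = 1.5 %·(altitude − 1000 m)/1000
  above 1000 m: acclimatisation depresses the baseline exactly as much as the
  labeling floor drops, so altitude alone never changes a label.
* **Pulse.** HR + N(0, 5.5 bpm): an independent-sensor reading of the same
  cardiac signal.

An important calibration fact: the **latent** correlation matrix is a knob, not
the observed target. Pooling subjects adds between-subject variance (regimes,
altitude, activity) and episode variance, all of which dilute or augment the
within-subject covariance. The default latent matrix (HR–RESP 0.50,
RESP–SpO2 −0.75, HR–SpO2 0) and the episode co-occurrence rules below were
calibrated by simulation so the **observed pooled** correlations land on
0.97 / 0.13 / −0.30; across 25 generation seeds the measured ranges were
0.967–0.972, 0.106–0.157 and −0.343 to −0.269, inside the ±0.02 / ±0.04 / ±0.05
tolerance bands. The pulse-noise sd (5.5 bpm) was likewise fitted with the
simulation oracle so corr(HR, Pulse) centres on 0.970.

### Abnormal episodes

Ground-truth anomalies are injected as explicit episodes on the clean
channels; the labeling rules then detect them. A scenario scheduler draws
~3.2 events per subject (durations U[30, 60] s), stratified so that every
block of three events contains one of each archetype:

* **exertion** — tachycardia of +(40 + 40·activity) bpm on HR and pulse with a
  mild respiratory co-elevation (+3.3 breaths/min). The magnitude grows with
  activity because the personalized HR ceiling does too; a fixed +30 bpm bump
  would hide below the ceiling of a hot, highly active subject.
* **hypoxia** — desaturation of −8 % SpO2 (floored at 70 %) with a compensatory
  tachypnea of +6.5 breaths/min.
* **hyperventilation** — isolated tachypnea of +(10 + 10·activity) breaths/min.

The co-occurrence is physiological (hypoxic ventilatory response, exertional
breathing) and is also what supplies the negative SpO2–RESP and positive
HR–RESP covariance at the pooled scale. `inject_episodes` itself applies each
episode to a single channel pair exactly as specified; only same-kind overlap
is rejected, and co-occurring kinds are separate `EpisodeSpec`s at the same
interval.

With these defaults, 29–32 % of rows are labeled abnormal (across seeds), the
episode-free baseline mislabel rate is below 1.5 % (distribution tails only),
and every injected default-magnitude episode overlapped at least one
abnormal-labeled row in 25 × ~280 scheduled episodes.

### What the generator does not emulate

Real monitor data has autocorrelated, non-Gaussian artefacts (motion, probe
detachment), circadian and respiratory-sinus structure, missing data, and
per-subject baseline diversity far richer than three latents. Passing tests on
this cohort demonstrates that the pipeline recovers structure it was built to
contain; it does not demonstrate clinical validity on real waveform-derived
vitals.

## Measurement noise

Applied after episode injection, per channel, in a fixed order — Gaussian →
salt-and-pepper → periodic — so zero-parameter operators are identities and a
fixed seed reproduces the noisy cohort exactly:

* Gaussian sd: HR 2.0, pulse 2.0, RESP 1.0, SpO2 0.5 (channel units);
* salt-and-pepper: p = 0.01 per sample, extremes HR/pulse (30, 200),
  RESP (4, 40), SpO2 (70, 100), low/high equiprobable;
* periodic: 1.0 breaths/min at 0.05 Hz, RESP only.

Noisy SpO2 is clipped at 100 %. Labels always come from clean channels: noise
corrupts what the classifier sees, never what is true. The magnitudes are
small relative to the labeling margins by design — large enough to force the
models to smooth and contextualise, small enough that the state remains
learnable.

## Features

17 model inputs per row: the four noisy channels; their trailing 5-sample
rolling means (partial windows at the head); the dominant non-DC DFT frequency
of a trailing 64-sample window per channel (mean-removed, ties to the lower
bin, sentinel 0 Hz below 8 samples of history); and Age, Gender (0 = male,
1 = female), Altitude, Temperature, Activity_level. No scaling is applied at
the table level; the scale-sensitive models standardise inside their own
pipelines.

Time-shift augmentation displaces each subject's 12 signal-derived columns by
k ∈ {±1, ±2, ±3} samples while keeping the label at the new alignment,
truncating the |k| undefined edge rows. Augmented rows carry a provenance flag
and are admitted only to training sets, and only when both the label row and
the feature-source row fall in the training portion — they never appear in any
evaluation fold or test split.

## Labeling

Personalized closed normal ranges per subject (boundary values are normal;
SpO2 has a floor only):

| vital | base range | adjustments |
|---|---|---|
| HR, pulse | [60, 100] bpm | ceiling +40·activity, +0.5·(T−30)⁺, −0.3·(age−30)⁺, +2 if female; floor −10·activity |
| RESP | [12, 20] br/min | ceiling +10·activity |
| SpO2 | ≥ 95 % | floor −1.5·(altitude−1000 m)⁺/1000 |

A row is abnormal iff any vital leaves its range. All coefficients are exposed
in `LabelingConfig`; they are this package's quantification of qualitative
physiology (exertion raises acceptable heart rate and breathing, heat adds
cardiac load, maximum heart rate declines with age, altitude lowers baseline
saturation) and have no external calibration source. There is no SpO2 upper
bound — 100 % is a physical ceiling, not an anomaly. Multi-class severity
grading and longitudinal fatigue tracking are out of scope.

## Classifiers

Six models, fixed hyperparameters, no search: logistic regression (L2, C = 1,
standardised inputs) as the linear baseline; k-NN (k = 15, distance-weighted,
standardised); random forest (300 trees); gradient boosting (300 estimators,
learning rate 0.1, depth 3); XGBoost (300, 0.1, depth 4; optional at runtime —
its absence downgrades the benchmark to five models with a warning); and an
MLP (64/32, early stopping, standardised).

Evaluation: stratified 80/20 train/test split (class proportions within one
row), stratified 5-fold cross-validation on the original training rows,
weighted-average precision/recall/F1, confusion matrix oriented with abnormal
as the positive class. Reports are deterministic given the seed. On the
default table the tree ensembles and the MLP sit near 0.99 held-out accuracy
and the linear baseline lower — the labels are threshold rules with context
interactions, which is the regime tree models excel in. The residual error is
concentrated where measurement noise crosses a subject's threshold boundary.

## Secure channel

Telemetry envelopes are DEFLATE-compressed then sealed with AES-128-GCM under
a 16-byte pre-shared squad key: fresh random 12-byte nonce per message,
16-byte tag, and the sender id plus a per-sender monotone sequence number
bound as associated data. Compression precedes encryption (ciphertext is
incompressible), replay rejection is a transport concern (the base station
enforces sequence monotonicity), and key distribution/rotation is out of
scope. The wire frame is a fixed big-endian layout (magic 0x5356, version,
length-prefixed sender, seq, nonce, length-prefixed ciphertext, tag).

The AES and GHASH primitives are implemented in the package (tables derived
algebraically at import; per-key cached GHASH byte tables) and are pinned to
the standard known-answer vectors in the test suite. The implementation is not
side-channel hardened; it protects simulated telemetry, not co-tenant secrets.

## Field simulation

N soldier nodes (default 8) advance on a logical clock (default 5 s per tick,
no wall-clock sleeping). Per tick a node ingests the next sample of its own
generator stream (with noise), assembles its feature row from trailing windows
over a ring buffer (capacity 64), predicts its state with the persisted model
(the feature manifest is checked at startup), and moves by a Gaussian random
walk (sd 2 map units/tick) reflected at the 0–100 map boundary. Only abnormal
predictions emit traffic: one sealed alert envelope per abnormal tick,
addressed to the base station and all peers. Link outages queue envelopes in a
FIFO outbox flushed on reconnection; the base station flags replays and
sequence gaps, drops tamper failures, and keeps a roster of last state,
position and liveness tick. Roster liveness is a link-layer heartbeat, not
payload traffic — all-normal runs generate zero messages.

Determinism contract: node state is owned by its node, nodes step before any
delivery is processed, deliveries run in sorted node order, and every random
stream (vitals, movement, nonces) is a child of the run seed — so
(config, seed, key) fully determine the event log. Peer recipients update a
local teammate-status table and do not re-broadcast. Real radio transports,
GPS, the command GUI and base-station model retraining are out of scope.

## Numerical and procedural choices

* Seed fan-out hashes stage names (SHA-256) into child seeds below 2³¹, so
  adding a stage never perturbs another stage's stream.
* The histogram mode estimator uses 1-unit bins centred on integers; for the
  bimodal HR search the counts are smoothed with a centred 5-bin moving
  average before peak-picking (single-bin sampling jitter at ~12k samples per
  mode otherwise moves the argmax by ±3 bpm), and the two highest local maxima
  at least 10 bpm apart are reported.
* `mixture_quantile` inverts the two-component normal CDF by Brent root
  finding (tolerance 1e−10); the dominant-frequency sentinel for sub-8-sample
  or constant windows is exactly 0.0 Hz.
* Degenerate stratified splits (a one-member class) fall back to a
  deterministic largest-remainder per-class allocation.
* Episode scheduling retries placement up to 50 times before skipping an
  event, keeping same-kind episodes disjoint without biasing timing.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the pipeline at the study's
native size — the 53 × 481 cohort — for generation, labeling and the two
reference ensembles (gradient boosting, random forest), and use an
8-subject × 200-sample cohort for unit-level checks and the simulator's
deployed model. The full six-model benchmark is exercised at reduced ensemble
sizes in tests and examples; the full-size benchmark is available through the
`benchmark` CLI.
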