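# Methods

This note documents the models, numerical choices and limits of the
`somnoscreen` pipeline: the synthetic cohort generator, the epoch
preprocessing, the sleep–wake classifier, and the OSA risk-detection
statistics. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

The generator produces, per patient, a binary hypnogram, a list of
obstructive respiratory events, beat times, a respiratory-effort
waveform and per-epoch/per-modality quality flags. It emulates the
features the downstream analysis exploits, not the full physiology of a
night of sleep.

**Hypnogram.** A two-state Markov chain over {sleep, wake} at epoch
resolution (30 s). With target wake fraction *w* and fragmentation *f*,
the transition probabilities are P(sleep→wake) = c·w and
P(wake→sleep) = c·(1−w) with c = 0.10·f, so the stationary wake
probability is exactly *w* and the expected transition density scales
linearly with *f*. The default wake fraction is drawn uniformly in
0.14–0.27, the range typical of diagnostic sleep-laboratory nights. A
bare chain with this persistence has a sampling SD of the realized wake
share of ≈ 5–6 percentage points over an 8 h night, which would let
single patients drift far from the intended cohort structure; the
generator therefore redraws (at most 50 times, deterministically under
the seed) until the realized share is within 4 points of the target for
recordings of ≥ 200 epochs, keeping the closest draw otherwise.
Fragmentation grows with severity as f = 1 + AHI/30, reflecting
event-driven arousals.

**Events.** The event count is ⌈AHI × hours-of-sleep⌋ with
hours-of-sleep = sleep epochs × 30/3600. Durations are uniform in
10–30 s (configurable within 10–60 s), the apnea/hypopnea mix is 50 %,
and events are placed uniformly in the free space of maximal contiguous
sleep runs with ≥ 5 s of recovered breathing between events, so events
never overlap each other or any wake epoch. Requested AHI is realized
within ±10 % for AHI ≥ 5 unless the night is so fragmented that free
sleep runs are exhausted.

**Cardiac model.** Instantaneous HR is the stage mean (defaults: wake
70 BPM, sleep mean drawn 8–14 BPM lower per patient) plus a slow
Ornstein–Uhlenbeck modulation (SD 2 BPM, correlation time 60 s). Each
event superimposes a piecewise-linear bradycardia ramp (down to −12 BPM
at the event end for apneas, half for hypopneas) followed by a
tachycardia overshoot (+18 BPM) decaying over 10 s — the autonomic
signature of breathing restoration. HR is clipped to 42–175 BPM, which
keeps all inter-beat gaps strictly inside the physiologic 0.33–1.5 s
band; beats are obtained by integrating the instantaneous rate.

**Respiratory model.** A phase-continuous oscillator with a second
harmonic (breath asymmetry). Rate and amplitude are stage dependent —
sleep is slower (≈ 13/min vs ≈ 17/min), deeper (amplitude 1.3 vs 0.9)
and far more regular (rate-OU SD 0.4 vs 1.5 breaths/min, amplitude
modulation 8 % vs 35 %) — so wake and sleep are separable from waveform
shape and rate even after amplitude information is destroyed by min–max
normalization. Obstructive apneas multiply the envelope down to 2 % of
the local baseline (a flat line, with 0.5 s cosine ramps); hypopneas
reduce it to 50 %. The default sampling rate is 32 Hz: every behavior
relevant to a 0.04–2 Hz analysis band and a 4 Hz grid is preserved while
keeping simulation fast; the rate is configurable for realism.

**Artifacts and quality.** Motion bursts — 1–3 s unit-RMS band-limited
transients scaled to 6× the baseline effort amplitude — occur as a
Poisson process at 80/h during wake and 5/h during sleep, plus one burst
with probability 0.35 at each event termination (the large body movement
when breathing resumes). A 10-min-period baseline drift (5 % of
baseline) is always present. An epoch is graded **low quality** exactly
when the artifact energy injected into it exceeds 5 (signal units)²·s;
the cardiac channel sees the same motion with gain 2, mimicking the
higher motion sensitivity of capacitive ECG electrodes. These rates were
chosen once to reproduce the qualitative pattern of capacitive-sensor
studies — roughly half of wake epochs and a sizable minority of apneic
sleep epochs degraded, wake > sleep and apnea > no-apnea in every severe
cohort — not any exact percentage, since the physical artifact process
is sensor specific. The energy-threshold grader is a stand-in interface:
real per-epoch signal-quality classifiers can be plugged in wherever a
per-epoch boolean per modality is accepted.

**What is not emulated.** REM/NREM substructure (the task is two-class),
oxygen saturation, body position, central apneas, periodic limb
movements, sensor-specific waveform morphology, and coupling between
quality loss and *signal content* beyond additive bursts. Consequently,
passing tests show that the pipeline's logic is correct and that its
statistics behave as designed under the stated generative assumptions;
they do not certify clinical performance on real recordings.

## Preprocessing

Numerical choices where the procedure leaves freedom:

* Tachogram interpolation is **linear**, with each R–R interval's HR
  anchored at the beat that closes it; linear interpolation is robust on
  30 s segments and consistent with the piecewise mirror-fill.
* The three outlier rules are applied to the 4 Hz interpolated segment
  (so the 2.5 s / 10-sample gap rule is well defined); the segment's
  median and SD are computed once, on the raw segment, before any
  correction.
* An outlier run at the very start of a segment has no preceding samples
  to mirror; it is filled by mirroring the *following* samples (logged).
  A run that cannot be filled either way rejects the segment.
* The respiratory band-pass is Butterworth order 4 applied
  forward–backward (zero phase) so filtering never shifts epochs against
  the hypnogram. Empirical bounds: |H| ≥ 0.95 at 0.3 Hz, ≤ 0.1 at
  0.005 Hz and at 4 Hz.
* Downsampling to 4 Hz uses polyphase resampling; its anti-alias filter
  protects the top band edge (2 Hz sits exactly at the 4 Hz Nyquist — a
  deliberate, documented tolerance).
* Patient-level statistics (median HR, respiratory median/SD) are
  computed over the **full recording before any epoch rejection**, so
  rejected epochs cannot shift normalization.
* Rejection reasons partition rejected cardiac epochs (`min-beats`,
  `long-outlier`, `degenerate`); kept + rejected always equals the epoch
  count.

## Sleep–wake classifier

The default architecture is three convolution blocks per branch (8/16/32
filters, kernel 5, ReLU, max-pool 2) with a 32-unit dense layer, dropout
0.25 and a 2-class softmax — small enough to train in minutes on one CPU
and fully configurable. The training engine (`somnoscreen.nn`) is a
compact numpy implementation (valid 1-D convolution, Adam, class-weighted
cross-entropy, early stopping on validation loss) verified against
numerical gradients; it is deterministic under a seeded generator with
single-threaded numpy.

Choices that matter:

* **Augmentation order.** Amplitude scaling is applied *after*
  normalization. Applied before, min–max normalization would cancel the
  scale exactly and the augmentation would be vacuous; applied after, it
  forces amplitude invariance of the learned decision function.
* **Logical duplication.** The ×4 duplication is implemented as four
  passes over the shuffled data per training pass with fresh scale
  draws — mathematically equivalent to materialized duplication,
  memory-free.
* **Augmented branches.** By default only the respiratory branch is
  rescaled: the tachogram is in absolute BPM and carries no cross-sensor
  amplitude confound. This is configurable (`AugmentationConfig.apply_to`).
* **Class imbalance.** Wake is ~20 % of epochs; the loss uses
  inverse-frequency class weights.
* **Optimizer defaults** (Adam, lr 1e-3, batch 64, patience 10) are
  configuration, not behavior: they live in `TrainingConfig`.
* **Selection.** The repeated protocol scores pooled κ over all
  selection-set epochs (not a per-patient mean) — the simpler reading,
  switchable by scoring per recording; ties break to the lowest repeat
  index. Splits are always by patient, never by epoch.
* **Fusion.** The fused model copies both trained convolutional stacks,
  freezes them (bit-identical weights before/after, asserted by
  checksum), and retrains only the dense head.
* **Tie rule.** p(wake) = 0.5 predicts sleep (the majority class); this
  is unmeasurable at float precision but must be deterministic.

## Risk detection

* **Threshold statistics** pool epochs across all reference recordings
  (not per-patient medians then averaged); the SD is the population SD
  of that pooled distribution. Both choices are the simpler reading of
  "median − SD over the reference patients" and are isolated in
  `fit_confidence_thresholds` if a per-patient variant is needed.
* **Denominators.** `% uncertain sleep` divides by *sleep-predicted*
  epochs (an operating point of 66 % would be implausible as a fraction
  of all epochs when ~80 % of the night is sleep); a recording with no
  sleep-predicted epochs reports 0 and is flagged. `% transitions`
  divides by adjacent retained-epoch pairs (n − 1); rejected epochs are
  skipped so their neighbours become adjacent, rather than breaking the
  sequence.
* **Decision rule.** Strict `>` at both index thresholds; a patient on
  the boundary is not flagged.
* **ROC selection.** Candidates are the observed index values (plus one
  point below the minimum); among thresholds achieving the target
  specificity the smallest — i.e. most sensitive — is returned. The
  maximum observed value always achieves specificity 1, so a feasible
  point exists; if the target itself is infeasible the max-specificity
  point is returned with a warning.
* **Degenerate tables.** A confusion table with a zero cell reports the
  DOR after a Haldane–Anscombe 0.5-count correction, flagged
  `dor_corrected`; with a single-class truth vector Se or Sp (and the
  DOR) are NaN.
* **Both AHI cuts** (≥ 15 and ≥ 30) are evaluated from the *same*
  decisions: thresholds are fitted once for the AHI ≥ 15 screen and
  reused for the ≥ 30 report.
* The paired comparison of index values between conditions uses the
  two-sided Wilcoxon signed-rank test (zero differences dropped, exact
  small-sample distribution).

## Problem sizes in the test and acceptance runs

All sizes are the package's own desk-scale choices. The acceptance test
suite trains the respiratory network once on a 20-patient low-AHI pool
with full 8 h nights (70/30 patient split) and evaluates on 5 held-out
patients; the risk-index study uses twenty 36-patient test-style cohorts
(6/4/9/17) and a 12-patient severe cohort at 2 h per night, where every
index is a per-patient fraction and shorter nights only widen its
sampling noise. `scripts/acceptance.py` uses a 12-patient pool at 4 h,
five test-style cohorts and a 10-patient severe cohort. Training runs 12
passes with patience 4; the repeated-selection protocol itself is
exercised at small scale in the unit tests (the full ten-repeat default
remains available through the CLI and pipeline).

## Known limitations

* The generator's separability is by construction; real sleep–wake κ
  from cardiorespiratory signals is far below the synthetic values, and
  none of the clinical agreement numbers are reproduced here.
* EDF export is minimal (plain EDF, 1 s records, 16-bit); EDF+
  annotations are read through MNE but not written.
* The quality model ties low quality to additive artifact energy only; a
  real signal-quality classifier also reacts to flat-lines, saturation
  and coupling loss.
* `% transitions` counts label changes over adjacent retained pairs; on
  heavily gapped recordings (aggressive cleaning) the index mixes true
  instability with stitching effects — which is precisely why the
  full-recording mode is the default for risk detection.
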