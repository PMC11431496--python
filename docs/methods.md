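# Methods

## Problem setting

Cortical arousals are brief (≥ 3 s) interruptions of sleep scored from
EEG changes under AASM rules.  Home-sleep-testing (HST) devices rarely
record EEG; they do capture autonomic correlates of arousal — transient
tachycardia, changes in respiratory effort, interrupted snoring.  This
package studies EEG-free arousal detection in a simulated limited-channel
setting: the candidate inputs are thoracic effort (`Thor`), ECG-derived
heart rate (`DHR`), cannula-vibration snore (`Snore`), body position
(`Pos`), a derived position-change indicator (`Pos_chg`) and a binary
wake/sleep trace (`WS`) extracted from the 30 s-epoch hypnogram
(1 = asleep; "wake" here means stable wakefulness, not arousal).

## Detector

The detector is a per-second sequence labeler over 4 Hz multichannel
input:

- **Inception block** — four parallel convolution blocks (convolution →
  batch normalization → ReLU) with kernel sizes 5, 33, 65 and 129,
  covering receptive fields from ~1 s to ~32 s; branch outputs are
  concatenated along the channel axis.
- **Two residual blocks** — each block has two components of two
  convolution blocks with skip connections; the second component of each
  block strides by 2, so the two blocks map 4 Hz → 1 Hz.  The four
  residual kernel sizes (1, 2, 7, 2) are assigned as: component 1 uses
  kernels (1, 2) at stride 1; component 2 uses (7, 2) with the stride on
  its first convolution and a stride-2 kernel-1 projection on its skip
  path.  A kernel-1 projection is also used wherever the channel count
  changes.  This is one consistent reading of the kernel-size list; the
  block-internal ordering is not uniquely determined by its description.
- **Two unidirectional LSTM layers** over the 1 Hz feature sequence,
  then a linear head with sigmoid activation: one arousal probability
  per second.

Convolutions are same-length with asymmetric padding for even kernels
(one extra sample on the left), which keeps the output-length law exact:
a T-second input always yields exactly T probabilities.  Convolutions
followed by batch normalization carry no bias (it would be cancelled by
the mean subtraction and receive zero gradient).

Channel widths are deliberately small and configurable (defaults: 16
filters per inception branch, 64 residual channels, LSTM hidden size
64); the tests and worked examples use an even smaller configuration
(4/16/32) that trains in about a minute per model on one CPU core.

The network, its reverse-mode automatic differentiation and the
optimizer are implemented in NumPy inside the package (`hstarousal.nn`):
float64 throughout, im2col-style convolutions with strided-slice
gathers, fused batch-normalization and binary-cross-entropy-with-logits
ops.  Gradients are verified against central finite differences in the
test suite.

## Training recipe

Per-second binary cross-entropy; truncated backpropagation through time
with a depth of 90 output steps (360 input samples), LSTM state carried
across segments within a record (detached at segment boundaries) and
reset between records; batches of up to 30 records advance in lockstep,
with shorter records masked out of the loss rather than padded into it;
Adam (β₁ = 0.9, β₂ = 0.999, weight decay λ = 1e-5), initial learning
rate 1e-4 reduced by a factor of 10 when validation AUPRC fails to
improve for four consecutive epochs; up to 30 epochs, returning the
epoch with the best validation AUPRC.  Validation AUPRC is computed on
sleep seconds only, consistent with the evaluation convention.  No class
re-weighting is applied.

For desk-scale demonstrations on synthetic cohorts the defaults are
overridden to a 10-epoch schedule at learning rate 1e-3 — with records
twenty times shorter than an overnight recording, the default schedule
would see too few optimizer steps to converge.

## Preprocessing

All channels are resampled to 4 Hz (linear interpolation for continuous
channels, nearest-neighbor for binary/categorical ones, so no fractional
codes appear) and standardized record-wise by removing the median and
scaling the interquartile range to 1.  No frequency filtering is
applied; noise robustness is delegated to the convolutional front end.
Heart rate is outlier-corrected before standardization: samples outside
25–220 bpm or deviating more than 30 bpm from a 5 s rolling median are
replaced by linear interpolation between valid neighbors.  The bounds
and the rolling-median rule are this package's concrete
operationalization; only the goal (undoing R-peak misdetection) is
externally fixed.

A record is excluded when any selected channel is missing, flat for more
than 5 s at a stretch, or out of physiological range for **more than
50 %** of sleep time (exactly 50 % still passes).  Flat-run detection
applies only to continuous channels — binary traces are legitimately
piecewise constant.

Time conventions: seconds from record start, 0-based; intervals are
half-open `[onset, offset)`; the 1 Hz label at index t covers
`[t, t + 1)`; a second is labeled positive iff it intersects an
annotated event.

## Postprocessing

Probabilities become events by thresholding (strict `>`; a probability
exactly at the threshold is negative) and run extraction, followed by
two steps in a fixed order: merge events separated by **less than 5 s**
(a deliberate relaxation of the AASM 10 s separation, absorbing up to
3 s of onset/offset uncertainty), then discard events shorter than
**3 s** (exactly 3 s is kept).  Merging precedes discarding so that
nearby short fragments can coalesce into a valid event.

The decision threshold is chosen on validation data: a 0.01-step sweep
of the pointwise F1 seeds a three-point pattern search (spacing 0.02,
then 0.01) on the event-based F1 computed after full postprocessing;
the triple shifts toward a winning endpoint and the search stops when
the center wins at spacing 0.01.  Ties favor the center, so a flat
landscape returns the pointwise seed.  The 0.01 sweep granularity and
the re-centering rule are this package's choices where the procedure's
description leaves freedom.

## Evaluation framework

- **Pointwise** — precision, recall, F1 over the concatenated per-second
  predictions of all test records, restricted to sleep seconds; AUPRC by
  step-wise precision–recall integration over unique thresholds (no
  interpolation) and AUROC by the rank statistic.
- **Event-based** — a detection D matches a ground-truth event G iff
  |G ∩ D| / |G| **strictly exceeds** Ω_min (default 0.5).  A detection
  matching at least one ground-truth event is a true positive; a
  detection spanning two ground-truth events counts once toward
  precision but credits both events as found in the recall numerator
  (the per-pair criterion does not fix the aggregation; this is the
  documented choice).
- **Recordwise** — the event-based metrics per test record, summarized
  as mean (SD); records without ground-truth events are flagged and
  excluded from summaries.  Models are compared with a two-sided
  bootstrap paired t-test (resampling mean-centered paired differences,
  default 10 000 replicates) under Holm–Bonferroni correction, where the
  family is the set of pairwise comparisons in one analysis round.
  Relative confusion matrices classify every ground-truth event as
  found-by-both / only-A / only-B / neither.
- **Agreement** — the arousal index (events per hour of sleep) per
  record, compared by Pearson correlation and Bland–Altman limits
  (mean bias ± 1.96 SD, sample SD).

Events and detections during stable wakefulness are discarded before
matching; an event partially covering wake is dropped when a strict
majority of its covered seconds are wake (the boundary case is kept).

## Incremental signal selection

Round I trains single-signal models on {Thor, DHR, Snore} — position
and wake/sleep are meaningless alone.  Each later round augments the
best combination with every unused signal and keeps the winner, ranked
by mean recordwise event-based F1.  Per-candidate seeds derive from the
master seed and a hash of the combination, so the path is bit-for-bit
reproducible and no combination is ever trained twice.  Two schedules
exist because the published analysis deviates from pure greedy once:

- `greedy` — strict best-first, to pool exhaustion or an optional
  no-improvement stop (both stopping rules are provided since neither is
  canonical);
- `paper` — the three best round-II pairs advance jointly; round III
  explores the 2-subsets of their partner signals plus Pos (six triples,
  never Pos_chg), and rounds IV–V add one signal each in the order
  Snore, DHR, WS, Pos.  Over the six-signal pool this evaluates exactly
  16 combinations, partitioned 3/5/6/1/1 by size.

## Synthetic data generator

The generator emulates the *signal semantics* the detector exploits, not
waveform physiology:

- `Thor`: a frequency- (±8 %, slow) and amplitude- (±10 %, slow)
  jittered sinusoid at ≈0.25 Hz whose amplitude is multiplied by
  `thor_amplitude_factor` during each arousal;
- `DHR`: 62 bpm baseline with slow ±3 bpm variability plus an additive
  arousal surge — 1 s linear rise to `hr_surge_bpm`, plateau for the
  event, exponential decay (τ = 5 s) after offset.  The fast-rise/
  plateau shape is chosen so the inside-event mean recovers the
  configured effect size (a rise spread over the whole event would
  halve it), matching the transient-tachycardia picture in the
  autonomic literature;
- `Snore`: respiratory-locked oscillatory bursts gated per epoch with
  probability `snore_probability`, suppressed (×0.1) during arousals;
- `Pos`/`Pos_chg`: piecewise-constant position codes with ~30 min mean
  dwell and the derived change indicator;
- `WS`: the hypnogram replicated at 4 Hz.

Ground-truth events are rejection-sampled wholly inside sleep epochs
with durations in `arousal_duration_range` (minimum ≥ 3 s so duration
filtering can never invalidate ground truth) and gaps ≥
`min_event_gap_s` (≥ 10 s so the merge rule cannot fuse ground-truth
events); the target count is Poisson at `arousal_rate` per sleep hour.
All channels are emitted at 4 Hz directly, avoiding resampling artifacts
in tests.  Default conditions: 1 h records, 15 arousals per sleep hour
(a mid-range arousal index for an older community population), 12 bpm
surge, 2× thoracic amplitude change, 15 % wake epochs.

What the generator does **not** emulate: real respiratory waveform
morphology, apnea events, cardiorespiratory coupling, movement
artifacts, or inter-scorer ambiguity.  Passing end-to-end tests on this
generator therefore demonstrates that the pipeline recovers
arousal-locked signatures of the configured kind at the configured
signal-to-noise ratio — not clinical-grade performance on real
polysomnography.

A corruption utility flips each epoch's wake/sleep label independently
with a configurable error rate, emulating an imperfect EEG-free
sleep/wake classifier standing in for the hypnogram.

## Numerical and scale choices

- End-to-end recovery runs use 30-record cohorts of 20-minute records
  (20 train / 4 validation / 6 test), 20 arousals per sleep hour, strong
  signatures (20 bpm surge, 3× thoracic change, low noise), a small
  detector (4/16/32 widths) and the 10-epoch, lr 1e-3 schedule.  One
  training takes roughly a minute on a single CPU core.
- The bootstrap calibration check uses 500 replicates per test and
  1000 null repetitions; production analyses default to 10 000
  replicates.
- Degenerate inputs: flat channels are median-centered and flagged
  instead of divided by a zero IQR; a validation split without positive
  sleep seconds makes AUPRC undefined and raises rather than returning
  a silent number; zero-variance paired differences return p = 1 with a
  degeneracy flag.

## Known limitations

- The lenient overlap criterion has a degenerate optimum: a detector
  emitting a near-constant probability produces (after merging) a single
  whole-record detection that matches every ground-truth event, scoring
  event precision = recall = 1; the majority wake-masking rule only
  removes it when more than half the record is wake.  The local
  three-point threshold search avoids this region whenever the input
  channel is informative enough that the F1 landscape dips between the
  pointwise seed and the degenerate cliff, which is why trained models
  on signal-bearing channels are unaffected.  Channel-discrimination
  experiments on synthetic cohorts therefore include substantial stable
  wakefulness, so a collapsed model's whole-record detection is
  majority-wake and discarded rather than perfectly scored.
- The residual-kernel assignment and the threshold-search re-centering
  rule are documented interpretations of under-specified procedures.
- The EDF writer covers the subset of EDF needed here (16-bit, 1 s
  records, integer sampling rates); it is not a general-purpose
  exporter.
- Training is single-threaded NumPy; it is sized for synthetic studies
  and method development, not for training on full overnight cohorts.
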