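# Methods

This note documents the models and procedures implemented in `emodec`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not demonstrate.

## Problem setting

Self-induced (imagery-evoked) emotions produce EEG responses with lower
amplitude than externally stimulated ones, and high-density montages
(hundreds of electrodes) make end-to-end convolutional decoding expensive:
the decoder's first convolution stage does work proportional to the
channel count C. The pipeline therefore (i) isolates one frequency band,
(ii) ranks channels by a per-channel amplitude statistic and keeps the top
K, and (iii) trains a shallow convolutional network on the raw selected
segments. Classification is binary on one circumplex axis: valence
(negative = 0 / positive = 1) or arousal (calm = 0 / active = 1).

## Preprocessing

**Band-pass filtering.** Butterworth band-pass designed in second-order
sections and applied forward–backward (`scipy.signal.sosfiltfilt`), so the
phase response is exactly zero and the effective magnitude response is the
squared single-pass response. The filter order is not prescribed by the
band definitions; the default is 4 (common EEG practice, stable at these
band edges for 256 Hz) and is configurable. Band edges: δ (1, 4), θ (4, 8),
α (8, 14), β (14, 30), γ (30, 50), all (1, 50) Hz; the upper edge must lie
below Nyquist.

**Segmentation.** Each event whose label is in the label scheme yields one
window of P = round(F<sub>s</sub>·T) samples, floor(P/2) before the event
sample and P − floor(P/2) after (half-open interval) — a deterministic
convention for odd and even P, symmetric about the button press. Windows
crossing a recording edge are dropped, not padded: padding would fabricate
data. Same-onset events produce segments in file order.

**Label binarisation.** Only a few example emotions per class are fixed by
the study description ("negative: anger, jealousy, disgust, etc."). The
default scheme assigns the remaining emotions by their usual Russell-
circumplex quadrant: valence-negative {anger, disgust, fear, frustration,
grief, jealousy, sadness}, valence-positive {awe, compassion,
contentedness, excitement, happiness, joy, love, relief}; arousal-high
{anger, awe, disgust, excitement, fear, frustration, happiness, jealousy,
joy, love}, arousal-low {compassion, contentedness, grief, relief,
sadness}. This completion is an interpretation, exposed as an editable
YAML mapping (`load_label_scheme`) rather than hard truth.

## Channel selection

Statistics use **population (divisor-N) moments**, exactly as the defining
formulas are written, not sample-corrected estimators; kurtosis is the
plain fourth standardised moment (Gaussian = 3). Per channel, the samples
of all in-scope segments are **concatenated and scored once** (the
formulas are written over a single signal of length N); this also makes
scores independent of segment order. Two scoping rules exist because the
original protocol is ambiguous about whether test data entered the
statistics: the evaluation harness defaults to `train_only` (statistics
fitted on training folds / training subjects only — methodologically
sound, no leakage), while `all` is available to mirror the permissive
reading.

Ranking is descending by score with ties broken by ascending channel
index; selection is deterministic and idempotent. Degenerate (zero-
variance) channels make skewness/kurtosis undefined and raise an error
naming the channel; with `tolerate_degenerate` they score −∞ and sort
last, which is what the evaluation harness uses.

The **mean statistic is degenerate after band-pass filtering**: every
channel's mean is ≈ 0 and the ranking is numerical noise. It is
implemented as defined, and the acceptance experiment documents that it
recovers planted channels at roughly the chance rate.

## Decoders

**Shallow decoder** (input: one P × K plane per segment):
temporal convolution, 40 filters, kernel 3×1, stride 1, valid (no
padding), no bias → spatial convolution, 40 filters, kernel 1×K over the
full channel axis, no bias → batch normalisation (ε = 1e-5, momentum 0.1)
→ square → average pooling 30×1, stride 4×1, floor mode → log activation →
dropout 0.5 → dense (with bias) → softmax. For P = 512, K = 68: conv
length 510, pooled length ⌊(510−30)/4⌋+1 = 121, dense input 40·121.

Open points resolved as follows:

* The temporal kernel is **3 as specified for this pipeline** (the
  original shallow-decoder lineage uses 25); the kernel is configurable.
* The log activation is floored at ε = 1e-6 so all-zero inputs stay
  finite; its gradient is zero below the floor.
* "Dense / softmax" is read as a single linear layer plus softmax — no
  hidden layer.
* Convolutions carry no bias (batch norm follows); the dense layer does.
* "Negative log likelihood" is applied to log-softmax outputs, i.e.
  standard cross-entropy.
* Inputs are raw microvolt values; no standardisation by default
  (standardisation using train-fold statistics can be added by the caller;
  the pipeline itself feeds raw band-passed segments).

**Deep decoder**: four convolution–max-pool blocks (25/50/100/200
filters, temporal kernel 10×1, max-pool 3×1 stride 3×1, ELU, batch norm,
dropout 0.5 before blocks 2–4 and the head), the first block split into
temporal + spatial convolutions like the shallow decoder.

**Training.** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), learning rate
6.25e-4, batch size 8 (final partial batch kept), NLL loss, a fixed number
of epochs — 150 for valence and 50 for arousal by default — with no early
stopping, schedules, or weight decay (none are part of the recipe). Weight
initialisation (Glorot uniform), per-epoch shuffling, and dropout masks
all derive from the run seed, so a rerun is bit-for-bit identical on the
same platform. The network kernel is a self-contained float64 NumPy
implementation with hand-written backward passes, verified against
finite-difference gradients in the test suite.

**Compute accounting.** The analytic FLOP counter for the temporal +
spatial convolution stage counts 2·k·F·T<sub>out</sub>·C (temporal) +
2·F²·C·T<sub>out</sub> (spatial) multiply-adds; both are linear in C, so
top-K selection reduces that stage's cost by exactly K/C. This is the
mechanism behind the efficiency claim and is asserted without timing
hardware; wall time is recorded in results for context but never used as
a correctness criterion.

## Evaluation

* **Subject-dependent:** stratified 5-fold CV within each subject (the
  80/20 protocol; stratification keeps class balance in small subjects and
  is a documented mild divergence from the unspecified original split).
  Channel statistics are fitted per fold on the training folds only.
  Subjects are evaluated independently and averaged with equal weight;
  subjects with a single class or too few segments are skipped with the
  reason recorded.
* **Subject-independent:** leave-one-subject-out; selection fitted on the
  pooled training subjects of each fold.
* **Metrics:** accuracy and macro-F1 (unweighted mean of per-class F1; a
  class with zero denominator contributes 0). The majority-class rate is
  reported as the chance reference because the emotion classes are
  imbalanced. Mean/SD are recomputable from the per-fold values.
* Per-fold model seeds are spawned deterministically from the run seed
  (`numpy.random.SeedSequence`), so sweeps are comparable across rows and
  reruns are identical. Result CSVs contain no wall-clock fields so rerun
  files are byte-identical.

## Synthetic benchmark

`emodec.synth` generates, per subject: pink-noise background (white noise
shaped to 1/f power in the frequency domain, RMS 10 µV per channel) on 32
channels at 256 Hz, with 80 button-press events on a jittered 4-s grid,
each labelled with an emotion name whose binary mapping encodes the
intended class (balanced). Planted channels (default 8) carry a Gaussian-
windowed oscillatory burst per event: carrier drawn from 30–50 Hz,
duration 0.3–0.8 s, latency jitter ±0.05 s, base amplitude 25 µV;
class-1 events get 1 + `class_effect` (default 0.8, i.e. ×1.8) larger
bursts. Burst duration, latency, carrier, and ±5 % gain are drawn
**independently per planted channel**: electrode sites express the
event-related burst with their own timing and width, and the cross-channel
independence lets a spatial readout average out per-burst power
variability so the class amplitude ratio remains the dominant
discriminative factor (with a shared per-event draw, burst-duration power
variance is common-mode across channels and caps 5-fold CV accuracy well
below what the planted effect supports). Class-neutral background bursts
(rate 0.1 /s per planted channel) keep planted channels heavy-tailed away
from events; they are placed one channel at a time so they barely perturb
spatially averaged power in labelled windows. Per-subject generators are
spawned from the master seed; the planted set is shared across subjects
(as LOSO transfer assumes) unless `shared_planted=False`.

What the generator emulates: the segment/event structure, event-locked
band-limited bursts, heavy-tailed planted channels, 1/f spectra, class
imbalance-free balanced labels, multi-subject transfer. What it does not:
volume conduction and inter-channel correlation, artifacts, non-stationary
background, realistic inter-subject variability, class-imbalanced labels.
Passing tests therefore demonstrate that the implementation realises the
method's mechanisms (recovery, band specificity, compute reduction,
learnability), not that comparable accuracies would be reached on real
recordings.

## Problem sizes and defaults used in verification

The test suite and acceptance script run at desk scale, chosen so the
full suite completes in minutes on one CPU: one to three synthetic
subjects, 32 channels / 8 planted, 80 segments per subject, K = 8, and
epoch budgets of 10–20 (10 for LOSO and null runs, 20 for the headline
subject-dependent run — the fixed 150/50-epoch budgets are the package
defaults for full-scale runs). The `emodec run` default K (68 for
valence, 90 for arousal) is capped at the available channel count when
the recording has fewer channels; an explicitly requested K larger than C
fails fast before any training.

## Known limitations

* EDF/BDF support covers plain continuous recordings (integer sampling
  rates, uniform per-channel rate, no EDF+ annotation channels); a
  trailing partial second is zero-padded on write.
* The mean-statistic ranking on band-passed data is noise (see above) —
  kept for fidelity, documented as degenerate.
* Training runtime is CPU-bound NumPy; fine at desk scale, not meant for
  246-channel, 150-epoch production runs.
* The label mapping for emotions beyond the documented examples is an
  interpretation; swap in your own YAML scheme for other conventions.
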