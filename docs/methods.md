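# Methods

`erpdecode` implements a complete single-trial ERP group-decoding pipeline:
a synthetic cohort generator with known ground truth, the standard
preprocessing chain, a compact depthwise-separable CNN classifier trained
and evaluated subject-wise, exact binomial chance-level statistics, and
gradient saliency attribution. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Synthetic cohort model

One trial of subject *s* in group *g* is

```
x(c, t) = Σ_i  a_i(s) · g_i(c) · exp( −(t − μ_i(s) − δ(trial))² / 2σ_i² )  +  ε(c, t)
```

* **Components.** Each ERP deflection is a Gaussian in time (latency μ in
  ms, width σ in ms, signed amplitude in µV) with a per-channel topography
  `g_i(c) ∈ [−1, 1]` built as a Gaussian falloff in great-circle distance
  from a focal electrode. The default component set mimics a visual
  stimulus-locked response: P1 (110 ms, occipital), N1 (170 ms,
  parieto-occipital), P2 (240 ms, parietal), a late parietal positivity
  (420 ms) and a slow fronto-central negativity (preparation/timing,
  ~1100 ms). Amplitudes sit at the upper (pediatric) end of the range —
  visual P1/N1 are markedly larger in children than adults.
* **Group effects** enter as amplitude scaling (and, if desired, topography
  or latency changes) of selected components. A per-subject Bernoulli
  "effect-carrier" flag with configurable probability reproduces the
  empirical situation that only part of a patient cohort expresses a
  decodable effect; non-carriers receive the control template.
* **Subject and trial variability.** Per subject, each component's
  amplitude is scaled by `1 + N(0, amplitude_jitter)` and its latency
  shifted by `N(0, latency_jitter)`; per trial all components shift
  jointly by `N(0, trial_latency_jitter)`. Full-scale defaults: 15%
  amplitude, 10 ms subject latency, 5 ms trial latency.
* **Noise** is Gaussian with a 1/f^α amplitude spectrum (spectral shaping
  of white noise, DC removed), scaled to `noise_sd` RMS per channel;
  defaults α = 1, 10 µV — typical for band-limited pediatric EEG
  background. Channels are independent: the generator does *not* model
  volume conduction, ocular/muscle artifacts (beyond the synthetic
  rejection fixtures), or non-stationarity. Passing tests therefore show
  pipeline correctness and calibration, not expected real-data accuracy.
* Trial counts are drawn per subject from round(N(235, 50)), clipped below
  at 50 so per-subject binomial thresholds stay well-defined. Identical
  configuration (including the seed) reproduces the cohort bit for bit.

Artifact injection adds, to a chosen fraction of trials, one of: an
amplitude spike beyond ±200 µV, a >200 µV step, or a flattened (<0.5 µV
peak-to-peak) stretch of ≥100 ms — each designed to trip exactly one
rejection rule.

## Preprocessing

Order: band-pass filter → baseline correction → artifact rejection →
(optional) CSD. Rejection operates on whole trials; all other stages
preserve shape.

* **Band-pass 0.5–20 Hz**: 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`), i.e. zero phase and an effective 48 dB/oct roll-off
  (double the one-pass 24 dB/oct). Zero phase matters: ERP component
  latencies must not shift.
* **Baseline**: per trial and channel, subtract the mean of −200…0 ms.
  Idempotent by construction.
* **Rejection** (per channel, trial-level exclusion): amplitude outside
  ±200 µV; max-minus-min above 200 µV within any sliding 200-ms window;
  max-minus-min below 0.5 µV within any sliding 100-ms window. Windows
  advance sample-by-sample and must fit entirely inside the epoch. The log
  records the first violated rule (amplitude → gradient → low-activity)
  and the lowest offending channel. Thresholds apply in the µV domain,
  before CSD.
* **CSD**: Perrin-style spherical-spline surface Laplacian. G and H
  matrices from Legendre expansions of inter-electrode cosine distances
  (order m = 4, 50 terms, the method's conventional defaults), Tikhonov
  regularization λ = 1e−5 on G's diagonal, spline coefficients solved per
  time sample under a zero-sum constraint, output scaled by 1/r² with head
  radius r = 0.1 m → µV/m². The operator is linear, annihilates
  channel-constant potentials, and matches MNE-Python's implementation to
  machine precision (cross-checked in the test suite).

Electrode geometry is an idealized spherical 10-10 montage constructed by
rule (18° arc steps from the vertex), not digitized positions; a
56-electrode 10-10 subset (full scale) and the 19-electrode 10-20 montage
(benchmark) ship as `.sfp` files and as code.

## Classifier

EEGNet-family compact CNN for input `(C, T)`:
temporal convolution (F1 = 4 filters, width 64 samples at 500 Hz, "same"
padding, linear, no bias) → batch-norm → depthwise spatial convolution
over all C electrodes (D = 2 filters per temporal filter, no bias) →
batch-norm → ELU → average-pool 4 → dropout 0.25 → separable convolution
(depthwise width 16 + pointwise, linear) → batch-norm → ELU → average-pool
8 → dropout → dense softmax head. Block 1's output shape is
(F1·D, 1, T/4). A second variant ("table") with two separable stages and
pooling 4+4 is available behind a flag; the single-separable-block variant
is the tested default. Max-norm constraints are not used. ELU α = 1;
batch-norm ε = 1e−5, momentum 0.1 (biased batch variance); biases only in
the dense head, matching the closed-form parameter-count formulas
(temporal: 64·F1; spatial: C·F1·D; 2 per batch-norm feature map).

The network, backpropagation, Adam, and the input-gradient path are
implemented in NumPy (float32), with numba-JIT inner loops for the two
convolutions and a pure-NumPy fallback; both paths are tested for
agreement, and all gradients are verified against central differences in
float64. Inference is deterministic; training is deterministic given the
seed (initialization, shuffling and dropout all derive from one

generator).

## Training and evaluation

Leave-one-subject-out (LOOS): one fold per subject; all of that subject's
trials form the test set. From the remaining subjects, 4 per group are
drawn at random as validation subjects (reduced to
min(4, max(1, remaining//3)) only when a group is too small). Training
minimizes class-weighted cross-entropy (weight = majority count / class
count, majority = 1, recomputed per fold from training trials only) with
Adam, batch size 32. After every epoch the unweighted validation
cross-entropy is computed in inference mode; the checkpoint with the
lowest validation loss (earliest epoch on ties) is evaluated on the test
subject. Accuracy is percent correct over the subject's trials; argmax
ties resolve to the lowest class index. The cohort summary is the mean ±
SD over per-subject accuracies. Full-scale defaults: 500 epochs, Adam
1e−3. Follow-up analyses on the well-classified subset (e.g. two-class
runs restricted to subjects above their threshold) are performed by
re-running `run_loos` on the filtered recording list — i.e. models are
retrained on the subsample rather than reusing the full-cohort models;
both usages are compositional calls of the same functions.

## Chance-level statistics

Under guessing, correct counts are Binomial(n, 1/c); the significance
threshold is `100/n · min{ k : CDF(k) ≥ 1 − α }` with α = 0.05 — the exact
inverse CDF (no normal approximation), computed via the regularized
incomplete beta function and verified against explicit summation for all
n ≤ 500 in the tests. A subject is *well classified* iff accuracy is
strictly above its own threshold. Averaged over trial counts drawn from
N(235, 50), the two-class threshold is ≈55.5% — this is the quantity
`scripts/acceptance.py` recomputes. α = 0.05 is forced numerically: at
n ≈ 235 it yields the ≈55.5% mean two-class threshold, whereas α = 0.01
would give ≈57.4%. Group accuracy distributions are compared with the
tie-corrected Kruskal–Wallis H (χ² p-values; the all-identical degenerate
case returns H = 0, p = 1). Sensitivity/specificity take the patient
group as positive (clinical convention).

## Saliency

The saliency map of a trial is ∂(pre-softmax score of a class)/∂(input),
evaluated in inference mode — exactly the same (C, T) shape as the trial.
Group maps average the per-trial gradients of the class of each trial's
own group (signed by default; an absolute-value option exists) and are
min-max normalized to [0, 1]; a constant map degenerates to all zeros
rather than dividing by zero. Feature ranking sums relevance in sliding
per-channel windows and returns the top-k non-overlapping (channel,
window) pairs with deterministic tie-breaking. Localization is quantified
as the enrichment of top-decile relevance mass inside the known injected
(channel × time) region relative to the region's share of the map.

## Desk-scale benchmark

Full-scale conditions (56 channels, 500 Hz, ~235 trials/subject, 500
epochs) are impractical for routine CPU testing. The standard benchmark
(module `erpdecode.benchmark`) is a faithful scale-down chosen as the
package's reference test bed:

| quantity | full scale | benchmark |
|---|---|---|
| montage | 56-ch 10-10 subset | 19-ch 10-20 |
| sampling rate | 500 Hz | 125 Hz (T = 400 over −200…3000 ms) |
| temporal kernel | 64 samples (128 ms) | 16 samples (128 ms) |
| trials/subject | ~235 ± 50 | 80 |
| subjects/group | ~44–52 | 10 |
| epochs / Adam lr | 500 / 1e−3 | 30 / 4e−3 |
| subject jitter | 15% amp, 10 ms | 8% amp, 5 ms |

The kernel keeps its physical 128-ms width. The larger Adam step
compensates the 17× shorter schedule and was selected by validation
cross-entropy (1e−3 demonstrably underfits in 30 epochs; kernels 32/48
and smaller dropout were also rejected by validation loss). The benchmark
keeps subject-level variability moderate because, with carrier fraction
1.0, it is defined as the favorable regime that isolates the group
effect; subject heterogeneity and unclassifiable subjects are exercised
through the carrier fraction instead. Two cohorts are standard: a
three-group *null* cohort (identical templates; decoding must calibrate
to 33.3% chance) and a two-group *effect* cohort (patients express a 30%
amplitude reduction of P1/N1/P2 over parietal/occipital sites in
100–250 ms; every patient a carrier).

The null cohort is deliberately *sharp*: subject-level jitter is
disabled so trials are iid across subjects and the binomial-threshold
assumptions hold at the trial level — the configuration that detects
pipeline leakage. The null calibration runs (06_null_calibration.py and
the acceptance suite) produce an instructive negative result about the
per-subject binomial chance test itself. The mean LOOS accuracy stays
within Monte-Carlo error of the 33.3% chance level — no information
leak. But the fraction of null subjects whose accuracy exceeds their
α = 0.05 binomial threshold lands far above α (roughly one third):
under the null, the checkpoints selected by validation cross-entropy
emit near-tied class probabilities, and the argmax decision amplifies
small fixed logit offsets into strongly non-uniform per-fold prediction
marginals. A subject's accuracy equals its fold's marginal on its own
group, so per-subject accuracies spread far beyond Binomial(n, 1/c)
even with iid trials. Class weighting interacts with this: without
weights the held-out subject's class (slightly fewer training trials)
is systematically avoided; the inverse-proportion weights overcorrect
the early-epoch transient. The effect shrinks with cohort size —
removing one subject at full scale shifts class proportions by only
~2% — but at desk scale it makes the per-subject binomial threshold
markedly anticonservative. Subject-level jitter (idiosyncratic
templates correlating each subject's predictions) makes the
miscalibration worse still; both findings are caveats that apply
directly to per-subject chance thresholds on clinical recordings.
Benchmark preprocessing applies
filter → baseline → rejection but not CSD: with channel-independent
noise and no volume conduction, the spatial high-pass of the Laplacian
only removes smooth signal.

At these conditions the matched-filter (template-oracle) single-trial
accuracy is ≈73%; the trained classifier reaches a pooled validation
accuracy of ≈69% and a LOOS mean of ≈66% with ~80% of subjects above
their binomial threshold — i.e. close to the information limit of the
simulated data, with the remaining gap attributable to subject-level
amplitude/latency jitter.

## Known limitations

* No volume conduction, channel covariance, ocular/pulse sources, or
  non-stationary noise in the generator; CSD and rejection are therefore
  exercised on stylized data.
* Electrode coordinates are idealized spherical positions.
* The benchmark's accuracy figures characterize the simulator's regime,
  not clinical decodability.
* Source localization of salient features is out of scope.
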