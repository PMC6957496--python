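# Methods

## Signal model and the synthetic generator

Beats are synthesized analytically as sums of Gaussian deflections. The
equine template carries a small P, a small r, a dominant negative S trough
(−1.2 mV), a terminal positive deflection and a tall T (0.55 mV, σ = 55 ms);
the human template the familiar P-QRS-T with a dominant +1.0 mV R wave.
`tall_t_equine_template` sharpens and raises the T (1.0 mV, σ = 30 ms) to
the peaked near-QRS-amplitude form some base-apex recordings show; this is
the morphology on which amplitude-based detectors fail. Ventricular ectopics
(VPC) widen the QRS by 1.6× and invert the dominant deflection with a
discordant T; atrial ectopics (APC) keep the normal morphology and differ
only by timing — both mirror the clinical definitions of the four classes.
Artefact (A) events are high-amplitude (1.6× the QRS peak) white-noise
bursts under a 25 ms Gaussian envelope, placed off-rhythm with ≥ 180 ms
clearance from beats; nothing in the source material characterizes artefact
morphology, so this burst model is our stand-in.

Rhythm is a jittered renewal process: normal RR intervals are
`(60/HR)·(1 + 0.03·ε)` with truncated-normal ε; an ectopic arrives after
`(1 − prematurity)·RR·U(0.85, 0.93)`, strictly satisfying
"preceding RR < (1 − prematurity) × running-mean RR"; a VPC is followed by a
full compensatory pause (the surrounding intervals sum to 2 RR), an APC
resets the rhythm. Default prematurity is 0.25 (APC) and 0.30 (VPC). Event
rates are per minute and converted to per-beat probabilities. Heart rate is
validated to [20, 240] bpm — horses span this entire range. Records are
2-lead (lead II at full amplitude, lead I a 0.55× projection), 500 Hz, with
annotations at the dominant-peak sample.

Noise presets: `clean` (nothing), `clinic` (0.15 mV wander at 0.25 Hz +
0.02 mV white noise — breathing and electrode noise at rest), `exercise`
(0.40 mV at 0.35 Hz + 0.05 mV). Baseline wander frequency is constrained
below 1 Hz. All randomness flows from one integer seed; identical seeds give
bit-identical records.

What the generator does *not* emulate: electrode motion steps, muscle-tremor
(EMG) noise with QRS-like spectra, atrial fibrillation and other sustained
arrhythmias, rate drift within a record, and real morphological variability
between horses. Detector and classifier scores on these records therefore
demonstrate correctness of the algorithms under controlled conditions, not
clinical performance.

## Filtering

Baseline estimation is the dual median cascade (200 ms then 600 ms windows,
window length `round(width·rate)` forced odd, reflect padding); the second
median's output is the baseline and is subtracted, so the operation is exact
on constants and adding a constant to the input leaves the output unchanged.
Denoising decomposes with a 4-level DWT (level capped by signal length) and
soft-thresholds every detail level at the universal threshold
`σ·sqrt(2·ln n)`, with σ the MAD/0.6745 of the finest detail level. Two
wavelets are named for this step in the source description — Coiflet-2 and
Daubechies-8 — and the threshold is unspecified; we default to db8 (the one
cited as best suited to ECG denoising) with coif2 selectable, and expose
`universal_soft`, `universal_hard` and `fixed:<v>` threshold rules. A fixed
threshold of 0 reconstructs the input exactly.

## S-peak detection

Detection operates on cd4², the squared SWT detail coefficients at scale 4
(Symlet 4). At 500 Hz this band (~16–31 Hz) brackets QRS energy and
attenuates P and T waves. The input is reflect-padded to a multiple of
2⁴ for the SWT and cropped after. "Relative maxima" are strict local maxima
with ≥ 10 ms separation (plateau guard). Every maximum — accepted or not —
enters a rolling 200-element history, and the threshold in effect is
`1.25 × mean(history)`, exactly `(1.25/200)·Σ` once the history is full.
A suprathreshold maximum opens a 200 ms refractory span; among suprathreshold
maxima inside it the largest is selected, and the next acceptance must fall
more than one span after it.

Two points are underdetermined by the published description and resolved
here as follows. *Warm-up*: before 200 maxima exist the threshold uses the
mean of the available history, which is seeded with a single value — half
the largest cd4² of the opening two seconds, the scale a QRS maximum is
expected to have. (Seeding with the raw global maximum would put the initial
threshold at 1.25× the first QRS's own energy and make the opening beats
undetectable.) *Refinement*: accepted coefficient maxima are mapped to the
physical peak as the extremum of the filtered signal within ±40 ms. The
default polarity is `abs` (largest deflection of either sign) rather than
species-fixed, because ventricular ectopics invert the dominant deflection;
pinning the S trough or R peak is available via configuration. Refinement
can pull two accepted peaks together, so the refractory rule is re-imposed
afterwards, keeping the larger deflection.

The Pan-Tompkins baseline is the classic chain — 5–15 Hz band-pass,
five-point derivative, squaring, 150 ms moving-window integration, adaptive
dual thresholds (SPKI/NPKI with `NPKI + 0.25·(SPKI − NPKI)`), 200 ms
refractory — without T-wave slope discrimination or search-back. Detection
scoring is greedy one-to-one matching of sorted index lists at a 50 ms
tolerance (no tolerance is stated for the original manual check; 50 ms is a
common beat-matching window).

## Beat dataset

Morphology windows are `[peak − 0.5 s, peak + 0.5 s)` on both leads
(2×500 at 500 Hz); the timing vector marks every detection within ±10 s,
subsampled by `i → floor(i/5)` to 100 Hz (2000 samples, centre element 1;
bin collisions keep a single 1). Both published input sizes (2×500/2000 and
2×512/2048) appear in the source; 500/2000 follow exactly from the stated
spans and rates and are canonical here, with 512/2048 available as
symmetrically zero-padded variants. Windows crossing record edges are
zero-padded. Splitting is a seeded random partition by beat (default
60/20/20). Median resampling computes the per-class target as the median of
the class counts (mean of the two middle counts for the even class number,
rounded to nearest), under-samples without replacement and over-samples with
replacement. Labels for detected beats come from reference annotations
matched at 50 ms; unmatched detections default to the artefact class.

## The parallel classifier

Input widths W = 500 (per lead) and T = 2000. Each morphology path is two
blocks of [conv → batch-norm → ReLU → dropout]; kernels span
`2·convolution_width` samples with `subsampling` stride and same-padding,
applied per lead (leads are folded into the batch axis, so no cross-lead
mixing occurs before the dense stage). A residual shortcut max-pools the
path input by the product of the two strides (ceil mode, so lengths always
agree) and passes through a 1×1 convolution to match channels before
element-wise addition — the merge operation is not specified in the source;
addition after 1×1 projection is standard residual practice. The timing path
is two 1D conv + dropout layers, without batch-norm, residual or ReLU. The
two morphology paths are flattened, concatenated and share one dense layer
(+ReLU); the timing path gets its own dense (+ReLU); their concatenation
passes through a final dense (+ReLU) into a 4-class softmax. Dropout
fraction 0.2, L2 0.001 on conv/dense kernels, Adam at 1e-4 with batch 500
and 20 epochs are the training defaults; the GA inner loop uses 50 epochs
with patience 3 on training accuracy. Weights use He initialization from a
recorded seed. Two architecture presets reproduce the published
GA-optimized layer tables for the human and equine datasets.

Transfer learning: `full_finetune` continues training every weight from the
source model; `freeze_features` sets every conv and batch-norm layer
non-trainable — frozen batch-norm also runs in inference mode, so running
statistics stay bit-identical, and the serialized feature-extractor bytes
are unchanged by training. Ensembles take per-input majority votes; ties go
to the tied label with the highest mean softmax probability.

The engine is numpy throughout (im2col convolutions via
`sliding_window_view`, explicit backward passes, Adam with bias correction).
This makes training exactly reproducible from a seed on any platform, at the
cost of speed — which is why the shipped smoke tests train 200-sample toy
sets rather than full corpora.

## Architecture search

NSGA-II with simulated binary crossover (η = 15, p = 0.9) and polynomial
mutation (η = 20, p = 1/n_genes). Genes: per conv block, log2-spaced integer
subsampling and filters (the published tables are powers of two) and linear
integer convolution width; log2 dense width; log10 L2; linear dropout.
Default bounds (subsampling [1, 32], width [5, 300], filters [4, 64], dense
[32, 1024]) envelope all published rows. Fitness is validation accuracy;
un-buildable genomes score 0; a cache keyed on the decoded architecture
prevents retraining identical genomes. Accuracy is the single stated
objective; parameter count can be enabled as a second minimized objective
(`minimize_size`), off by default. Survival is elitist (μ+λ over the
combined pool), so generation-best fitness is non-decreasing.

## Metrics

Per class, one-vs-rest: TP is the diagonal entry, FP/FN the column/row
remainders, TN the rest; recall, PPV and F1 follow the standard formulas;
overall accuracy is trace/total (the multi-class reading of the binary
accuracy formula, and identical to micro-averaged recall). Macro averages
are unweighted class means; a class absent from truth (or never predicted)
has undefined recall (or PPV), reported as absent and excluded from the
macro average. Replicate-training reports are averaged element-wise.
Percentages print to one decimal.

## Test and acceptance problem sizes

Chosen so the full suite and the acceptance script each run in minutes on
one CPU: detector quality uses ten 2-minute clinic-preset records at
40–76 bpm with 2 APC/min, 2 VPC/min and 1 artefact/min; the refractory fuzz
uses one hundred 10 s records over 30–230 bpm and all noise presets;
smoke training uses 200-sample toy sets with the equine architecture preset,
20 epochs, batch 20. The timing-ablation effect is measured as APC recall on
a held-out draw of the timing-only-separable set, because on the training
draw a large network can memorize per-sample noise and mask the ablation;
that set also makes N twice as frequent as APC (as in real rhythm strips),
so a morphology-only model's optimum resolves the N/APC ambiguity to N
rather than arbitrarily dumping it into APC, which would inflate APC recall
without any real discrimination.
Unit tests for training mechanics use a miniature architecture (inputs
40/80) whose gradients were verified against central differences.

## Known limitations

- The WFDB reader covers headers, signal formats 16 and 212 and MIT `.atr`
  annotations — enough for the common arrhythmia corpora — not multi-segment
  records or other signal formats.
- Pan-Tompkins omits search-back and T-discrimination, matching the classic
  core rather than any specific production implementation.
- The numpy engine trains small corpora in minutes but is not suited to
  full-scale corpus training; published full-corpus accuracies are out of
  desk-scale reach and are not claimed by the test suite.
- The GA defaults (population 20, 10 generations) reproduce the published
  search shape; tests exercise reduced searches (population 4, 2–3
  generations) for runtime.
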