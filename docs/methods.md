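# Methods

`semgbench` is a benchmark pipeline for six-class hand-gesture recognition
from low-channel surface electromyography (sEMG). It covers synthetic data
generation, the preprocessing stack, two classifiers — a classical
convolutional network and a conv-stem Transformer — a subject-specific
training protocol, the metric suite, and a paired statistical comparison
battery. This note records the models, assumptions, parameter choices and
their rationale, and what the synthetic experiments do and do not show.

## Signal model of the synthetic generator

Surface EMG at a bipolar electrode is the interference pattern of many
motor-unit action-potential trains; at normal contraction levels it is well
approximated by amplitude-modulated colored Gaussian noise. The generator
draws zero-mean white Gaussian noise per channel, shapes it with a 4th-order
low-pass Butterworth filter at fs/4 (sEMG power concentrates in the lower
half of the recordable band), and modulates its amplitude with a trapezoidal
activation envelope per gesture segment (10% rise, 10% fall) so contractions
ramp rather than switch.

Class identity is encoded purely in the per-channel RMS pattern: subject s
has a gain matrix G[c, j] ≥ 0 (classes × channels) and during a gesture-c
segment the steady-state RMS of channel j is

    RMS(c, j) = baseline_rms · (1 + snr · G[c, j]),

with `snr` the ratio of gesture-driven RMS excess to baseline. Rest (class
0) carries gain 0 on every channel, so rest segments sit exactly at the
baseline RMS regardless of snr, and `snr = 0` removes all class information
(every class then has identical statistics). The cohort template gives each
gesture a smooth channel-activation bump centred on a class-specific
channel, with a 0.3 floor so every channel stays mildly active; per-subject
gains multiply the template by lognormal factors with multiplicative spread
`variability` (default 0.15), emulating inter-subject variability in
electrode placement and musculature. A *degenerate* subject mode collapses
all gesture rows to their mean: gestures become mutually indistinguishable
while rest remains separable by amplitude — the profile of a participant
with no residual forearm musculature, whose classifier accuracy lands near
1/3 on balanced six-class data (rest recognized, the five gestures at
chance) rather than 1/6.

Timeline: each repetition r contributes one contiguous rest run followed by
one contiguous run per gesture class, so every requested (class,
repetition) pair is exactly one run and repetition-based splits are
well-defined. Defaults are 6 repetitions, 5 s gestures, 3 s rests, all
configurable. Amplitude units are arbitrary; no attempt is made to mimic
device ADC ranges, since the pipeline standardizes amplitudes anyway.

What the generator does **not** emulate: motor-unit discharge structure,
inter-channel correlation, class-dependent spectral content, electrode
shift, fatigue, or session-to-session drift. Synthetic realism is limited
to class-dependent RMS structure by design, so a passing recovery test
shows that the pipeline can extract amplitude-coded class structure end to
end — it does not certify accuracy on real recordings.

## Preprocessing

* **Per-class standardization.** x′ = (x − μ[c, j]) / σ[c, j] with
  class-and-channel-conditional statistics (population SD). Statistics are
  always fitted on training data and applied as a fixed transform
  (fit/transform split) so no test information leaks into the scaling.
* **Protocol default: class-agnostic scaling.** The training protocol uses
  per-channel *global* statistics instead of class-conditional ones, for
  two reasons: a class-conditional transform cannot be applied to unlabeled
  test data, and on amplitude-coded signals it provably removes all class
  information (every class–channel pair is scaled to unit variance, which
  is exactly the discriminative statistic here; empirically both
  classifiers drop to chance). The class-conditional operation remains
  available (`PipelineOptions(per_class_standardization=True)`) and fully
  tested.
* **µ-law companding.** F(x) = sign(x) ln(1 + µ|x|) / ln(1 + µ) on [−1, 1];
  odd, strictly monotone, fixes 0 and ±1. µ defaults to 255, the classic
  telephony companding constant. Channels are rescaled by their
  training-set max |x| before companding (test values beyond the training
  scale are clipped to ±1 so the domain holds). Off by default in the
  Myo-style pipeline; available for the DB3-style one.
* **Butterworth cascade.** The same signal low-passed at orders 1, 3, 5
  (zero-phase forward–backward filtering, unit DC gain), stacked into a
  3-deep representation. The cutoff is configurable (default fs/4, the
  generator's own band edge). The cascade is exposed as a standalone
  operation and is not wired into the training protocol by default: the
  classifiers consume depth-1 inputs, and reconciling a 3-deep
  representation with a depth-1 input layer is left to the caller.
* **Windowing.** Class-pure sliding windows of W samples with overlap O
  (stride W − O): 30/15 at 200 Hz (~150 ms) for the Myo profile, 50/15 at
  2 kHz (~25 ms) for the DB3 profile. Windows are aligned within each
  maximal (label, repetition) run (first window at the run start, 0-based,
  half-open), so a run of length L ≥ W yields exactly
  ⌊(L − W)/(W − O)⌋ + 1 windows and no window straddles a label or
  repetition boundary.
* **Balancing.** Seeded downsampling without replacement to the minimum
  class count, then a seeded reshuffle. Balancing precedes the
  train/test split, so both sides stay (approximately) balanced.
* **Repetition splits.** Six canonical train/test partitions by stimulus
  repetition; split 1 ({1,3,4,6} / {2,5}) is the default. Split 5, kept
  verbatim from the benchmark's legacy tabulation, lists repetition 6 on
  both sides; the validator refuses overlapping splits rather than
  guessing the intended set.

## Classifiers

Both models consume (channels × W × 1) windows and end in a softmax over
six classes.

**CNN** (channels × time, NHWC): conv 32@1×12 valid → conv 32@3×3 valid →
avg-pool 2×2 → conv 64@5×5 same → avg-pool 2×2 → conv 64@9×1 same (ReLU
after every conv) → flatten → dense 6 softmax. Average pooling uses floor
division without padding — the convention under which the CNN-Myo total
is exactly 99,398 and the stem token counts come out as below. On the 8×30×1 Myo input the shape chain is
(8,19) → (6,17) → (3,8) → (3,8) → (1,4) → (1,4) with depth 64.

**Conv-stem Transformer (CViT).** The CNN truncated before flatten is the
patch extractor: each spatial position of the stem output (depth 64) is one
patch, linearly projected to d = 64. A learnable class token is prepended
(sequence lengths: 4 + 1 = 5 for Myo, 18 + 1 = 19 for DB3) and learnable
positional embeddings — class token included, standard practice — are
added. Four pre-norm encoder layers follow: LayerNorm → 8-head
self-attention → residual → LayerNorm → MLP (256 hidden, GELU, dropout
0.1) → residual. The per-head width is d/h = 8 and enters the 1/√d_k
attention temperature; a 64-wide per-head key with 8 heads would more than
double the encoder size, inconsistent with a compact low-channel model.
The class token, after a final LayerNorm, feeds a GELU dense head (width
128 — the head width is a free choice, configurable) with dropout, then the
softmax layer. Total trainable parameters with these conventions: 311,558
(Myo) / 312,454 (DB3), dominated by the stem (97,856) and the four encoder
layers (49,984 each).

**Numerics.** No deep-learning framework is used: the package ships a
small reverse-mode autodiff engine over numpy (`semgbench.nn`) providing
broadcast arithmetic, batched matmul, im2col-based convolution, floor-mode
average pooling, softmax, exact erf-based GELU, LayerNorm composition, and
a fused softmax-cross-entropy. Every primitive's gradient is checked
against central finite differences in the test suite. Initialization is
Glorot-uniform for conv/dense kernels, zeros for biases, truncated normal
(σ = 0.02) for class/positional tokens; all randomness (weights, dropout,
batch order, balancing, fold assignment) flows from explicit seeds, so a
run is bit-reproducible.

## Training protocol

Per model: CNN — SGD (lr 0.001, momentum 0.9), batch 15, ≤100 epochs;
CViT — Adam (lr 0.001), batch 32, ≤200 epochs. Both use categorical
cross-entropy, early stopping on validation loss (patience 15),
reduce-on-plateau (factor 0.5, patience 7, floor 1e-5 — the reduction
schedule is not pinned by the source protocol and is configurable), and
best-validation checkpointing: reported metrics always come from the
minimum-validation-loss epoch.

The subject-specific protocol runs `n_experiments` (default 14)
independently seeded repetitions of: segment → balance → split by
repetition → standardize (fit on train) → carve one stratified validation
fold (of k = 5) out of the train windows, rotating the fold with the
experiment index → train → evaluate once on the held-out repetitions.
Stratified folds serve validation/early stopping only; the test metric
always comes from the held-out repetitions, which never reach the
optimizer (asserted from repetition provenance tags). Aggregates are
mean ± sample SD with the normal-quantile 95% CI, x̄ ± 1.96·s/√n, n =
number of experiments.

## Metrics and statistics

Accuracy, per-class precision/recall/F1 from one-vs-rest counts on the 6×6
confusion matrix, macro (equal-weight) and weighted (support-weight)
aggregates. A class never predicted gets precision 0 and a flag rather
than being dropped, keeping macro averages defined on degenerate subjects.
Confusion matrices are also exposed row-normalized.

The paired battery: Student t = d̄/(s_d/√n) with n−1 df (two-sided);
Wilcoxon signed-rank with W the smaller signed-rank sum, zero differences
dropped (Wilcoxon's original rule, drop count reported), exact two-sided p
by full 2^n enumeration on average ranks for n ≤ 15 and the
tie-corrected normal approximation beyond; Friedman
χ²_F = [12n/(k(k+1))]·Σ(R̄_j − (k+1)/2)² on a complete subjects×models
matrix (incomplete matrices are refused — cohorts must be aligned before a
joint test); Nemenyi post hoc via the studentized-range distribution with
CD = q_α·√(k(k+1)/(6n)) (k ≥ 3; with two models pairwise Wilcoxon applies
instead); effect sizes Cohen's d = d̄/s_d (paired form; a pooled-SD variant
is available by flag) and Wilcoxon r = Z/√n signed by the median
difference; Bonferroni α_adj = α/m, adjusted p = min(1, m·p), with m
required to cover the whole hypothesis family.

## Problem sizes used by the test and acceptance runs

The recovery experiments run on a 3-subject Myo-profile cohort with 6
repetitions of 1.5 s gestures and 1.5 s rests (≈ 300 balanced windows per
subject after the split), two seeded experiments per subject and model,
plus single-experiment runs at snr 0 and 1 for the chance-level and
monotonicity checks. These sizes are the package's choice for a compact,
fully reproducible synthetic benchmark; the generator defaults (5 s / 3 s)
describe the full-scale study conditions.

## Known limitations

* Class information in the synthetic data is amplitude-only; results do
  not transfer to claims about waveform- or spectrum-coded gestures.
* The CViT parameter total depends on head-width and head-count
  conventions that admit alternatives; the counts above are exact for this
  implementation but are not a universal constant of the architecture.
* The Friedman/Nemenyi path requires complete cohorts; comparing models
  evaluated on different subject sets requires intersecting the cohorts
  first.
* Training is CPU-bound numpy; it is sized for low-channel short-window
  problems, not for high-density sEMG.
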