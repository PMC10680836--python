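# Methods

## Overview

`nanonascent` detects 5-ethynyl-uridine (5EU) incorporation in individual
direct-RNA nanopore reads from the raw current trace alone, and derives RNA
kinetics from the per-read calls. This note documents the model and its
assumptions, the synthetic-data generator, the numerical choices, and the
limits of what the package's own tests demonstrate.

## Preprocessing

Each read's raw trace is processed as:

1. **Length filter** (pre-crop): reads with ≤ 5,000 or > 400,000 raw samples
   are discarded. The lower bound is exclusive because the subsequent crop
   removes exactly 5,000 samples; a read of exactly 5,000 samples would be
   empty afterwards.
2. **Head crop**: the first 5,000 samples are removed (sequencing-start
   artifacts such as adapter and stall signal).
3. **med-MAD normalisation**: `x ← (x − median(x)) / median(|x − median(x)|)`.
   The plain MAD is used, with no Gaussian consistency constant (no ×1.4826).
   The transform is invariant to positive affine rescaling, so whether the
   container stores DAC integers or picoamperes cannot change the classifier
   input; the constant's convention is likewise immaterial as long as it is
   consistent between training and inference. Signals with MAD = 0 are
   degenerate; the policy is to drop the read with a warning (at inference
   they appear in the skipped list with a reason code).

## Classifier

Three 1-D convolution blocks (channels 1→16→32→64, kernel 5, stride 3, batch
norm, ReLU) reduce the sampling rate by 27× while extracting local signal
shapes; a bidirectional GRU (hidden 48 per direction) integrates information
across the whole read; the variable-length GRU output is collapsed to a
fixed 288-vector by concatenating max-pool over time, mean-pool over time,
and the final forward and backward hidden states; a dense head (288→70→1)
with a sigmoid emits the per-read probability of 5EU labeling. There is no
padding anywhere: every read is processed at its own length (minimum 53
samples after cropping, the shortest input for which all three conv outputs
are nonempty). The reference configuration totals 66,349 trainable
parameters under the two-bias GRU convention (66,061 if the two recurrent
bias vectors per direction are fused), i.e. ≈ 66k.

Choices made where the design was genuinely open:

- **Layer sizes** are pinned to the reference configuration above so that the
  parameter budget is reproducible; all sizes remain configurable through
  `ClassifierConfig`.
- **Input features**: a single channel (the normalised current). No dwell,
  basecall or alignment features are used, keeping inference independent of
  external software.
- **Batch norm with batch size 1**: statistics across examples are undefined,
  so training mode normalises each channel over the *time* axis of the
  current sequence and maintains running statistics (momentum 0.1, biased
  variance) for evaluation.
- **No dropout** in the reference configuration.
- Output head uses a sigmoid with binary cross-entropy loss.

### Implementation

The network, backpropagation and AdamW live in `nanonascent.nn`, a small
numpy engine written for single-sequence, variable-length work; the GRU
recurrence loops are numba-JIT-compiled with a pure-numpy fallback. Every
backward pass is checked against central-difference numerical gradients in
`tests/test_nn.py` (relative tolerance 1e-4), and gradient accumulation is
verified to be exactly additive.

## Training protocol

- **Chromosome holdout**: reads mapping to chr1 are test-only and chr20
  validation-only (these defaults are configurable via `SplitRule`);
  unmapped and secondary reads are excluded. The split is computed from an
  externally produced read table (read_id, chromosome, is_secondary) — the
  aligner itself is out of scope.
- **Balanced sampling**: positives and negatives are drawn 1:1; multiple
  negative sources are sampled proportionally to their read counts.
- **Optimisation**: AdamW, lr 0.001, weight decay 0.01 (decoupled, applied
  to all parameters), batch size 1 with gradients *averaged* over an
  accumulation window (default 64 sequences) so the effective learning rate
  is invariant to the window size; linear warmup of the learning rate from 0
  over the first 1,000 optimizer steps; early stopping on validation AUROC
  with improvement threshold 0 and patience 50 evaluations. "Steps" for both
  warmup and evaluation cadence are optimizer updates (post-accumulation),
  not micro-batches: warmup counted in single sequences would span only
  1,000 reads and be vanishingly short. The evaluation cadence defaults to
  one validation pass per 200 optimizer steps. Because the balanced sampler
  is an infinite stream, an "epoch" is a configurable number of draws,
  defaulting to the size of the positive pool.
- The returned checkpoint is always the best-validation-AUROC state, and the
  set of read ids that contributed gradients is recorded so leakage can be
  asserted, not assumed.

The desk-scale experiments in `nanonascent.benchmark` use the same recipe
with sizes suited to a single CPU core: accumulation window 16, warmup 20
steps, evaluation every 10 steps, at most 4 epochs of 1,200 draws on a
2,000-read dataset. At a few hundred optimizer steps total, the full-scale
warmup (1,000 steps) would keep the learning rate near zero and a 64-sequence
window would allow too few updates; the defaults in `TrainConfig` itself
remain the full-scale recipe.

## Squiggle simulator

The generator emulates exactly the features of direct-RNA signal that the
classifier consumes:

- **Transcripts**: i.i.d. uniform sequences over {A,C,G,U}, lengths uniform
  in 600–1,200 nt, 20 per chromosome over chr1/chr20/chr2/chr3 with weights
  0.1/0.1/0.4/0.4 (so held-out splits have usable sizes at desk scale).
  U-content stratification arises naturally from sampling variance.
- **Pore response**: a synthetic 5-mer pore model with per-k-mer means drawn
  uniformly in 60–130 pA and sds in 1–4 pA; per-window dwell is geometric
  with mean 30 samples (memoryless — the simplest dwell model that exercises
  variable-length handling; a dispersion parameter is reserved for a
  negative-binomial extension); samples are Gaussian around the window mean.
- **Labeling**: a read is labeled with probability `labeled_fraction` (or,
  in kinetics mode, with the transcript's `f_new = 1 − 2^(−t/t½)`, t½
  log-uniform in 0.5–24 h); each U of a labeled read incorporates 5EU
  independently with probability 0.025, matching the low (2–3%) per-
  nucleotide labeling efficiency of 5EU. A labeled read can therefore carry
  zero incorporations and be physically indistinguishable from unlabeled —
  this is deliberate and caps achievable AUC below 1.
- **5EU effect**: a pure mean shift (`delta_mean_pA`) on the k-mer windows
  overlapping an incorporated position; no dwell effect by default.

**Choice of the default shift (40 pA).** Per-read med-MAD normalisation
leaves the upper edge of the unmodified current band varying by ~±0.2 MAD
units between reads (dwell-weighted k-mer composition differs read to read).
A shift comparable to the pore noise would therefore be confounded with
composition variance, making the end-to-end check a statement about sample
size rather than about the pipeline. The default is set so that a shifted
dwell plateau clears the unmodified band for most k-mer contexts
(oracle detectors based on smoothed level exceedances reach AUC ≈ 0.98,
close to the ≈ 0.99 ceiling set by zero-incorporation labeled reads). The
read-length default (600–1,200 nt) keeps the expected number of incorporated
5EUs in the post-crop signal high enough that zero-incorporation reads are
rare. The *null* configuration (`delta_mean_pA = 0`) leaves labels
statistically independent of the signal and is used to verify that no
shortcut features leak the label.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: real 5EU current shifts are far subtler and
context-dependent; there are no adapter/stall artifacts, no basecallable
structure, no homopolymer segmentation ambiguity, no RNA secondary-structure
translocation effects, and no batch effects between flow cells. Performance
numbers on this synthetic data validate the machinery (preprocessing,
training protocol, leakage control, metrics, kinetics algebra), not
biological detection accuracy.

## Evaluation

ROC-AUC follows the Mann–Whitney identity (ties count ½); PR-AUC is
step-wise average precision (trapezoidal interpolation in PR space is
optimistically biased); balanced accuracy is (sensitivity + specificity)/2;
thresholded calls treat a score equal to the threshold as positive.
Stratified reports use chromosome, U-content quintiles, or read-length bins
(default edges 0/1/2/3 kb in bases, falling back to signal samples divided
by the mean dwell when base lengths are unavailable — the bin edges are
configurable since canonical edges are not standardised). Strata with a
missing class report NaN rather than being dropped silently.

## Kinetics

Under first-order turnover with decay rate `k`, the fraction of molecules
synthesised during a pulse of duration `t` is `f_new = 1 − e^(−kt)`;
inverting the observed modified fraction gives `k = −ln(1 − f_new)/t` and
`t½ = ln 2/k`. This is the standard single-pulse kinetic model for
nucleoside-analog labeling. Optionally the modified fraction is first
corrected for classifier error by inverting the confusion matrix,
`f_new = (f_obs − FPR)/(TPR − FPR)`, clamped to [0, 1] with a flag when
clamping occurs. No pseudocounts are added; `f_new = 0` yields an infinite
half-life and `f_new = 1` a zero half-life, both flagged, so the effect of
read support stays visible instead of being masked. Aggregation is agnostic
to whether the assignment table maps reads to transcripts or genes.
Coverage-stratified concordance correlates log half-lives against a
reference at increasing read-support thresholds, excluding flagged boundary
estimates (their logs are undefined).

## Problem sizes and numerical choices

- Desk-scale detection experiment: 2,000 simulated reads (~1,500 training,
  ~200 validation, ~200 test), null control of 400 reads; runs in ~3 minutes
  on one CPU core and reaches held-out AUC ≈ 0.99.
- Kinetics experiment: 200 transcripts × ~300 reads (manifest-only
  simulation; squiggles are not synthesised where only labels are needed),
  plus a shallower run with bimodal read support for the coverage
  stratification.
- Checkpoints are single HDF5 files carrying the config as JSON, every
  weight and batch-norm buffer, and training metadata; a config hash and a
  format version are verified on load.
- All computation is float64; med-MAD tolerance for the normalisation
  invariants is 1e-9; checkpoint round-trips reproduce probabilities to
  1e-6.
- All randomness flows through `numpy.random.default_rng` seeds; fixed seeds
  give bit-identical simulations and training traces on one machine.

## Known limitations

- The simulator's strong-shift regime is intentionally easy; the package
  makes no claim about detection power on real 5EU data without retraining
  on labeled sequencing runs.
- The engine is CPU-only and single-sequence; throughput is adequate for the
  desk-scale experiments, not for production-scale training runs.
- POD5 containers, basecalled-FASTQ handling, event segmentation, transfer
  learning from basecaller backbones, differential expression, and
  multi-timepoint chase designs are out of scope.
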