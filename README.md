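# nanonascent

Detection of nascent (metabolically labeled) RNA molecules directly from raw
nanopore direct-RNA sequencing signal, and quantification of RNA kinetics
from the resulting per-read calls.

## The problem

In a metabolic-labeling experiment, cells are pulsed with the uridine analog
5-ethynyl-uridine (5EU). RNA transcribed during the pulse incorporates the
analog sparsely (2–3% of uridines), and each incorporated 5EU perturbs the
ionic current as the molecule transits a nanopore. `nanonascent` classifies
individual reads as *labeled* (nascent) or *unlabeled* (pre-existing) using
**only the raw current trace** — no basecalling, alignment or other metadata
enters the classifier — and then turns read-level calls into biology:

- per-transcript modified/unmodified counts and modification fractions,
- relative modification increase between conditions,
  `100·(f_condition/f_control − 1)`,
- first-order RNA half-lives from a single pulse:
  `f_new = n_mod/n_total`, `k = −ln(1 − f_new)/t`, `t½ = ln 2 / k`.

It is aimed at transcriptomics groups running direct-RNA nanopore experiments
with nucleoside-analog labeling who want read-level nascent/pre-existing
resolution and transcript-level turnover estimates.

## The classifier

A deliberately small network (66,349 trainable parameters) consumes one
med-MAD-normalised signal of any length with no padding:

```
conv(1→16, k=5, s=3) → BN → ReLU
conv(16→32, k=5, s=3) → BN → ReLU
conv(32→64, k=5, s=3) → BN → ReLU
bi-GRU(64→48 per direction)
concat[max-pool_t, mean-pool_t, h_fwd_final, h_bwd_final]  (288 features)
dense(288→70) → ReLU → dense(70→1) → sigmoid
```

Training follows a chromosome-holdout protocol (chr1 reads are test-only,
chr20 validation-only, everything else trains) with balanced positive/negative
sampling, AdamW (lr 0.001, weight decay 0.01), batch size 1 with gradient
accumulation, linear learning-rate warmup, and early stopping on validation
AUROC. The network, backpropagation and optimizer are implemented in
numpy/numba inside the package (`nanonascent.nn`) and are verified against
numerical gradients in the test-suite.

Because real labeled sequencing runs are large, the package ships a squiggle
simulator (`nanonascent.simulate`) that generates variable-length current
traces from a synthetic k-mer pore model, with geometric dwell, Gaussian
noise, sparse per-U incorporation and ground-truth labels — enough to train,
evaluate and validate the entire pipeline end to end on a laptop.

## Worked example

Train on a simulated dataset (2,000 reads, strong 40 pA shift, 2.5% per-U
incorporation) and evaluate on the held-out chromosome:

```python
from nanonascent.benchmark import detection_benchmark, kinetics_benchmark

b = detection_benchmark(seed=0)
print(b.auc_test, b.auc_null, b.train_result.best_val_auroc)
```

prints (about three minutes on one CPU core):

```
0.988 0.484 0.996
```

i.e. the trained classifier separates labeled from unlabeled held-out reads
with AUC 0.988, while on a *null* simulation (5EU current shift set to zero)
it scores AUC 0.484 ≈ 0.5 — labels carry no signal there, confirming the
simulator leaks no shortcut features. Half-life recovery:

```python
k = kinetics_benchmark(seed=0)
print(k.spearman, k.pearson)
print(k.concordance)
```

```
0.993 0.992
 threshold    n   pearson  spearman
         1  200  0.974176  0.975153
        50  104  0.986030  0.983615
       100  100  0.987136  0.984716
```

Estimated half-lives of 200 simulated transcripts (log-uniform 0.5–24 h,
2 h pulse, ~300 reads each) correlate with truth at Spearman 0.993, and
concordance improves monotonically with required read support.

The same steps are available from the shell:

```
nanonascent simulate --n-reads 1000 --out reads.h5 --manifest truth.tsv
nanonascent train --positives pos.h5 --negatives neg.h5 \
    --read-table reads.tsv --out model.ckpt
nanonascent predict --input reads.h5 --checkpoint model.ckpt --output calls.tsv
nanonascent eval --predictions calls.tsv --truth truth.tsv --by length
nanonascent kinetics --predictions calls.tsv --assignments tx.tsv \
    --label-time 2 --min-reads 100 --out halflives.tsv
```

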