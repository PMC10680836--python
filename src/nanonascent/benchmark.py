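"""Reference desk-scale experiments: end-to-end detection and half-life recovery.

These functions wire the simulator, training loop, classifier and kinetics
into the two self-contained experiments the package uses to demonstrate (and
test) itself end to end:

* :func:`detection_benchmark` — simulate a labeled/unlabeled squiggle dataset
  under the reference conditions, train the classifier with the
  chromosome-holdout protocol, and measure held-out (test-chromosome) AUC
  plus the AUC on a *null* dataset in which the 5EU current shift is zero
  (any real signal there would indicate label leakage through simulation
  artifacts).
* :func:`kinetics_benchmark` — simulate transcripts with known half-lives in
  kinetics mode, recover half-lives from per-read labels, and report the
  concordance with ground truth overall and stratified by read support.

The training recipe here is the published recipe at desk scale: gradient
accumulation over 16 sequences, 20 warmup steps, a validation evaluation
every 10 optimizer steps, and at most 4 epochs of 1200 sampler draws — sizes
chosen so the whole experiment runs on a single CPU core in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import roc_auc
from .kinetics import (
    aggregate_by_transcript,
    coverage_stratified_concordance,
    estimate_half_life,
    half_lives_to_frame,
)
from .model import ClassifierConfig, ReadPrediction, model_from_checkpoint, predict
from .signal_io import PreprocessConfig
from .simulate import SimConfig, manifest_to_read_table, simulate_dataset
from .training import DatasetPool, SplitRule, TrainConfig, TrainResult, assign_splits, train


@dataclass
class DetectionBenchmark:
    auc_test: float
    auc_null: float
    train_result: TrainResult
    split: object
    test_scores: np.ndarray
    test_truth: np.ndarray
    n_test: int
    n_null: int


def detection_benchmark(
    seed: int = 0,
    n_reads: int = 2000,
    n_null_reads: int = 400,
    max_epochs: int = 4,
    epoch_size: int = 1200,
) -> DetectionBenchmark:
    """Train on simulated squiggles and measure held-out and null AUC."""
    sim_cfg = SimConfig(n_reads=n_reads, seed=seed)
    reads, manifest = simulate_dataset(sim_cfg)
    split = assign_splits(manifest_to_read_table(manifest), SplitRule())

    labels = dict(zip(manifest["read_id"], manifest["label"]))
    positives = [r for r in reads if labels[r.read_id] == "labeled"]
    negatives = [r for r in reads if labels[r.read_id] == "unlabeled"]
    pool = DatasetPool([positives], [negatives])

    train_cfg = TrainConfig(
        accumulate=16,
        warmup_steps=20,
        eval_every=10,
        max_epochs=max_epochs,
        epoch_size=epoch_size,
        seed=seed,
    )
    result = train(pool, split, ClassifierConfig(), train_cfg)
    model = model_from_checkpoint(result.checkpoint)

    test_ids = split.ids("test")
    test_reads = [r for r in reads if r.read_id in test_ids]
    predictions, _ = predict(model, test_reads, PreprocessConfig())
    scores = np.array([p.probability for p in predictions])
    truth = np.array([labels[p.read_id] == "labeled" for p in predictions])
    auc_test = roc_auc(scores, truth)

    null_cfg = SimConfig(n_reads=n_null_reads, delta_mean_pA=0.0, seed=seed + 1)
    null_reads, null_manifest = simulate_dataset(null_cfg)
    null_labels = dict(zip(null_manifest["read_id"], null_manifest["label"]))
    null_preds, _ = predict(model, null_reads, PreprocessConfig())
    null_scores = np.array([p.probability for p in null_preds])
    null_truth = np.array([null_labels[p.read_id] == "labeled" for p in null_preds])
    auc_null = roc_auc(null_scores, null_truth)

    return DetectionBenchmark(
        auc_test=auc_test,
        auc_null=auc_null,
        train_result=result,
        split=split,
        test_scores=scores,
        test_truth=truth,
        n_test=len(predictions),
        n_null=len(null_preds),
    )


@dataclass
class KineticsBenchmark:
    spearman: float
    pearson: float
    estimates: pd.DataFrame
    concordance: pd.DataFrame
    n_transcripts: int


def perfect_calls(manifest: pd.DataFrame) -> list[ReadPrediction]:
    """Turn ground-truth labels into error-free read predictions."""
    return [
        ReadPrediction.from_probability(rid, 1.0 if label == "labeled" else 0.0)
        for rid, label in zip(manifest["read_id"], manifest["label"])
    ]


def kinetics_benchmark(
    seed: int = 0,
    n_reads: int = 60000,
    transcripts_per_chromosome: int = 50,
    label_time_h: float = 2.0,
    min_reads: int = 200,
    concordance_n_reads: int = 20000,
    concordance_thresholds: tuple[int, ...] = (1, 50, 100),
) -> KineticsBenchmark:
    """Recover simulated half-lives from per-read labels (perfect calls).

    The main run uses deep coverage (mean ~300 reads/transcript, transcripts
    below ``min_reads`` excluded) to measure recovery accuracy.  A second,
    shallower run feeds :func:`coverage_stratified_concordance`: its uneven
    chromosome weights make read support bimodal, so rising support
    thresholds should not decrease concordance.
    """
    uniform_chroms = tuple((c, 1.0) for c in ("chr1", "chr2", "chr3", "chr20"))
    cfg = SimConfig(
        n_reads=n_reads,
        kinetics=True,
        emit_signals=False,
        transcripts_per_chromosome=transcripts_per_chromosome,
        label_time_h=label_time_h,
        chromosomes=uniform_chroms,  # even coverage so all transcripts clear min_reads
        seed=seed,
    )
    reads, manifest = simulate_dataset(cfg)
    assignment = pd.DataFrame(
        {"read_id": manifest["read_id"], "target_id": manifest["transcript_id"]}
    )
    stats, _ = aggregate_by_transcript(perfect_calls(manifest), assignment, min_reads=min_reads)
    estimates = [estimate_half_life(s, label_time_h) for s in stats]
    true_half_life = (
        manifest.drop_duplicates("transcript_id")
        .set_index("transcript_id")["true_half_life_h"]
    )
    finite = [e for e in estimates if 0 < e.t_half < np.inf]
    est_log = np.log([e.t_half for e in finite])
    true_log = np.log([true_half_life[e.transcript_id] for e in finite])
    from .evaluation import correlate

    spearman = correlate(est_log, true_log, "spearman")
    pearson = correlate(est_log, true_log, "pearson")

    shallow_cfg = SimConfig(
        n_reads=concordance_n_reads,
        kinetics=True,
        emit_signals=False,
        transcripts_per_chromosome=transcripts_per_chromosome,
        label_time_h=label_time_h,
        seed=seed + 1,
    )
    _, shallow_manifest = simulate_dataset(shallow_cfg)
    shallow_assignment = pd.DataFrame(
        {"read_id": shallow_manifest["read_id"], "target_id": shallow_manifest["transcript_id"]}
    )
    shallow_stats, _ = aggregate_by_transcript(
        perfect_calls(shallow_manifest), shallow_assignment, min_reads=1
    )
    shallow_estimates = [estimate_half_life(s, label_time_h) for s in shallow_stats]
    shallow_truth = (
        shallow_manifest.drop_duplicates("transcript_id")
        .set_index("transcript_id")["true_half_life_h"]
    )
    concordance = coverage_stratified_concordance(
        shallow_estimates, shallow_truth, concordance_thresholds
    )
    return KineticsBenchmark(
        spearman=spearman,
        pearson=pearson,
        estimates=half_lives_to_frame(estimates),
        concordance=concordance,
        n_transcripts=len(finite),
    )
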