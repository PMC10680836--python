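"""Splits, balanced sampling, warmup schedule, and the training loop."""

import numpy as np
import pandas as pd
import pytest

from nanonascent.model import ClassifierConfig
from nanonascent.signal_io import PreprocessConfig, SignalRead
from nanonascent.training import (
    DatasetPool,
    SplitRule,
    TrainConfig,
    assign_splits,
    balanced_sampler,
    lr_at_step,
    train,
)


def read_table(rows):
    return pd.DataFrame(rows, columns=["read_id", "chromosome", "is_secondary"])


class TestAssignSplits:
    def test_chromosome_rules(self):
        table = read_table(
            [
                ("r1", "chr1", False),
                ("r2", "unmapped", False),
                ("r3", "chr5", True),
                ("r4", "chr20", False),
                ("r5", "chr7", False),
            ]
        )
        split = assign_splits(table, SplitRule())
        assert split["r1"] == "test"
        assert split["r2"] == "excluded"  # unmapped
        assert split["r3"] == "excluded"  # secondary alignment
        assert split["r4"] == "validation"
        assert split["r5"] == "train"

    def test_splits_disjoint_and_exhaustive(self):
        table = read_table([(f"r{i}", c, False) for i, c in
                            enumerate(["chr1", "chr2", "chr20", "chr3"] * 10)])
        split = assign_splits(table)
        names = [split[f"r{i}"] for i in range(40)]
        assert set(names) <= {"train", "validation", "test"}
        assert len(names) == len(table)

    def test_duplicate_read_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assign_splits(read_table([("r1", "chr1", False), ("r1", "chr2", False)]))


def tiny_reads(n, prefix):
    return [SignalRead(f"{prefix}{i}", np.arange(3.0) + i) for i in range(n)]


class TestBalancedSampler:
    def test_class_marginal_is_half(self):
        pool = DatasetPool([tiny_reads(40, "p")], [tiny_reads(160, "n")])
        draws = [label for _, label in zip_n(balanced_sampler(pool, seed=0), 10_000)]
        frac = np.mean(draws)
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 10_000)

    def test_negative_sources_proportional_to_size(self):
        big = tiny_reads(300, "a")
        small = tiny_reads(100, "b")
        pool = DatasetPool([tiny_reads(10, "p")], [big, small])
        items = [r for r, label in zip_n(balanced_sampler(pool, seed=1), 25_000) if label == 0]
        from_big = np.mean([r.read_id.startswith("a") for r in items])
        se = np.sqrt(0.75 * 0.25 / len(items))
        assert abs(from_big - 0.75) <= 3 * se

    def test_single_negative_source(self):
        pool = DatasetPool([tiny_reads(5, "p")], [tiny_reads(5, "n")])
        for read, label in zip_n(balanced_sampler(pool, seed=2), 100):
            if label == 0:
                assert read.read_id.startswith("n")

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            DatasetPool([], [tiny_reads(5, "n")])


class TestWarmup:
    def test_linear_warmup_schedule(self):
        cfg = TrainConfig(lr=0.001, warmup_steps=1000)
        assert lr_at_step(0, cfg) == 0.0
        assert lr_at_step(500, cfg) == pytest.approx(0.0005)
        assert lr_at_step(1000, cfg) == pytest.approx(0.001)
        assert lr_at_step(5000, cfg) == pytest.approx(0.001)


TINY_MODEL = ClassifierConfig(conv_channels=(2, 3), kernel_size=3, stride=2,
                              gru_hidden=3, head_hidden=4)
RAW_PREPROCESS = PreprocessConfig(crop_head=0, min_raw_length=1, max_raw_length=10**9)


def labeled_pool(rng, n_per_class=30, length=40):
    """Small two-class pool over chr1/chr20/chr2 with a crude class difference."""
    reads, rows = {"pos": [], "neg": []}, []
    chroms = ["chr1", "chr20", "chr2", "chr3"]
    for cls, offset in (("pos", 2.0), ("neg", 0.0)):
        for i in range(n_per_class):
            chrom = chroms[i % 4]
            rid = f"{cls}{i}"
            sig = rng.normal(offset, 1.0, size=length)
            reads[cls].append(SignalRead(rid, sig, {"chromosome": chrom}))
            rows.append((rid, chrom, False))
    table = pd.DataFrame(rows, columns=["read_id", "chromosome", "is_secondary"])
    return DatasetPool([reads["pos"]], [reads["neg"]]), assign_splits(table)


class TestTrainLoop:
    def test_optimizer_step_count_from_accumulation(self, rng):
        """floor(130/64) = 2 optimizer steps after 130 sequences."""
        pool, split = labeled_pool(rng)
        cfg = TrainConfig(accumulate=64, eval_every=10**6, max_epochs=1,
                          epoch_size=130, warmup_steps=1, seed=0)
        result = train(pool, split, TINY_MODEL, cfg, RAW_PREPROCESS)
        assert result.log["step"].iloc[-1] == 2

    def test_patience_stops_training_and_keeps_best(self, rng):
        """With an unbeatable improvement threshold, exactly the first
        evaluation defines the best state and patience ends the run."""
        pool, split = labeled_pool(rng)
        cfg = TrainConfig(accumulate=4, eval_every=1, max_epochs=100, epoch_size=8,
                          early_stop_min_delta=1.0, early_stop_patience=3,
                          warmup_steps=1, seed=0)
        result = train(pool, split, TINY_MODEL, cfg, RAW_PREPROCESS)
        assert len(result.log) == 1 + 3  # first eval + patience exhausted
        assert result.best_val_auroc == result.log["val_auroc"].iloc[0]

    def test_no_leakage_into_gradient_set(self, rng):
        pool, split = labeled_pool(rng)
        cfg = TrainConfig(accumulate=4, eval_every=2, max_epochs=2, epoch_size=20,
                          warmup_steps=1, seed=0)
        result = train(pool, split, TINY_MODEL, cfg, RAW_PREPROCESS)
        assert result.consumed_read_ids
        assert not result.consumed_read_ids & split.ids("test")
        assert not result.consumed_read_ids & split.ids("validation")
        assert result.consumed_read_ids <= split.ids("train")

    def test_reproducible_under_seed(self, rng):
        pool, split = labeled_pool(rng)
        cfg = TrainConfig(accumulate=4, eval_every=2, max_epochs=1, epoch_size=16,
                          warmup_steps=2, seed=9)
        a = train(pool, split, TINY_MODEL, cfg, RAW_PREPROCESS)
        b = train(pool, split, TINY_MODEL, cfg, RAW_PREPROCESS)
        pd.testing.assert_frame_equal(a.log, b.log)
        for k in a.checkpoint.weights:
            np.testing.assert_array_equal(a.checkpoint.weights[k], b.checkpoint.weights[k])

    def test_best_checkpoint_not_worse_than_any_evaluation(self, rng):
        pool, split = labeled_pool(rng)
        cfg = TrainConfig(accumulate=2, eval_every=1, max_epochs=2, epoch_size=16,
                          warmup_steps=2, seed=1)
        result = train(pool, split, TINY_MODEL, cfg, RAW_PREPROCESS)
        assert result.best_val_auroc >= result.log["val_auroc"].max()

    def test_single_class_validation_rejected(self, rng):
        pool, split = labeled_pool(rng)
        # restrict the validation chromosome to one that only negatives use
        reads = [r for source in pool.positives for r in source]
        for r in reads:
            if r.meta["chromosome"] == "chr20":
                split.split[r.read_id] = "train"
        cfg = TrainConfig(accumulate=2, eval_every=1, max_epochs=1, epoch_size=4,
                          warmup_steps=1, seed=0)
        from nanonascent.evaluation import UndefinedMetricError

        with pytest.raises(UndefinedMetricError):
            train(pool, split, TINY_MODEL, cfg, RAW_PREPROCESS)


def zip_n(iterator, n):
    for _, item in zip(range(n), iterator):
        yield item
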