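"""Chromosome-holdout splitting, balanced sampling, and the optimisation recipe.

Reads are split by the chromosome they map to — test and validation
chromosomes (defaults chr1 and chr20) are never seen during training, which
removes sequence-level confounds from the evaluation.  Training draws from
positive (labeled) and negative (unlabeled) pools with a balanced 1:1 class
ratio; multiple negative sources are sampled proportionally to their size.

The optimiser is AdamW (lr 0.001, weight decay 0.01) on per-sequence binary
cross-entropy with batch size 1; gradients are *averaged* over an
accumulation window of 64 sequences to simulate minibatch learning, the
learning rate warms up linearly from 0 over the first 1000 optimizer steps,
and training early-stops on validation AUROC with patience 50 evaluations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import nn
from .evaluation import roc_auc
from .model import Checkpoint, ClassifierConfig, SignalClassifier, build_model
from .signal_io import (
    DegenerateSignalError,
    PreprocessConfig,
    SignalRead,
    crop,
    length_filter_reason,
    normalize_med_mad,
)

logger = logging.getLogger(__name__)

SPLITS = ("train", "validation", "test", "excluded")


@dataclass(frozen=True)
class SplitRule:
    test_chromosomes: frozenset = frozenset({"chr1"})
    validation_chromosomes: frozenset = frozenset({"chr20"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "test_chromosomes", frozenset(self.test_chromosomes))
        object.__setattr__(self, "validation_chromosomes", frozenset(self.validation_chromosomes))
        if self.test_chromosomes & self.validation_chromosomes:
            raise ValueError("test and validation chromosome sets overlap")


@dataclass
class SplitAssignment:
    """read_id -> split in {train, validation, test, excluded}."""

    split: dict[str, str]
    rule: SplitRule

    def ids(self, name: str) -> set[str]:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return {rid for rid, s in self.split.items() if s == name}

    def __getitem__(self, read_id: str) -> str:
        return self.split[read_id]


def assign_splits(read_table: pd.DataFrame, rule: SplitRule | None = None) -> SplitAssignment:
    """Assign each read to a split based on its mapped chromosome.

    ``read_table`` has columns ``read_id``, ``chromosome`` (or ``"unmapped"``)
    and ``is_secondary``.  Unmapped and secondary reads are excluded; reads on
    the rule's test/validation chromosomes go to those splits; all other
    mapped primary reads train.
    """
    rule = rule or SplitRule()
    ids = read_table["read_id"]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()[:5]
        raise ValueError(f"duplicate read_ids in read table: {list(dupes)}")
    split: dict[str, str] = {}
    for row in read_table.itertuples(index=False):
        if bool(row.is_secondary) or row.chromosome == "unmapped":
            split[row.read_id] = "excluded"
        elif row.chromosome in rule.test_chromosomes:
            split[row.read_id] = "test"
        elif row.chromosome in rule.validation_chromosomes:
            split[row.read_id] = "validation"
        else:
            split[row.read_id] = "train"
    return SplitAssignment(split, rule)


@dataclass
class DatasetPool:
    """Positive (labeled) and negative (unlabeled) read sources.

    Each source is a sequence of reads; multiple negative sources model
    independent unlabeled experiments and are sampled proportionally to the
    number of reads they contain.
    """

    positives: list[Sequence[SignalRead]]
    negatives: list[Sequence[SignalRead]]

    def __post_init__(self) -> None:
        if not any(len(s) for s in self.positives):
            raise ValueError("no positive reads in pool")
        if not any(len(s) for s in self.negatives):
            raise ValueError("no negative reads in pool")


def balanced_sampler(
    pool: DatasetPool, seed: int
) -> Iterator[tuple[SignalRead, int]]:
    """Infinite stream of (read, class label) with balanced class marginals.

    Each draw picks the positive or negative class with probability 0.5; the
    source within the class is chosen proportionally to its read count, and a
    read is drawn uniformly within the source.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    sources = {1: [s for s in pool.positives if len(s)], 0: [s for s in pool.negatives if len(s)]}
    probs = {
        label: np.array([len(s) for s in srcs], dtype=float) / sum(len(s) for s in srcs)
        for label, srcs in sources.items()
    }
    while True:
        label = int(rng.random() < 0.5)
        srcs = sources[label]
        src = srcs[int(rng.choice(len(srcs), p=probs[label]))]
        yield src[int(rng.integers(len(src)))], label


@dataclass
class TrainConfig:
    """Optimisation recipe; defaults are the published full-scale recipe."""

    lr: float = 0.001
    weight_decay: float = 0.01
    batch_size: int = 1
    accumulate: int = 64
    warmup_steps: int = 1000
    max_epochs: int = 1000
    early_stop_min_delta: float = 0.0
    early_stop_patience: int = 50
    eval_every: int = 200  # optimizer steps between validation evaluations
    epoch_size: int | None = None  # sampler draws per epoch; default: positive pool size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("variable-length training uses batch_size 1")
        positive = (self.lr, self.accumulate, self.max_epochs,
                    self.early_stop_patience, self.eval_every)
        if any(v <= 0 for v in positive) or self.warmup_steps < 0:
            raise ValueError("invalid training configuration")
        if self.early_stop_min_delta < 0:
            raise ValueError("early_stop_min_delta must be >= 0")


def lr_at_step(step: int, cfg: TrainConfig) -> float:
    """Linear warmup: lr * min(1, step / warmup_steps); lr(0) = 0."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if cfg.warmup_steps == 0:
        return cfg.lr
    return cfg.lr * min(1.0, step / cfg.warmup_steps)


@dataclass
class TrainResult:
    checkpoint: Checkpoint
    log: pd.DataFrame  # columns: step, lr, loss, val_auroc
    consumed_read_ids: set[str]
    best_val_auroc: float


def _preprocess_pool(
    sources: list[Sequence[SignalRead]],
    keep_ids: set[str],
    preprocess: PreprocessConfig,
    min_length: int,
) -> list[list[tuple[str, np.ndarray]]]:
    """Filter/crop/normalise reads once, keeping only ids in ``keep_ids``."""
    out = []
    n_dropped = 0
    for source in sources:
        cleaned = []
        for read in source:
            if read.read_id not in keep_ids:
                continue
            if length_filter_reason(read.length, preprocess) is not None:
                n_dropped += 1
                continue
            cropped = crop(read, preprocess)
            if cropped.length < min_length:
                n_dropped += 1
                continue
            try:
                normalised = normalize_med_mad(cropped)
            except DegenerateSignalError:
                n_dropped += 1
                continue
            cleaned.append((read.read_id, normalised.signal))
        out.append(cleaned)
    if n_dropped:
        logger.info("preprocessing dropped %d reads", n_dropped)
    return out


def _bce(p: float, y: int) -> float:
    eps = 1e-12
    return -(y * math.log(p + eps) + (1 - y) * math.log(1 - p + eps))


def train(
    pool: DatasetPool,
    split: SplitAssignment,
    model_cfg: ClassifierConfig | None = None,
    cfg: TrainConfig | None = None,
    preprocess: PreprocessConfig | None = None,
) -> TrainResult:
    """Train the classifier with the chromosome-holdout protocol.

    Only reads assigned to the train split ever contribute gradients; the
    validation split drives early stopping on AUROC, and the returned
    checkpoint holds the best-validation-AUROC parameter state.  The log
    records (step, lr, loss, val AUROC) at each evaluation.
    """
    cfg = cfg or TrainConfig()
    model_cfg = model_cfg or ClassifierConfig()
    preprocess = preprocess or PreprocessConfig()
    model = build_model(model_cfg, seed=cfg.seed)

    train_ids = split.ids("train")
    val_ids = split.ids("validation")
    pos_sources = _preprocess_pool(pool.positives, train_ids, preprocess, model.min_input_length)
    neg_sources = _preprocess_pool(pool.negatives, train_ids, preprocess, model.min_input_length)
    if not any(pos_sources) or not any(neg_sources):
        raise ValueError("train split must contain both positive and negative reads")

    val_set: list[tuple[np.ndarray, int]] = []
    for label, sources in ((1, pool.positives), (0, pool.negatives)):
        for source in _preprocess_pool(sources, val_ids, preprocess, model.min_input_length):
            val_set.extend((sig, label) for _, sig in source)
    if not val_set:
        raise ValueError("validation split is empty")

    sampler = balanced_sampler(
        DatasetPool(
            [_SignalSource(s) for s in pos_sources], [_SignalSource(s) for s in neg_sources]
        ),
        seed=cfg.seed,
    )
    optimizer = nn.AdamW(
        model.parameters(), model.gradients(), lr=cfg.lr, weight_decay=cfg.weight_decay
    )

    n_positive = sum(len(s) for s in pos_sources)
    epoch_size = cfg.epoch_size or n_positive
    consumed: set[str] = set()
    log_rows: list[dict] = []
    best_auroc = -math.inf
    best_state: tuple[dict, dict, dict] | None = None
    evals_since_best = 0
    micro = 0
    step = 0
    window_loss = 0.0
    window_n = 0
    last_loss = math.nan
    stop = False

    def _evaluate() -> float:
        scores = np.array([model.predict_proba(sig) for sig, _ in val_set])
        truth = np.array([y for _, y in val_set], dtype=bool)
        return roc_auc(scores, truth)

    def _snapshot() -> tuple[dict, dict, dict]:
        return (
            {k: v.copy() for k, v in model.parameters().items()},
            {k: v.copy() for k, v in model.buffers().items()},
            {"step": step, "epoch": epoch},
        )

    for epoch in range(cfg.max_epochs):
        for _ in range(epoch_size):
            item, label = next(sampler)
            read_id, signal = item.read_id, item.signal
            assert read_id in train_ids  # leakage guard
            consumed.add(read_id)
            logit = model.forward(signal, train=True)
            p = nn.sigmoid(logit)
            window_loss += _bce(p, label)
            window_n += 1
            model.backward((p - label) / cfg.accumulate)  # averaged over the window
            micro += 1
            if micro < cfg.accumulate:
                continue
            optimizer.step(lr=lr_at_step(step, cfg))
            model.zero_grad()
            micro = 0
            step += 1
            last_loss = window_loss / window_n
            window_loss = 0.0
            window_n = 0
            if step % cfg.eval_every == 0:
                auroc = _evaluate()
                log_rows.append(
                    {"step": step, "lr": lr_at_step(step, cfg), "loss": last_loss,
                     "val_auroc": auroc}
                )
                if auroc > best_auroc + cfg.early_stop_min_delta:
                    best_auroc = auroc
                    best_state = _snapshot()
                    evals_since_best = 0
                else:
                    evals_since_best += 1
                if evals_since_best >= cfg.early_stop_patience:
                    stop = True
                    break
        if stop:
            break

    if best_state is None:  # no evaluation ever ran; fall back to final state
        best_auroc = _evaluate()
        best_state = _snapshot()
        log_rows.append(
            {"step": step, "lr": lr_at_step(step, cfg), "loss": last_loss,
             "val_auroc": best_auroc}
        )
    weights, buffers, state_meta = best_state
    checkpoint = Checkpoint(
        config=model_cfg,
        weights=weights,
        buffers=buffers,
        training_meta={
            "epoch": state_meta["epoch"],
            "step": state_meta["step"],
            "best_val_auroc": best_auroc,
            "seed": cfg.seed,
        },
    )
    log = pd.DataFrame(log_rows, columns=["step", "lr", "loss", "val_auroc"])
    return TrainResult(checkpoint, log, consumed, best_auroc)


class _SignalSource(Sequence):
    """Adapter presenting preprocessed (read_id, signal) pairs as SignalReads."""

    def __init__(self, items: list[tuple[str, np.ndarray]]) -> None:
        self._items = items

    def __len__(self) -> int:
        return len(self._items)

    def __getitem__(self, i):
        read_id, signal = self._items[i]
        return SignalRead(read_id, signal)
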