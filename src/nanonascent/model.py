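"""The 5EU read classifier: a padding-free conv + bi-GRU network.

The network consumes one med-MAD-normalised current trace of *any* length (no
padding anywhere in the forward path) and emits a single probability that the
molecule was 5EU-labeled:

    conv blocks (1-D conv, stride s, batch norm, ReLU)
      -> bidirectional GRU over the conv feature sequence
      -> concat[max-pool over time, mean-pool over time,
                final forward hidden, final backward hidden]
      -> dense (head_hidden) -> ReLU -> dense (1) -> sigmoid

The reference configuration (channels 1->16->32->64, kernel 5, stride 3,
batch norm, bi-GRU hidden 48, head 288->70->1) has 66,349 trainable
parameters (66,061 under a single-bias GRU convention), i.e. ~66k — small
enough to train on modest hardware and to resist overfitting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

from . import nn
from .signal_io import (
    DegenerateSignalError,
    PreprocessConfig,
    SignalRead,
    crop,
    length_filter_reason,
    normalize_med_mad,
)

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1


class InputLengthError(ValueError):
    """Input signal shorter than the network's minimum length."""


class CheckpointError(IOError):
    """Checkpoint file is incompatible, corrupt, or from another format version."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture hyperparameters; defaults pin the reference network."""

    conv_channels: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 5
    stride: int = 3
    use_batch_norm: bool = True
    gru_hidden: int = 48
    gru_bidirectional: bool = True
    head_hidden: int = 70
    activation: str = "relu"

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_channels", tuple(int(c) for c in self.conv_channels))
        sizes = (*self.conv_channels, self.kernel_size, self.stride,
                 self.gru_hidden, self.head_hidden)
        if any(s < 1 for s in sizes):
            raise ValueError("all architecture sizes must be positive")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierConfig":
        return cls(**json.loads(text))


@dataclass
class ReadPrediction:
    """Per-read modification probability and thresholded call."""

    read_id: str
    probability: float
    call: str
    threshold: float = 0.5

    @classmethod
    def from_probability(cls, read_id: str, probability: float,
                         threshold: float = 0.5) -> "ReadPrediction":
        call = "modified" if probability >= threshold else "unmodified"
        return cls(read_id, float(probability), call, threshold)


@dataclass
class Checkpoint:
    """Serialized model state: architecture, weights and training metadata."""

    config: ClassifierConfig
    weights: dict[str, np.ndarray]
    buffers: dict[str, np.ndarray] = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)


class SignalClassifier:
    """Variable-length raw-signal classifier (see module docstring)."""

    def __init__(self, config: ClassifierConfig | None = None, seed: int = 0) -> None:
        self.config = config or ClassifierConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.layers: list[tuple[str, nn.Layer]] = []
        in_ch = 1
        for i, out_ch in enumerate(cfg.conv_channels):
            self.layers.append(
                (f"conv{i}", nn.Conv1d(in_ch, out_ch, cfg.kernel_size, cfg.stride, rng))
            )
            if cfg.use_batch_norm:
                self.layers.append((f"bn{i}", nn.BatchNorm1d(out_ch)))
            self.layers.append((f"act{i}", nn.ReLU()))
            in_ch = out_ch
        self.layers.append(
            ("gru", nn.GRU(in_ch, cfg.gru_hidden, cfg.gru_bidirectional, rng))
        )
        pool = nn.PoolConcat(cfg.gru_hidden, cfg.gru_bidirectional)
        self.layers.append(("pool", pool))
        self.layers.append(("fc0", nn.Dense(pool.out_features, cfg.head_hidden, rng)))
        self.layers.append(("fc_act", nn.ReLU()))
        self.layers.append(("fc1", nn.Dense(cfg.head_hidden, 1, rng)))

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": p for ln, layer in self.layers for pn, p in layer.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": g for ln, layer in self.layers for pn, g in layer.grads.items()}

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{bn}": b for ln, layer in self.layers for bn, b in layer.buffers.items()}

    def zero_grad(self) -> None:
        for _, layer in self.layers:
            layer.zero_grad()

    def load_state(self, weights: dict[str, np.ndarray],
                   buffers: dict[str, np.ndarray] | None = None) -> None:
        own = self.parameters()
        if set(own) != set(weights):
            raise CheckpointError("weight names do not match the architecture")
        for name, value in weights.items():
            if own[name].shape != value.shape:
                raise CheckpointError(f"shape mismatch for {name}")
            own[name][...] = value
        if buffers:
            own_buf = self.buffers()
            for name, value in buffers.items():
                if name in own_buf:
                    own_buf[name][...] = value

    # -- forward / backward -------------------------------------------------

    @property
    def min_input_length(self) -> int:
        """Smallest signal length for which every conv output is nonempty."""
        length = 1
        for _ in self.config.conv_channels:
            length = self.config.kernel_size + self.config.stride * (length - 1)
        return length

    def forward(self, signal: np.ndarray, train: bool = False) -> float:
        """Normalised signal (T,) -> logit."""
        signal = np.asarray(signal, dtype=np.float64)
        if signal.ndim != 1:
            raise ValueError("expected a 1-D signal")
        if signal.size < self.min_input_length:
            raise InputLengthError(
                f"signal of length {signal.size} is shorter than the minimum "
                f"input length {self.min_input_length} of this architecture"
            )
        x = signal[:, None]
        for _, layer in self.layers:
            x = layer.forward(x, train=train)
        return float(x[0])

    def backward(self, dlogit: float) -> None:
        dy = np.array([float(dlogit)])
        for _, layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict_proba(self, signal: np.ndarray) -> float:
        """Probability the read is 5EU-labeled; strictly in (0, 1)."""
        return float(nn.sigmoid(self.forward(signal, train=False)))


def build_model(config: ClassifierConfig | None = None, seed: int = 0) -> SignalClassifier:
    """Instantiate the classifier with deterministic weight initialisation."""
    return SignalClassifier(config, seed=seed)


def count_parameters(model: SignalClassifier) -> int:
    """Exact count of trainable scalars (buffers such as BN running stats excluded)."""
    return int(sum(p.size for p in model.parameters().values()))


# ---------------------------------------------------------------------------
# Checkpoint IO
# ---------------------------------------------------------------------------


def _config_hash(config_json: str) -> str:
    return hashlib.sha256(config_json.encode()).hexdigest()


def save_checkpoint(model: SignalClassifier, path, training_meta: dict | None = None) -> None:
    """Write a single-file HDF5 checkpoint (config JSON + weights + metadata)."""
    config_json = model.config.to_json()
    with h5py.File(Path(path), "w") as fh:
        fh.attrs["format"] = "nanonascent-checkpoint"
        fh.attrs["format_version"] = CHECKPOINT_FORMAT_VERSION
        fh.attrs["config_json"] = config_json
        fh.attrs["config_hash"] = _config_hash(config_json)
        fh.attrs["training_meta_json"] = json.dumps(training_meta or {}, sort_keys=True)
        wgrp = fh.create_group("weights")
        for name, value in model.parameters().items():
            wgrp.create_dataset(name, data=value)
        bgrp = fh.create_group("buffers")
        for name, value in model.buffers().items():
            bgrp.create_dataset(name, data=value)


def load_checkpoint(path) -> Checkpoint:
    """Read a checkpoint; verifies format version and config integrity."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("format_version", -1))
        if version != CHECKPOINT_FORMAT_VERSION:
            raise CheckpointError(
                f"{path}: checkpoint format version {version} is not "
                f"supported (expected {CHECKPOINT_FORMAT_VERSION})"
            )
        config_json = fh.attrs["config_json"]
        if _config_hash(config_json) != fh.attrs["config_hash"]:
            raise CheckpointError(f"{path}: config hash mismatch (corrupt or edited file)")
        config = ClassifierConfig.from_json(config_json)
        weights = {name: fh["weights"][name][()] for name in fh["weights"]}
        buffers = {name: fh["buffers"][name][()] for name in fh.get("buffers", {})}
        meta = json.loads(fh.attrs.get("training_meta_json", "{}"))
    return Checkpoint(config, weights, buffers, meta)


def model_from_checkpoint(ckpt: Checkpoint | str | Path) -> SignalClassifier:
    if not isinstance(ckpt, Checkpoint):
        ckpt = load_checkpoint(ckpt)
    model = SignalClassifier(ckpt.config)
    model.load_state(ckpt.weights, ckpt.buffers)
    return model


# ---------------------------------------------------------------------------
# Batch inference
# ---------------------------------------------------------------------------


def predict(
    model: SignalClassifier | Checkpoint | str | Path,
    reads: Iterable[SignalRead],
    preprocess: PreprocessConfig | None = None,
    threshold: float = 0.5,
) -> tuple[list[ReadPrediction], list[tuple[str, str]]]:
    """Classify raw reads; preprocessing is applied internally.

    Each read is length-filtered, head-cropped and med-MAD normalised before
    the forward pass.  Reads removed by the filters, with degenerate signals,
    or too short for the network after cropping are reported in the skipped
    list as ``(read_id, reason)``.  Reads are consumed one at a time, so
    memory does not grow with the number of reads; output order matches the
    input order of survivors.
    """
    if not isinstance(model, SignalClassifier):
        model = model_from_checkpoint(model)
    preprocess = preprocess or PreprocessConfig()
    predictions: list[ReadPrediction] = []
    skipped: list[tuple[str, str]] = []
    for read in reads:
        reason = length_filter_reason(read.length, preprocess)
        if reason is not None:
            skipped.append((read.read_id, reason))
            continue
        cropped = crop(read, preprocess)
        if cropped.length < model.min_input_length:
            skipped.append((read.read_id, "too_short_for_model"))
            continue
        try:
            normalised = normalize_med_mad(cropped)
        except DegenerateSignalError:
            logger.warning("read %s dropped: degenerate signal (MAD=0)", read.read_id)
            skipped.append((read.read_id, "degenerate_signal"))
            continue
        prob = model.predict_proba(normalised.signal)
        predictions.append(ReadPrediction.from_probability(read.read_id, prob, threshold))
    return predictions, skipped


def predictions_to_frame(predictions: Sequence[ReadPrediction]):
    import pandas as pd

    return pd.DataFrame(
        [(p.read_id, p.probability, p.call) for p in predictions],
        columns=["read_id", "probability", "call"],
    )
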