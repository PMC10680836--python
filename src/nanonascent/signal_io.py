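"""Raw-signal containers and per-read preprocessing.

Direct-RNA nanopore reads arrive as variable-length current traces ("squiggles")
stored in multi-read HDF5 containers.  This module reads and writes two HDF5
dialects — a multi-read fast5-style layout and a simpler flat fixture layout —
and implements the per-read preprocessing applied before classification:

1. discard reads shorter than 5000 or longer than 400000 raw samples,
2. crop the first 5000 samples (sequencing-start artifacts),
3. med-MAD normalise: ``(x - median(x)) / median(|x - median(x)|)``.

The med-MAD scaling uses the plain median absolute deviation with no Gaussian
consistency constant; because the transform is invariant to any positive affine
rescaling of the input, the choice of constant (and whether signals are in DAC
units or picoamperes) cannot change the classifier input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

FIXTURE_FORMAT_NAME = "nanonascent-fixture"
FIXTURE_FORMAT_VERSION = 1

#: read-level metadata keys serialised by the fixture format
_META_KEYS = ("chromosome", "transcript_id", "label", "u_fraction", "base_length")

LABELS = ("labeled", "unlabeled", "unknown")


class DegenerateSignalError(ValueError):
    """Raised when a signal cannot be med-MAD normalised (MAD == 0 or too short)."""


@dataclass
class SignalRead:
    """One sequencing read: a raw current trace plus identity metadata.

    Parameters
    ----------
    read_id : str
        Unique identifier within a container.
    signal : ndarray
        1-D array of current samples (raw DAC units or picoamperes).
    meta : dict
        Optional per-read metadata: ``chromosome`` (or ``"unmapped"``),
        ``transcript_id``, ``label`` (one of ``labeled``/``unlabeled``/
        ``unknown``), ``u_fraction``, ``base_length``.
    """

    read_id: str
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 1:
            raise ValueError(f"read {self.read_id}: signal must be 1-D")
        if self.signal.size == 0:
            raise ValueError(f"read {self.read_id}: empty signal")

    @property
    def length(self) -> int:
        """Number of raw samples."""
        return int(self.signal.size)

    @property
    def label(self) -> str:
        return self.meta.get("label", "unknown")


@dataclass(frozen=True)
class PreprocessConfig:
    """Thresholds for the raw-read length filter and head crop.

    ``min_raw_length`` and ``max_raw_length`` apply to the *pre-crop* raw
    length; a read of exactly ``min_raw_length`` samples is discarded since
    it would be empty after cropping.
    """

    crop_head: int = 5000
    min_raw_length: int = 5000
    max_raw_length: int = 400000

    def __post_init__(self) -> None:
        if self.crop_head < 0:
            raise ValueError("crop_head must be >= 0")
        if not (0 < self.min_raw_length <= self.max_raw_length):
            raise ValueError("require 0 < min_raw_length <= max_raw_length")


@dataclass
class FilterCounts:
    """Per-call bookkeeping for :func:`filter_and_crop`."""

    n_input: int = 0
    discarded_short: int = 0
    discarded_long: int = 0
    kept: int = 0


def length_filter_reason(length: int, cfg: PreprocessConfig) -> str | None:
    """Return ``"too_short"``/``"too_long"`` if the raw length fails the filter, else None."""
    if length <= cfg.min_raw_length:
        return "too_short"
    if length > cfg.max_raw_length:
        return "too_long"
    return None


def crop(read: SignalRead, cfg: PreprocessConfig) -> SignalRead:
    """Remove the first ``cfg.crop_head`` samples (caller must have length-filtered)."""
    return SignalRead(read.read_id, read.signal[cfg.crop_head:], dict(read.meta))


def filter_and_crop(
    reads: Iterable[SignalRead], cfg: PreprocessConfig | None = None
) -> tuple[list[SignalRead], FilterCounts]:
    """Apply the raw-length filter then crop the head of each surviving read.

    Reads with raw length <= ``min_raw_length`` or > ``max_raw_length`` are
    removed; survivors lose their first ``crop_head`` samples.  Input order is
    preserved.  Returns the surviving reads and per-call counts.
    """
    cfg = cfg or PreprocessConfig()
    counts = FilterCounts()
    kept: list[SignalRead] = []
    for read in reads:
        counts.n_input += 1
        reason = length_filter_reason(read.length, cfg)
        if reason == "too_short":
            counts.discarded_short += 1
            continue
        if reason == "too_long":
            counts.discarded_long += 1
            continue
        counts.kept += 1
        kept.append(crop(read, cfg))
    return kept, counts


def normalize_med_mad(read: SignalRead) -> SignalRead:
    """Median-centre and MAD-scale a read's signal.

    Output has median 0 and MAD 1.  Raises :class:`DegenerateSignalError` for
    signals of fewer than 2 samples or with MAD == 0 (constant signal); the
    caller's policy is to drop such reads with a warning.
    """
    x = np.asarray(read.signal, dtype=np.float64)
    if x.size < 2:
        raise DegenerateSignalError(f"read {read.read_id}: fewer than 2 samples")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        raise DegenerateSignalError(f"read {read.read_id}: MAD is zero")
    return SignalRead(read.read_id, (x - med) / mad, dict(read.meta))


# ---------------------------------------------------------------------------
# Container IO
# ---------------------------------------------------------------------------


def _decode(value):
    if isinstance(value, bytes):
        return value.decode()
    if isinstance(value, np.generic):
        return value.item()
    return value


def _load_fixture(path: Path) -> Iterator[SignalRead]:
    with h5py.File(path, "r") as fh:
        for name in fh:
            grp = fh[name]
            if "signal" not in grp:
                logger.warning("read %s in %s has no signal dataset; skipped", name, path)
                continue
            meta = {k: _decode(grp.attrs[k]) for k in _META_KEYS if k in grp.attrs}
            yield SignalRead(name, grp["signal"][()], meta)


def _load_fast5_multi(path: Path) -> Iterator[SignalRead]:
    with h5py.File(path, "r") as fh:
        for name in fh:
            grp = fh[name]
            if not isinstance(grp, h5py.Group):
                continue
            if "Raw" not in grp or "Signal" not in grp["Raw"]:
                logger.warning("read %s in %s has no Raw/Signal dataset; skipped", name, path)
                continue
            raw = np.asarray(grp["Raw"]["Signal"][()])
            read_id = name[5:] if name.startswith("read_") else name
            meta: dict = {}
            if "channel_id" in grp:
                attrs = grp["channel_id"].attrs
                if all(k in attrs for k in ("offset", "range", "digitisation")):
                    offset = float(attrs["offset"])
                    rng = float(attrs["range"])
                    digitisation = float(attrs["digitisation"])
                    raw = (raw.astype(np.float64) + offset) * rng / digitisation
            yield SignalRead(read_id, raw, meta)


def load_reads(path, format: str = "fixture") -> Iterator[SignalRead]:
    """Lazily yield :class:`SignalRead` objects from an HDF5 container.

    ``format`` is ``"fixture"`` (flat layout written by :func:`write_reads`) or
    ``"fast5_multi"`` (per-read group with a ``Raw/Signal`` dataset; DAC values
    are converted to picoamperes via the ``channel_id`` attrs ``offset``,
    ``range``, ``digitisation`` when present, else passed through unscaled).

    Reads are yielded one container at a time so memory does not grow with the
    number of containers processed by a caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal container not found: {path}")
    if format == "fixture":
        return _load_fixture(path)
    if format == "fast5_multi":
        return _load_fast5_multi(path)
    raise ValueError(f"unknown container format: {format!r}")


def write_reads(reads: Sequence[SignalRead], path, format: str = "fixture") -> int:
    """Write reads to an HDF5 container; returns the number written.

    In fixture format, ``load_reads(write_reads(R))`` reproduces signals
    bit-exactly along with metadata; the label field defaults to ``"unknown"``.
    """
    path = Path(path)
    n = 0
    with h5py.File(path, "w") as fh:
        if format == "fixture":
            fh.attrs["format"] = FIXTURE_FORMAT_NAME
            fh.attrs["format_version"] = FIXTURE_FORMAT_VERSION
            for read in reads:
                grp = fh.create_group(read.read_id)
                grp.create_dataset("signal", data=read.signal)
                meta = dict(read.meta)
                meta.setdefault("label", "unknown")
                for key in _META_KEYS:
                    if key in meta and meta[key] is not None:
                        grp.attrs[key] = meta[key]
                n += 1
        elif format == "fast5_multi":
            for read in reads:
                grp = fh.create_group(f"read_{read.read_id}")
                grp.create_dataset("Raw/Signal", data=read.signal)
                n += 1
        else:
            raise ValueError(f"unknown container format: {format!r}")
    return n
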