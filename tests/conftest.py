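"""Shared fixtures: the expensive end-to-end experiments run once per session."""

from __future__ import annotations

import numpy as np
import pytest

from nanonascent.benchmark import (
    DetectionBenchmark,
    KineticsBenchmark,
    detection_benchmark,
    kinetics_benchmark,
)
from nanonascent.signal_io import SignalRead


@pytest.fixture(scope="session")
def detection_run() -> DetectionBenchmark:
    """Full synthetic training run under the reference strong-shift conditions."""
    return detection_benchmark(seed=0)


@pytest.fixture(scope="session")
def kinetics_run() -> KineticsBenchmark:
    """Half-life recovery from kinetics-mode simulation with perfect calls."""
    return kinetics_benchmark(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_reads(rng: np.random.Generator, lengths, prefix: str = "r", **meta) -> list[SignalRead]:
    return [
        SignalRead(f"{prefix}{i}", rng.normal(90.0, 15.0, size=n).astype(np.float32), dict(meta))
        for i, n in enumerate(lengths)
    ]
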