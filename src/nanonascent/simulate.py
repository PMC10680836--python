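"""Synthetic direct-RNA squiggle generation with ground-truth 5EU labels.

The generator emulates the features of direct-RNA nanopore data that matter to
a raw-signal modification caller: variable-length current traces, k-mer
dependent current levels with per-k-mer dwell and Gaussian noise, and *sparse*
5EU incorporation — each uridine of a labeled (nascent) molecule carries the
analog with low probability (default 2.5%, matching the 2–3% per-nucleotide
labeling efficiency of 5EU pulse labeling), producing localised current shifts
on the k-mer windows that overlap an incorporated position.

In kinetics mode, each transcript is assigned a true half-life and its reads
are labeled with probability ``f_new = 1 - 2^(-t_label / t_half)``, the
fraction of molecules synthesised during a pulse of duration ``t_label`` under
first-order turnover.  This provides ground truth for half-life estimation.

The simulator is deliberately minimal: the 5EU effect is a pure mean shift on
overlapping k-mers, dwell times are geometric, and transcript sequences are
i.i.d. uniform over {A, C, G, U}.  See ``docs/methods.md`` for what this does
and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_io import SignalRead

BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MANIFEST_COLUMNS = [
    "read_id",
    "label",
    "chromosome",
    "transcript_id",
    "n_U_incorporated",
    "base_length",
    "u_fraction",
    "true_half_life_h",
]


@dataclass
class PoreModel:
    """k-mer → (mean current, sd) table driving squiggle synthesis.

    Stored as dense arrays indexed by the base-4 encoding of the k-mer
    (A=0, C=1, G=2, U=3, most significant base first).
    """

    k: int
    means: np.ndarray  # shape (4**k,), picoamperes
    sds: np.ndarray  # shape (4**k,), picoamperes, all > 0

    def __post_init__(self) -> None:
        n = 4**self.k
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        if self.means.shape != (n,) or self.sds.shape != (n,):
            raise ValueError(f"pore model tables must cover all {n} {self.k}-mers")
        if not np.all(self.sds > 0):
            raise ValueError("all pore-model sds must be > 0")

    @property
    def table(self) -> dict[str, tuple[float, float]]:
        """Mapping view: k-mer string → (mean_pA, sd_pA)."""
        kmers = ("".join(p) for p in product(BASES, repeat=self.k))
        return {km: (float(self.means[i]), float(self.sds[i])) for i, km in enumerate(kmers)}

    def to_tsv(self, path) -> None:
        rows = [(km, m, s) for km, (m, s) in self.table.items()]
        pd.DataFrame(rows, columns=["kmer", "mean_pA", "sd_pA"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "PoreModel":
        df = pd.read_csv(path, sep="\t")
        k = len(df["kmer"].iloc[0])
        means = np.empty(4**k)
        sds = np.empty(4**k)
        for km, m, s in df.itertuples(index=False):
            idx = 0
            for base in km:
                idx = idx * 4 + _BASE_INDEX[base]
            means[idx] = m
            sds[idx] = s
        return cls(k, means, sds)


def make_default_pore_model(seed: int, k: int = 5) -> PoreModel:
    """Deterministic synthetic pore model: means in 60–130 pA, sds in 1–4 pA."""
    rng = np.random.default_rng(seed)
    n = 4**k
    return PoreModel(k, rng.uniform(60.0, 130.0, n), rng.uniform(1.0, 4.0, n))


@dataclass
class SimConfig:
    """Conditions for a simulated dataset.

    The defaults define the reference study conditions used throughout the
    test-suite: 2.5% per-U incorporation, a strong 40 pA mean shift on k-mers
    overlapping an incorporated 5EU (chosen so a shifted dwell plateau clears
    the band of unmodified k-mer levels for most k-mer contexts — per-read
    med-MAD normalisation leaves the band edge varying by a few tenths of a
    MAD unit between reads, so a weak shift would be confounded with k-mer
    composition), geometric dwell with mean 30 samples per base, and
    transcripts of 600–1200 nt spread over four chromosomes.
    """

    n_reads: int = 1000
    labeled_fraction: float = 0.5
    p_incorporation: float = 0.025
    delta_mean_pA: float = 40.0
    dwell_mean: float = 30.0
    dwell_dispersion: float = 1.0  # reserved for a negative-binomial extension
    noise_sd_scale: float = 1.0
    read_length_range: tuple[int, int] = (600, 1200)
    chromosomes: tuple[tuple[str, float], ...] = (
        ("chr1", 0.1),
        ("chr20", 0.1),
        ("chr2", 0.4),
        ("chr3", 0.4),
    )
    transcripts_per_chromosome: int = 20
    kinetics: bool = False
    half_life_range_h: tuple[float, float] = (0.5, 24.0)
    label_time_h: float = 2.0
    emit_signals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("labeled_fraction", "p_incorporation"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.read_length_range
        if not (0 < lo <= hi):
            raise ValueError("read_length_range must be a nonempty positive range")
        if self.n_reads < 0 or self.dwell_mean < 1:
            raise ValueError("n_reads must be >= 0 and dwell_mean >= 1")
        if self.kinetics:
            lo, hi = self.half_life_range_h
            if not (0 < lo <= hi) or self.label_time_h <= 0:
                raise ValueError("invalid kinetics parameters")
        weights = np.array([w for _, w in self.chromosomes], dtype=float)
        if len(weights) == 0 or np.any(weights < 0) or weights.sum() == 0:
            raise ValueError("chromosome weights must be nonnegative and sum > 0")


def encode_sequence(sequence: str) -> np.ndarray:
    """RNA string over {A,C,G,U} → integer codes (A=0, C=1, G=2, U=3)."""
    try:
        return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid RNA base {exc.args[0]!r}") from None


def _kmer_indices(codes: np.ndarray, k: int) -> np.ndarray:
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return windows @ powers


def simulate_read(
    sequence: str,
    incorporated_positions,
    pore: PoreModel,
    cfg: SimConfig,
    rng: np.random.Generator,
    read_id: str = "sim_read",
    meta: dict | None = None,
) -> SignalRead:
    """Synthesise one squiggle from an RNA sequence and its 5EU positions.

    For each k-mer window a geometric dwell (mean ``cfg.dwell_mean`` samples)
    is drawn and samples are emitted from
    ``Normal(mean_pA + delta·[window overlaps an incorporated U],
    (sd_pA·noise_sd_scale)^2)``.
    """
    codes = encode_sequence(sequence)
    k = pore.k
    if codes.size < k:
        raise ValueError(f"sequence shorter than k-mer length {k}")
    positions = np.asarray(sorted(incorporated_positions), dtype=np.int64)
    if positions.size:
        if positions.min() < 0 or positions.max() >= codes.size:
            raise ValueError("incorporated position out of range")
        if np.any(codes[positions] != _BASE_INDEX["U"]):
            raise ValueError("incorporated position is not a U")

    n_win = codes.size - k + 1
    idx = _kmer_indices(codes, k)
    means = pore.means[idx].copy()
    sds = pore.sds[idx] * cfg.noise_sd_scale

    if positions.size and cfg.delta_mean_pA != 0.0:
        shifted = np.zeros(n_win, dtype=bool)
        for p in positions:  # window i covers bases i .. i+k-1
            shifted[max(0, p - k + 1) : min(n_win, p + 1)] = True
        means[shifted] += cfg.delta_mean_pA

    dwells = rng.geometric(1.0 / cfg.dwell_mean, size=n_win)
    level = np.repeat(means, dwells)
    noise_sd = np.repeat(sds, dwells)
    signal = rng.normal(level, noise_sd).astype(np.float32)
    return SignalRead(read_id, signal, dict(meta or {}))


def _simulate_transcripts(cfg: SimConfig, rng: np.random.Generator):
    """Per-chromosome transcript pools: sequences, U positions, half-lives."""
    transcripts = []
    lo, hi = cfg.read_length_range
    log_lo, log_hi = (np.log(h) for h in cfg.half_life_range_h)
    for chrom, _ in cfg.chromosomes:
        for t in range(cfg.transcripts_per_chromosome):
            length = int(rng.integers(lo, hi + 1))
            codes = rng.integers(0, 4, size=length)
            t_half = float(np.exp(rng.uniform(log_lo, log_hi))) if cfg.kinetics else np.nan
            transcripts.append(
                {
                    "transcript_id": f"{chrom}_tx{t:03d}",
                    "chromosome": chrom,
                    "codes": codes,
                    "sequence": "".join(BASES[c] for c in codes),
                    "u_positions": np.flatnonzero(codes == _BASE_INDEX["U"]),
                    "u_fraction": float(np.mean(codes == _BASE_INDEX["U"])),
                    "true_half_life_h": t_half,
                }
            )
    return transcripts


def simulate_dataset(
    cfg: SimConfig, pore: PoreModel | None = None
) -> tuple[list[SignalRead], pd.DataFrame]:
    """Generate a dataset of squiggles plus a ground-truth manifest.

    In classification mode each read is labeled (nascent) with probability
    ``cfg.labeled_fraction``; in kinetics mode the label probability per read
    is the transcript's ``f_new = 1 - 2^(-label_time / t_half)``.  Labeled
    reads incorporate 5EU at each U independently with ``cfg.p_incorporation``
    (so a labeled read may carry zero incorporations, as in real pulse
    labeling); unlabeled reads incorporate none.

    Fixed ``cfg.seed`` gives bit-identical output.  With
    ``cfg.emit_signals=False`` only the manifest is produced (reads carry a
    placeholder one-sample signal); useful for kinetics-scale runs where the
    squiggles themselves are not needed.
    """
    rng = np.random.default_rng(cfg.seed)
    if pore is None:
        pore = make_default_pore_model(int(rng.integers(2**31)))
    transcripts = _simulate_transcripts(cfg, rng)
    per_chrom = [
        [t for t in transcripts if t["chromosome"] == chrom] for chrom, _ in cfg.chromosomes
    ]
    weights = np.array([w for _, w in cfg.chromosomes], dtype=float)
    weights = weights / weights.sum()

    chrom_draws = rng.choice(len(weights), size=cfg.n_reads, p=weights)
    reads: list[SignalRead] = []
    rows = []
    for i in range(cfg.n_reads):
        pool = per_chrom[chrom_draws[i]]
        tx = pool[int(rng.integers(len(pool)))]
        if cfg.kinetics:
            p_labeled = 1.0 - 2.0 ** (-cfg.label_time_h / tx["true_half_life_h"])
        else:
            p_labeled = cfg.labeled_fraction
        labeled = bool(rng.random() < p_labeled)
        if labeled and tx["u_positions"].size:
            mask = rng.random(tx["u_positions"].size) < cfg.p_incorporation
            positions = tx["u_positions"][mask]
        else:
            positions = np.empty(0, dtype=np.int64)

        read_id = f"r{i:06d}"
        meta = {
            "chromosome": tx["chromosome"],
            "transcript_id": tx["transcript_id"],
            "label": "labeled" if labeled else "unlabeled",
            "u_fraction": tx["u_fraction"],
            "base_length": len(tx["codes"]),
        }
        if cfg.emit_signals:
            reads.append(
                simulate_read(tx["sequence"], positions, pore, cfg, rng, read_id, meta)
            )
        else:
            reads.append(SignalRead(read_id, np.zeros(1, dtype=np.float32), meta))
        rows.append(
            {
                "read_id": read_id,
                "label": meta["label"],
                "chromosome": tx["chromosome"],
                "transcript_id": tx["transcript_id"],
                "n_U_incorporated": int(positions.size),
                "base_length": len(tx["codes"]),
                "u_fraction": tx["u_fraction"],
                "true_half_life_h": tx["true_half_life_h"],
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return reads, manifest


def manifest_to_read_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Derive the aligner-style read table (read_id, chromosome, is_secondary)."""
    return pd.DataFrame(
        {
            "read_id": manifest["read_id"],
            "chromosome": manifest["chromosome"],
            "is_secondary": False,
        }
    )


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(Path(path), sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
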