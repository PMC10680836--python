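"""Transcript-level RNA kinetics from per-read modification calls.

After classifying individual reads as modified (5EU-labeled, i.e. synthesised
during the pulse) or unmodified, reads are aggregated per transcript (or per
gene — the aggregation target is whatever the assignment table maps to).  The
modified fraction estimates the fraction of *new* molecules,
``f_new = 1 - e^(-k·t)`` under first-order turnover with decay rate ``k`` and
pulse duration ``t``, giving

    k = -ln(1 - f_new) / t,        t_half = ln(2) / k.

An optional correction for imperfect calls inverts the classifier's confusion
matrix, ``f_new = (mod_fraction - FPR) / (TPR - FPR)`` clamped to [0, 1],
before the kinetic inversion.  Saturated fractions (0 or 1) produce flagged
boundary estimates (infinite or zero half-life) rather than silently clipped
values, so low read support stays visible downstream.

The relative modification increase between an experimental condition and a
control is ``100 · (mod_fraction_condition / mod_fraction_control - 1)``,
positive when modified reads are more prevalent under the condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .evaluation import UndefinedMetricError, correlate
from .model import ReadPrediction

logger = logging.getLogger(__name__)


class UndefinedIncreaseError(ZeroDivisionError):
    """Relative modification increase is undefined (control fraction is 0)."""


@dataclass(frozen=True)
class ErrorRates:
    """Classifier sensitivity (TPR) and false-positive rate for call correction."""

    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fpr < self.tpr <= 1.0:
            raise ValueError("require 0 <= fpr < tpr <= 1")


@dataclass
class TranscriptModStats:
    """Modified/unmodified read counts for one transcript in one condition."""

    transcript_id: str
    n_mod: int
    n_unmod: int
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_mod < 0 or self.n_unmod < 0 or self.n_mod + self.n_unmod == 0:
            raise ValueError("counts must be nonnegative with n_total > 0")

    @property
    def n_total(self) -> int:
        return self.n_mod + self.n_unmod

    @property
    def mod_fraction(self) -> float:
        return self.n_mod / self.n_total


@dataclass
class HalfLifeEstimate:
    transcript_id: str
    t_half: float  # hours; inf when no turnover observed
    k_decay: float  # per hour
    f_new: float
    n_total: int
    label_time: float
    flags: tuple[str, ...] = ()


@dataclass
class AggregationSummary:
    n_reads: int = 0
    n_unassigned: int = 0
    n_transcripts_excluded: int = 0


def aggregate_by_transcript(
    predictions: Iterable[ReadPrediction],
    assignment: pd.DataFrame,
    min_reads: int = 100,
) -> tuple[list[TranscriptModStats], AggregationSummary]:
    """Count modified/unmodified calls per assignment target.

    ``assignment`` maps ``read_id`` to ``target_id`` (transcript or gene) with
    an optional ``condition`` column.  Targets with fewer than ``min_reads``
    total reads are excluded (and counted in the summary); reads without an
    assignment are ignored with a logged count.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    cols = ["target_id"] + (["condition"] if "condition" in assignment else [])
    lookup = assignment.set_index("read_id")[cols]
    summary = AggregationSummary()
    counts: dict[tuple[str, str], list[int]] = {}
    for pred in predictions:
        summary.n_reads += 1
        try:
            row = lookup.loc[pred.read_id]
        except KeyError:
            summary.n_unassigned += 1
            continue
        key = (str(row["target_id"]), str(row["condition"]) if "condition" in cols else "")
        pair = counts.setdefault(key, [0, 0])
        pair[0 if pred.call == "modified" else 1] += 1
    if summary.n_unassigned:
        logger.info("%d reads had no transcript assignment", summary.n_unassigned)
    stats = []
    for (target, condition), (n_mod, n_unmod) in sorted(counts.items()):
        if n_mod + n_unmod < min_reads:
            summary.n_transcripts_excluded += 1
            continue
        stats.append(TranscriptModStats(target, n_mod, n_unmod, condition))
    return stats, summary


def relative_modification_increase(
    condition: TranscriptModStats, control: TranscriptModStats
) -> float:
    """Percent increase of the modified fraction in condition over control."""
    if condition.transcript_id != control.transcript_id:
        raise ValueError("condition and control must refer to the same transcript")
    if control.mod_fraction == 0:
        raise UndefinedIncreaseError(
            f"{control.transcript_id}: control modified fraction is zero"
        )
    return 100.0 * (condition.mod_fraction / control.mod_fraction - 1.0)


def estimate_half_life(
    stats: TranscriptModStats,
    label_time: float,
    correction: ErrorRates | None = None,
) -> HalfLifeEstimate:
    """First-order half-life from the modified fraction after a pulse.

    ``f_new = mod_fraction`` (optionally confusion-corrected and clamped),
    then ``k = -ln(1 - f_new) / label_time`` and ``t_half = ln(2) / k``.
    """
    if label_time <= 0:
        raise ValueError("label_time must be > 0 hours")
    flags: list[str] = []
    f_new = stats.mod_fraction
    if correction is not None:
        raw = (f_new - correction.fpr) / (correction.tpr - correction.fpr)
        f_new = min(1.0, max(0.0, raw))
        if f_new != raw:
            flags.append("correction_clamped")
    if f_new == 0.0:
        flags.append("no_turnover")
        k = 0.0
        t_half = math.inf
    elif f_new == 1.0:
        flags.append("saturated")
        k = math.inf
        t_half = 0.0
    else:
        k = -math.log1p(-f_new) / label_time
        t_half = math.log(2.0) / k
    return HalfLifeEstimate(
        stats.transcript_id, t_half, k, f_new, stats.n_total, label_time, tuple(flags)
    )


def coverage_stratified_concordance(
    estimates: Sequence[HalfLifeEstimate],
    reference: dict[str, float] | pd.Series,
    thresholds: Sequence[int],
) -> pd.DataFrame:
    """Correlation of log half-lives with a reference at rising read support.

    For each read-support threshold, Pearson and Spearman correlations of
    ``log(t_half)`` are computed over transcripts with ``n_total`` at or above
    the threshold that have finite estimates in both tables.  Thresholds with
    fewer than 3 overlapping transcripts (or degenerate values) yield NaN
    entries rather than failing.
    """
    reference = pd.Series(dict(reference), dtype=float)
    rows = []
    for threshold in thresholds:
        pairs = [
            (e.t_half, reference[e.transcript_id])
            for e in estimates
            if e.n_total >= threshold
            and e.transcript_id in reference.index
            and 0 < e.t_half < math.inf
            and 0 < reference[e.transcript_id] < math.inf
        ]
        pearson = spearman = np.nan
        if len(pairs) >= 3:
            est = np.log(np.array([p[0] for p in pairs]))
            ref = np.log(np.array([p[1] for p in pairs]))
            try:
                pearson = correlate(est, ref, "pearson")
                spearman = correlate(est, ref, "spearman")
            except UndefinedMetricError:
                pass
        rows.append(
            {"threshold": int(threshold), "n": len(pairs),
             "pearson": pearson, "spearman": spearman}
        )
    return pd.DataFrame(rows, columns=["threshold", "n", "pearson", "spearman"])


def half_lives_to_frame(estimates: Sequence[HalfLifeEstimate]) -> pd.DataFrame:
    rows = [
        {
            "target_id": e.transcript_id,
            "n_total": e.n_total,
            "f_new": e.f_new,
            "k": e.k_decay,
            "t_half": e.t_half,
            "flags": ",".join(e.flags),
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows, columns=["target_id", "n_total", "f_new", "k", "t_half", "flags"]
    )
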