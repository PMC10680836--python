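"""Classification metrics and stratified evaluation.

ROC-AUC follows the Mann–Whitney identity (probability a random positive
outranks a random negative, ties counted 1/2); PR-AUC is step-wise average
precision, not trapezoidal interpolation, avoiding the optimistic bias of
linear interpolation in PR space.  Stratified reports mirror the standard
read-level breakdowns for this problem: by chromosome, by transcript U
content, and by read length.

Numerical work delegates to scikit-learn and scipy; the package's test-suite
pins these against brute-force oracles (exhaustive pair counting and
threshold enumeration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. a single-class set)."""


@dataclass
class ScoredSet:
    """Scores with binary truth and optional per-item strata.

    ``strata`` columns used by :func:`stratified_eval`: ``chromosome``,
    ``u_fraction``, ``base_length`` (nucleotides) or ``length`` (signal
    samples).
    """

    scores: np.ndarray
    truth: np.ndarray  # boolean; True = positive
    strata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.truth = np.asarray(self.truth, dtype=bool)
        if self.scores.shape != self.truth.shape or self.scores.ndim != 1:
            raise ValueError("scores and truth must be 1-D and equal-length")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.strata is not None and len(self.strata) != len(self.scores):
            raise ValueError("strata must have one row per scored item")


def _as_arrays(scores, truth=None):
    if isinstance(scores, ScoredSet):
        return scores.scores, scores.truth
    return np.asarray(scores, dtype=float), np.asarray(truth, dtype=bool)


def roc_auc(scores, truth=None) -> float:
    """Area under the ROC curve (Mann–Whitney identity, ties count 1/2)."""
    s, t = _as_arrays(scores, truth)
    if t.all() or not t.any():
        raise UndefinedMetricError("ROC-AUC needs at least one positive and one negative")
    return float(roc_auc_score(t, s))


def pr_auc(scores, truth=None) -> float:
    """Area under the precision–recall curve as step-wise average precision."""
    s, t = _as_arrays(scores, truth)
    if not t.any():
        raise UndefinedMetricError("PR-AUC needs at least one positive")
    return float(average_precision_score(t, s))


def _confusion(scores, truth, threshold: float):
    calls = scores >= threshold  # ties at the threshold call positive
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    tn = int(np.sum(~calls & ~truth))
    return tp, fp, fn, tn


def balanced_accuracy(scores, truth=None, threshold: float = 0.5) -> float:
    """(sensitivity + specificity) / 2 at a threshold; robust to imbalance."""
    s, t = _as_arrays(scores, truth)
    if t.all() or not t.any():
        raise UndefinedMetricError("balanced accuracy needs both classes")
    tp, fp, fn, tn = _confusion(s, t, threshold)
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def f1(scores, truth=None, threshold: float = 0.5) -> float:
    """Harmonic mean of precision and recall at a threshold; 0 when both vanish."""
    s, t = _as_arrays(scores, truth)
    tp, fp, fn, _ = _confusion(s, t, threshold)
    if tp + fp == 0 and tp + fn == 0:
        raise UndefinedMetricError("F1 needs a predicted or actual positive")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


DEFAULT_LENGTH_BINS_NT = (0, 1000, 2000, 3000, np.inf)
STRATUM_KEYS = ("chromosome", "u_fraction", "length")


@dataclass
class StratifiedReport:
    """Per-stratum metrics; bins with a missing class carry NaN, not silence."""

    by: str
    table: pd.DataFrame  # columns: label, n, auc, pr_auc
    bin_edges: tuple | None = None


def stratified_eval(
    scored: ScoredSet,
    by: str,
    bins: Sequence[float] | None = None,
    dwell_mean: float = 30.0,
) -> StratifiedReport:
    """Compute AUC and PR-AUC within strata of chromosome, U content or length.

    ``by="u_fraction"`` uses quantile bins (quintiles by default);
    ``by="length"`` bins base lengths in nucleotides (default edges 0/1/2/3 kb
    and beyond), falling back to signal samples divided by ``dwell_mean`` when
    ``base_length`` is unavailable.  Stratum item counts always sum to the
    total number of scored items.
    """
    if by not in STRATUM_KEYS:
        raise ValueError(f"unknown stratum key {by!r}; expected one of {STRATUM_KEYS}")
    if scored.strata is None:
        raise ValueError("scored set has no strata metadata")
    strata = scored.strata
    if by == "chromosome":
        groups = strata["chromosome"].astype(str)
        edges = None
    elif by == "u_fraction":
        q = np.linspace(0, 1, 6) if bins is None else np.asarray(bins, dtype=float)
        if bins is None:
            groups = pd.qcut(strata["u_fraction"], q=q, duplicates="drop")
        else:
            groups = pd.cut(strata["u_fraction"], bins=q, include_lowest=True)
        edges = tuple(q)
    else:
        if "base_length" in strata:
            lengths = strata["base_length"].astype(float)
        else:
            lengths = strata["length"].astype(float) / dwell_mean
        edges = tuple(DEFAULT_LENGTH_BINS_NT if bins is None else bins)
        groups = pd.cut(lengths, bins=list(edges), right=False)

    rows = []
    for label, idx in pd.Series(range(len(groups))).groupby(groups, observed=False):
        sel = idx.to_numpy()
        sub_scores = scored.scores[sel]
        sub_truth = scored.truth[sel]
        try:
            auc = roc_auc(sub_scores, sub_truth)
        except UndefinedMetricError:
            auc = np.nan
        try:
            ap = pr_auc(sub_scores, sub_truth) if len(sub_truth) else np.nan
        except UndefinedMetricError:
            ap = np.nan
        rows.append({"label": str(label), "n": int(len(sel)), "auc": auc, "pr_auc": ap})
    return StratifiedReport(by, pd.DataFrame(rows, columns=["label", "n", "auc", "pr_auc"]), edges)


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank correlation (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with >= 3 items")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
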