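"""Metrics vs brute-force oracles, plus stratified evaluation."""

import numpy as np
import pandas as pd
import pytest

from nanonascent.evaluation import (
    ScoredSet,
    UndefinedMetricError,
    balanced_accuracy,
    correlate,
    f1,
    pr_auc,
    roc_auc,
    stratified_eval,
)


def pairwise_auc_oracle(scores, truth):
    """O(n^2) Mann-Whitney: P(random positive outranks random negative), ties 1/2."""
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def average_precision_oracle(scores, truth):
    """Exhaustive threshold enumeration: AP = sum (R_i - R_{i-1}) * P_i."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    t = truth[order]
    n_pos = t.sum()
    ap = 0.0
    prev_recall = 0.0
    i = 0
    n = len(s)
    tp = fp = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # process tied scores as one threshold
            tp += t[j]
            fp += ~t[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def random_scored(rng, max_n=50, with_ties=True):
    n = int(rng.integers(4, max_n + 1))
    truth = rng.random(n) < rng.uniform(0.2, 0.8)
    if not truth.any():
        truth[0] = True
    if truth.all():
        truth[0] = False
    if with_ties:
        scores = rng.integers(0, 6, size=n) / 5.0  # coarse grid forces ties
    else:
        scores = rng.random(n)
    return scores.astype(float), truth


class TestRocAuc:
    def test_examples(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False]) == 1.0
        assert roc_auc([0.6, 0.6], [True, False]) == 0.5
        assert roc_auc([0.8, 0.4, 0.5, 0.3], [True, True, False, False]) == 0.75

    def test_matches_pairwise_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            scores, truth = random_scored(rng)
            assert roc_auc(scores, truth) == pytest.approx(
                pairwise_auc_oracle(scores, truth), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores, truth = random_scored(rng, with_ties=False)
        base = roc_auc(scores, truth)
        for transform in (np.exp, np.tanh, lambda x: 3 * x - 7, lambda x: x**3):
            assert roc_auc(transform(scores), truth) == pytest.approx(base, abs=1e-12)

    def test_label_flip_maps_to_complement(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores, truth = random_scored(rng)
            assert roc_auc(scores, ~truth) == pytest.approx(
                1.0 - roc_auc(scores, truth), abs=1e-12
            )

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.9], [True, True])


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.1], [True, True, False]) == 1.0

    def test_matches_threshold_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            scores, truth = random_scored(rng)
            assert pr_auc(scores, truth) == pytest.approx(
                average_precision_oracle(scores, truth), abs=1e-12
            )

    def test_random_scores_give_prevalence(self):
        rng = np.random.default_rng(4)
        prevalence = 0.3
        values = []
        for _ in range(30):
            n = 500
            truth = rng.random(n) < prevalence
            truth[0] = True
            values.append(pr_auc(rng.random(n), truth))
        # mean AP of an uninformative classifier approaches the prevalence
        assert np.mean(values) == pytest.approx(prevalence, abs=0.03)

    def test_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pr_auc([0.5, 0.2], [False, False])


class TestThresholdedMetrics:
    def test_balanced_accuracy_examples(self):
        assert balanced_accuracy([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5) == 1.0
        assert balanced_accuracy([0.9, 0.9, 0.9, 0.9], [1, 1, 0, 0], 0.5) == 0.5
        # TP=3 FN=1 TN=1 FP=1 -> (0.75 + 0.5)/2
        scores = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1]
        truth = [1, 1, 1, 1, 0, 0]
        assert balanced_accuracy(scores, truth, 0.5) == pytest.approx(0.625)

    def test_balanced_accuracy_maximized_at_youden_optimum(self):
        """BA = (J + 1)/2, so both are maximized at the same threshold."""
        rng = np.random.default_rng(5)
        scores = np.concatenate([rng.normal(0.6, 0.2, 80), rng.normal(0.4, 0.2, 80)])
        truth = np.repeat([True, False], 80)
        thresholds = np.unique(scores)
        ba = [balanced_accuracy(scores, truth, t) for t in thresholds]
        tpr = [(scores[truth] >= t).mean() for t in thresholds]
        fpr = [(scores[~truth] >= t).mean() for t in thresholds]
        youden = np.array(tpr) - np.array(fpr)
        assert np.argmax(ba) == np.argmax(youden)

    def test_f1_examples(self):
        assert f1([0.9, 0.1], [1, 0], 0.5) == 1.0
        # TP=2 FP=1 FN=2 -> 2*(2/3)*(1/2)/((2/3)+(1/2)) = 4/7
        scores = [0.9, 0.8, 0.7, 0.2, 0.1]
        truth = [1, 1, 0, 1, 1]
        assert f1(scores, truth, 0.5) == pytest.approx(4 / 7)

    def test_f1_zero_when_no_true_positive(self):
        assert f1([0.9, 0.1], [0, 1], 0.5) == 0.0


class TestStratifiedEval:
    def scored(self):
        rng = np.random.default_rng(6)
        n = 300
        truth = rng.random(n) < 0.5
        base_length = rng.integers(200, 5000, size=n)
        long = base_length >= 1000
        # informative scores only for long reads
        scores = np.where(long, np.where(truth, 0.8, 0.2) + rng.normal(0, 0.05, n),
                          rng.random(n))
        strata = pd.DataFrame(
            {
                "chromosome": rng.choice(["chr1", "chr2"], n),
                "u_fraction": rng.uniform(0.1, 0.4, n),
                "base_length": base_length,
            }
        )
        return ScoredSet(scores, truth, strata)

    def test_single_bin_equals_unstratified(self):
        s = self.scored()
        report = stratified_eval(s, "length", bins=[0, np.inf])
        assert report.table["auc"].iloc[0] == pytest.approx(roc_auc(s))
        assert report.table["n"].iloc[0] == len(s.scores)

    def test_bin_counts_partition_total(self):
        s = self.scored()
        report = stratified_eval(s, "length")
        assert report.table["n"].sum() == len(s.scores)
        report_u = stratified_eval(s, "u_fraction")
        assert report_u.table["n"].sum() == len(s.scores)

    def test_informative_stratum_scores_higher(self):
        s = self.scored()
        report = stratified_eval(s, "length", bins=[0, 1000, np.inf])
        auc_short, auc_long = report.table["auc"]
        assert auc_long > auc_short

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="stratum"):
            stratified_eval(self.scored(), "gc_content")


class TestCorrelate:
    def test_linear_relation_pearson(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1, "pearson") == pytest.approx(1.0)

    def test_decreasing_spearman(self):
        x = np.array([1.0, 2, 5, 9])
        assert correlate(x, -(x**3), "spearman") == pytest.approx(-1.0)

    def test_rank_example(self):
        assert correlate([1, 2, 3, 4], [1, 3, 2, 4], "spearman") == pytest.approx(0.8)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedMetricError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
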