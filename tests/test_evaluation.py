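"""Confusion rates, ROC/AUC, log loss, bootstrap CIs and scoring modes.

The AUC implementation is cross-checked against a hand-written O(n^2)
Mann-Whitney pair count; log loss against direct summation.
"""

import math

import numpy as np
import pytest

from prostriage.evaluation import (
    CIError,
    UndefinedAUCError,
    bootstrap_ci,
    confusion,
    evaluate_set,
    log_loss,
    resolve_calls,
    roc_auc,
)
from prostriage.wsi_inference import WSIPrediction


def _auc_pair_oracle(y, s):
    """Pairwise ranking probability, ties counted one half."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _prediction(slide_id, s_ind, s_agg, threshold=0.5):
    label_set = frozenset(
        l for l, s in (("indolent", s_ind), ("aggressive", s_agg)) if s >= threshold
    )
    if not label_set:
        exclusive = "benign"
    elif len(label_set) == 1:
        exclusive = next(iter(label_set))
    else:
        exclusive = "aggressive" if s_agg >= s_ind else "indolent"
    return WSIPrediction(slide_id, s_ind, s_agg, label_set, exclusive)


class TestConfusion:
    def test_tpr_arithmetic(self):
        counts = confusion([1] * 10 + [0] * 5, [1] * 9 + [0] + [0] * 5)
        assert counts.tp == 9 and counts.fn == 1
        assert counts.tpr == pytest.approx(0.9)

    def test_fpr_arithmetic(self):
        counts = confusion([0] * 10, [0] * 10)
        assert counts.fp == 0 and counts.tn == 10
        assert counts.fpr == pytest.approx(0.0)

    def test_all_positive_truth_flags_fpr_undefined(self):
        counts = confusion([1, 1, 1], [1, 0, 1])
        assert not counts.fpr_defined
        assert math.isnan(counts.fpr)
        assert counts.tpr_defined

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([1, 1, 1], [0.2, 0.5, 0.9])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.round(rng.random(n), 1)  # coarse scores force ties
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(_auc_pair_oracle(y, s), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        s = rng.random(30)
        _, auc1 = roc_auc(y, s)
        _, auc2 = roc_auc(y, 1 / (1 + np.exp(-7 * s + 2)))
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, size=25)
        y[:2] = [0, 1]
        curve, _ = roc_auc(y, rng.random(25))
        assert curve[0] == (0.0, 0.0)
        assert curve[-1] == (1.0, 1.0)
        fprs = [p[0] for p in curve]
        tprs = [p[1] for p in curve]
        assert fprs == sorted(fprs)
        assert tprs == sorted(tprs)


class TestLogLoss:
    def test_confident_correct_is_near_zero(self):
        assert log_loss([1], [1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_prediction_is_ln_two(self):
        assert log_loss([0, 1, 1, 0], [0.5] * 4) == pytest.approx(np.log(2))

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, size=100)
        p = rng.uniform(0.01, 0.99, size=100)
        direct = -sum(
            yi * math.log(pi) + (1 - yi) * math.log(1 - pi) for yi, pi in zip(y, p)
        ) / len(y)
        assert log_loss(y, p) == pytest.approx(direct, abs=1e-12)


class TestBootstrap:
    def test_constant_statistic_gives_degenerate_interval(self):
        lo, hi = bootstrap_ci(lambda t, s: 0.7, [0, 1] * 10, [0.5] * 20, n_iter=50, seed=0)
        assert lo == hi == pytest.approx(0.7)

    def test_same_seed_reproduces_interval(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.random(40)
        auc_stat = lambda t, sc: roc_auc(t, sc)[1]
        assert bootstrap_ci(auc_stat, y, s, n_iter=200, seed=5) == bootstrap_ci(
            auc_stat, y, s, n_iter=200, seed=5
        )

    def test_mostly_degenerate_resamples_rejected(self):
        # a statistic needing two specific slides in the resample is defined
        # on only ~40% of bootstrap draws, under the 50% floor
        ids = np.arange(20)

        def needs_both_sentinels(t, s):
            if 0 not in t or 1 not in t:
                raise ValueError("degenerate resample")
            return 0.5

        with pytest.raises(CIError):
            bootstrap_ci(needs_both_sentinels, ids, np.linspace(0, 1, 20), n_iter=200, seed=0)


class TestEvaluateSet:
    def _perfect_predictions(self):
        truths = ["benign"] * 4 + ["indolent"] * 4 + ["aggressive"] * 4
        preds = []
        for i, t in enumerate(truths):
            s_ind = 0.9 if t == "indolent" else 0.1
            s_agg = 0.9 if t == "aggressive" else 0.1
            preds.append(_prediction(f"s{i}", s_ind, s_agg))
        return preds, truths

    def test_perfect_predictions_have_unit_accuracy(self):
        preds, truths = self._perfect_predictions()
        report = evaluate_set(preds, truths, mode="exclusive", n_bootstrap=50)
        for head in ("indolent", "aggressive"):
            assert report.heads[head].accuracy.point == pytest.approx(1.0)
            assert report.heads[head].roc_auc.point == pytest.approx(1.0)

    def test_double_label_counted_correct_only_under_acceptance(self):
        # an indolent-truth slide called both indolent and aggressive, with
        # the aggressive score higher: exclusive mode counts it wrong for
        # the indolent head, acceptance mode counts it right
        preds = [
            _prediction("d", 0.8, 0.9),
            _prediction("b", 0.1, 0.1),
            _prediction("a", 0.2, 0.9),
        ]
        truths = ["indolent", "benign", "aggressive"]
        assert resolve_calls(preds, truths, "exclusive") == ["aggressive", "benign", "aggressive"]
        assert resolve_calls(preds, truths, "double_label_accept") == [
            "indolent", "benign", "aggressive",
        ]

    def test_acceptance_never_hurts_accuracy(self):
        rng = np.random.default_rng(17)
        labels = ["benign", "indolent", "aggressive"]
        for _ in range(20):
            n = 30
            preds = [
                _prediction(f"s{i}", rng.random(), rng.random()) for i in range(n)
            ]
            truths = [labels[i] for i in rng.integers(0, 3, size=n)]
            exclusive = evaluate_set(preds, truths, "exclusive", n_bootstrap=1)
            accept = evaluate_set(preds, truths, "double_label_accept", n_bootstrap=1)
            for head in ("indolent", "aggressive"):
                assert (
                    accept.heads[head].accuracy.point
                    >= exclusive.heads[head].accuracy.point - 1e-12
                )

    def test_shuffled_truth_auc_near_half(self):
        rng = np.random.default_rng(23)
        n = 600
        preds = [_prediction(f"s{i}", rng.random(), rng.random()) for i in range(n)]
        labels = ["benign", "indolent", "aggressive"]
        truths = [labels[i] for i in rng.integers(0, 3, size=n)]
        report = evaluate_set(preds, truths, "exclusive", n_bootstrap=1)
        for head in ("indolent", "aggressive"):
            assert report.heads[head].roc_auc.point == pytest.approx(0.5, abs=0.08)

    def test_unknown_truth_label_rejected(self):
        with pytest.raises(ValueError):
            evaluate_set([_prediction("s", 0.5, 0.5)], ["atypical"], "exclusive")
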