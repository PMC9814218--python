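"""Slide-level evaluation: confusion counts, TPR/FPR, ROC-AUC, log loss,
accuracy/sensitivity/specificity, percentile-bootstrap confidence intervals,
and double-label acceptance scoring.

Each head (indolent, aggressive) is evaluated one-vs-rest: the truth is
binarized as ``truth == head`` and the score is that head's max-aggregated
slide probability. Hard calls come in two modes:

* ``exclusive`` — the slide's single collapsed label (``exclusive_label``)
  is compared against the truth;
* ``double_label_accept`` — a slide called both indolent and aggressive is
  accepted as correct when the truth is either of the two; operationally
  the double call is resolved to the truth when the truth is a member of
  the call set, and to the exclusive label otherwise. This only ever moves
  calls toward the truth, so accept-mode accuracy is never below
  exclusive-mode accuracy. ROC-AUC is threshold-free and always uses the
  raw per-head scores, identical in both modes.

Bootstrap intervals resample slides with replacement (percentile method,
95% by default, 1000 iterations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .wsi_inference import WSIPrediction

__all__ = [
    "ConfusionCounts",
    "MetricValue",
    "MetricReport",
    "UndefinedAUCError",
    "CIError",
    "confusion",
    "roc_auc",
    "log_loss",
    "bootstrap_ci",
    "evaluate_set",
]

HEADS = ("indolent", "aggressive")
LOG_LOSS_CLIP = 1e-15


class UndefinedAUCError(ValueError):
    """ROC-AUC is undefined when only one class is present."""


class CIError(ValueError):
    """Bootstrap CI failed (statistic undefined on most resamples)."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 cross-tabulation with the derived TPR/FPR rates.

    ``tpr`` = TP/(TP+FN) and ``fpr`` = FP/(FP+TN); a rate whose denominator
    is zero is NaN with the matching ``*_defined`` flag cleared.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr_defined(self) -> bool:
        return self.tp + self.fn > 0

    @property
    def fpr_defined(self) -> bool:
        return self.fp + self.tn > 0

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tpr_defined else math.nan

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fpr_defined else math.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tpr

    @property
    def specificity(self) -> float:
        return 1.0 - self.fpr if self.fpr_defined else math.nan


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Confusion counts for binary truth vs binary hard calls."""
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("y_true and y_pred must be equal-length non-empty 1-D sequences")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> tuple[list[tuple[float, float]], float]:
    """ROC curve (FPR, TPR points) and trapezoidal AUC.

    The curve sweeps the decision threshold over all distinct scores plus
    the endpoints; the resulting AUC equals the probability that a positive
    outranks a negative, ties counted one half (Mann-Whitney convention).
    """
    t = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=np.float64)
    if t.shape != s.shape or t.ndim != 1:
        raise ValueError("y_true and scores must be equal-length 1-D sequences")
    if len(np.unique(t)) < 2:
        raise UndefinedAUCError("ROC-AUC undefined: only one class present in y_true")
    fpr, tpr, _ = _sk_roc_curve(t, s, drop_intermediate=False)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def log_loss(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Mean binary cross-entropy with probabilities clipped to [1e-15, 1-1e-15]."""
    t = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(scores, dtype=np.float64)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("y_true and scores must be equal-length non-empty 1-D sequences")
    p = np.clip(p, LOG_LOSS_CLIP, 1.0 - LOG_LOSS_CLIP)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    y_true: Sequence[int],
    scores: Sequence[float],
    n_iter: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a statistic over slide-level resamples.

    Resamples on which the statistic raises (e.g. single-class AUC) are
    skipped; if more than half are degenerate the interval is refused.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    t = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(t)
    values = []
    skipped = 0
    for _ in range(n_iter):
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic(t[idx], s[idx])
        except (ValueError, ZeroDivisionError):
            skipped += 1
            continue
        if math.isnan(v):
            skipped += 1
            continue
        values.append(v)
    if skipped > n_iter / 2:
        raise CIError(f"statistic undefined on {skipped}/{n_iter} resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class MetricValue:
    point: float
    ci_low: float
    ci_high: float


@dataclass
class HeadMetrics:
    roc_auc: MetricValue
    log_loss: MetricValue
    accuracy: MetricValue
    sensitivity: MetricValue
    specificity: MetricValue
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        out = {}
        for name in ("roc_auc", "log_loss", "accuracy", "sensitivity", "specificity"):
            mv: MetricValue = getattr(self, name)
            out[name] = {"point": mv.point, "ci_low": mv.ci_low, "ci_high": mv.ci_high}
        out["counts"] = {"tp": self.counts.tp, "fp": self.counts.fp,
                         "tn": self.counts.tn, "fn": self.counts.fn}
        return out


@dataclass
class MetricReport:
    heads: dict[str, HeadMetrics]
    scoring_mode: str
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    n_slides: int = 0

    def as_dict(self) -> dict:
        return {
            "scoring_mode": self.scoring_mode,
            "n_bootstrap": self.n_bootstrap,
            "ci_level": self.ci_level,
            "n_slides": self.n_slides,
            "heads": {head: hm.as_dict() for head, hm in self.heads.items()},
        }


def resolve_calls(
    predictions: Sequence[WSIPrediction], truths: Sequence[str], mode: str
) -> list[str]:
    """Per-slide categorical calls under the chosen scoring mode."""
    calls = []
    for pred, truth in zip(predictions, truths):
        if mode == "double_label_accept" and pred.is_double_label and truth in pred.label_set:
            calls.append(truth)
        else:
            calls.append(pred.exclusive_label)
    return calls


def evaluate_set(
    predictions: Sequence[WSIPrediction],
    truths: Sequence[str],
    mode: str = "exclusive",
    n_bootstrap: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> MetricReport:
    """Per-head one-vs-rest metrics with bootstrap CIs over slides."""
    if mode not in ("exclusive", "double_label_accept"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths must align")
    bad = set(truths) - {"benign", "indolent", "aggressive"}
    if bad:
        raise ValueError(f"unknown truth label(s): {sorted(bad)}")
    calls = resolve_calls(predictions, truths, mode)
    rng = np.random.default_rng(seed)
    heads: dict[str, HeadMetrics] = {}
    for head in HEADS:
        y = np.array([int(t == head) for t in truths])
        yhat = np.array([int(c == head) for c in calls])
        s = np.array([p.score(head) for p in predictions])
        counts = confusion(y, yhat)
        _, auc_pt = roc_auc(y, s)
        ll_pt = log_loss(y, s)

        def _auc(t, sc):
            return roc_auc(t, sc)[1]

        def _from_calls(stat_name):
            # bootstrap the hard-call statistic by resampling (truth, call) pairs
            def stat(t, pair):
                c = confusion(t, pair)
                return getattr(c, stat_name)

            return stat

        auc_ci = bootstrap_ci(_auc, y, s, n_bootstrap, ci_level, rng)
        ll_ci = bootstrap_ci(lambda t, sc: log_loss(t, sc), y, s, n_bootstrap, ci_level, rng)
        acc_ci = bootstrap_ci(_from_calls("accuracy"), y, yhat, n_bootstrap, ci_level, rng)
        sen_ci = bootstrap_ci(_from_calls("sensitivity"), y, yhat, n_bootstrap, ci_level, rng)
        spe_ci = bootstrap_ci(_from_calls("specificity"), y, yhat, n_bootstrap, ci_level, rng)
        heads[head] = HeadMetrics(
            roc_auc=MetricValue(auc_pt, *auc_ci),
            log_loss=MetricValue(ll_pt, *ll_ci),
            accuracy=MetricValue(counts.accuracy, *acc_ci),
            sensitivity=MetricValue(counts.sensitivity, *sen_ci),
            specificity=MetricValue(counts.specificity, *spe_ci),
            counts=counts,
        )
    return MetricReport(
        heads=heads,
        scoring_mode=mode,
        n_bootstrap=n_bootstrap,
        ci_level=ci_level,
        n_slides=len(predictions),
    )
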