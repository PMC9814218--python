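"""Rater agreement statistics for the three-way slide classification.

Inter-rater agreement across two or more raters uses Bennett's S (the
"S-score"): mean pairwise percent agreement P̄o, chance-corrected with the
uniform-chance baseline 1/c over the c=3 categories,
S = (c·P̄o − 1)/(c − 1). Intra-rater (test-retest) agreement for one rater's
two sessions uses the weighted kappa with distance weights over the ordered
categories benign < indolent < aggressive (linear by default, quadratic
optional).

Interpretation bands: ≤0 poor, (0, 0.20] slight, (0.20, 0.40] fair,
(0.40, 0.60] moderate, (0.60, 0.80] substantial, (0.80, 1.00] almost
perfect. Intervals are left-open/right-closed so every value in (−∞, 1]
maps to exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .wsi_inference import WSIPrediction

__all__ = [
    "CATEGORIES",
    "RatingMatrix",
    "AgreementResult",
    "s_score",
    "weighted_kappa",
    "interpret_agreement",
    "sample_reliability_cohort",
    "read_rating_matrix",
]

CATEGORIES = ("benign", "indolent", "aggressive")


@dataclass
class RatingMatrix:
    """Items x raters categorical ratings with no missing cells."""

    ratings: pd.DataFrame  # index = item ids, columns = rater ids

    def __post_init__(self) -> None:
        if self.ratings.isna().any().any():
            raise ValueError("rating matrix has missing cells")
        bad = set(self.ratings.values.ravel()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"ratings outside category set: {sorted(bad)}")

    @property
    def items(self) -> list:
        return list(self.ratings.index)

    @property
    def raters(self) -> list:
        return list(self.ratings.columns)

    @property
    def n_categories(self) -> int:
        return len(CATEGORIES)


@dataclass(frozen=True)
class AgreementResult:
    value: float
    interpretation: str


def interpret_agreement(value: float) -> str:
    """Map an agreement coefficient to the verbal scale."""
    if not np.isfinite(value):
        raise ValueError("agreement value must be finite")
    if value > 1.0:
        raise ValueError(f"agreement value {value} exceeds 1")
    if value <= 0.0:
        return "poor"
    if value <= 0.20:
        return "slight"
    if value <= 0.40:
        return "fair"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "substantial"
    return "almost perfect"


def s_score(matrix: RatingMatrix) -> AgreementResult:
    """Multi-rater Bennett S: chance-corrected mean pairwise agreement.

    P̄o is the mean over items of the fraction of agreeing rater pairs;
    S = (c·P̄o − 1)/(c − 1) with c = 3.
    """
    values = matrix.ratings.to_numpy()
    n_items, n_raters = values.shape
    if n_raters < 2:
        raise ValueError("S-score needs at least two raters")
    if n_items < 1:
        raise ValueError("S-score needs at least one item")
    n_pairs = n_raters * (n_raters - 1) / 2
    agree = np.zeros(n_items)
    for a, b in combinations(range(n_raters), 2):
        agree += values[:, a] == values[:, b]
    po = float(np.mean(agree / n_pairs))
    c = matrix.n_categories
    s = (c * po - 1.0) / (c - 1.0)
    return AgreementResult(value=s, interpretation=interpret_agreement(s))


def weighted_kappa(
    session1: Sequence[str],
    session2: Sequence[str],
    weights: str = "linear",
) -> AgreementResult:
    """Weighted kappa between one rater's two sessions.

    κw = 1 − Σ wij·oij / Σ wij·eij with observed proportions oij,
    chance-expected proportions eij from the marginal product, and weights
    wij = |i−j|/(c−1) (linear) or its square (quadratic) over the category
    order benign < indolent < aggressive.
    """
    if weights not in ("linear", "quadratic"):
        raise ValueError(f"unknown weight scheme {weights!r}")
    s1 = list(session1)
    s2 = list(session2)
    if len(s1) != len(s2):
        raise ValueError("sessions must have equal length")
    if not s1:
        raise ValueError("sessions are empty")
    bad = (set(s1) | set(s2)) - set(CATEGORIES)
    if bad:
        raise ValueError(f"ratings outside category set: {sorted(bad)}")
    c = len(CATEGORIES)
    index = {cat: i for i, cat in enumerate(CATEGORIES)}
    n = len(s1)
    observed = np.zeros((c, c))
    for a, b in zip(s1, s2):
        observed[index[a], index[b]] += 1
    observed /= n
    marg1 = observed.sum(axis=1)
    marg2 = observed.sum(axis=0)
    expected = np.outer(marg1, marg2)
    ij = np.arange(c)
    w = np.abs(ij[:, None] - ij[None, :]) / (c - 1)
    if weights == "quadratic":
        w = w**2
    expected_disagreement = float((w * expected).sum())
    observed_disagreement = float((w * observed).sum())
    if expected_disagreement == 0.0:
        # both sessions concentrated on a single category pair with no
        # chance-expected disagreement; agreement is perfect iff observed
        # disagreement is zero, otherwise the statistic is degenerate
        if observed_disagreement == 0.0:
            return AgreementResult(value=1.0, interpretation=interpret_agreement(1.0))
        raise ZeroDivisionError(
            "degenerate weighted kappa: zero expected but nonzero observed disagreement"
        )
    kappa = 1.0 - observed_disagreement / expected_disagreement
    return AgreementResult(value=kappa, interpretation=interpret_agreement(kappa))


def sample_reliability_cohort(
    predictions: Sequence[WSIPrediction],
    truths: Sequence[str],
    n_per_cohort: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the four reliability-study cohorts from model outputs.

    Cohorts mirror the reader-study design: true-negative benign slides,
    true-positive indolent, double-label calls, and true-positive
    aggressive, each sampled without replacement.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pool = list(zip(predictions, truths))

    def pick(filt, cohort):
        matching = [(p, t) for p, t in pool if filt(p, t)]
        if len(matching) < n_per_cohort:
            raise ValueError(
                f"cohort {cohort!r} needs {n_per_cohort} slides, found {len(matching)}"
            )
        idx = rng.choice(len(matching), size=n_per_cohort, replace=False)
        for i in sorted(idx):
            p, t = matching[i]
            rows.append({"slide_id": p.slide_id, "cohort": cohort,
                         "truth": t, "predicted": "&".join(sorted(p.label_set)) or "benign"})

    pick(lambda p, t: t == "benign" and p.exclusive_label == "benign", "true_negative")
    pick(lambda p, t: t == "indolent" and p.label_set == {"indolent"}, "true_positive_indolent")
    pick(lambda p, t: p.is_double_label, "double_label")
    pick(lambda p, t: t == "aggressive" and p.label_set == {"aggressive"}, "true_positive_aggressive")
    return pd.DataFrame(rows)


def read_rating_matrix(path: str | Path) -> RatingMatrix:
    """Read a ratings CSV (rows = items, columns = raters, cells = categories)."""
    table = pd.read_csv(path, index_col=0, dtype=str)
    return RatingMatrix(ratings=table)
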