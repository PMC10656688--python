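"""Diagnostic performance and inter-rater agreement statistics.

Covers confusion-matrix metrics with integer-percent reporting,
tie-aware ordinal ROC/AUC with DeLong variance and the paired DeLong
test, Cohen's kappa with interpretation bins, McNemar's test on
discordant pairs, and overall/conditional percent agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "round_percent",
    "confusion_metrics",
    "auc_ordinal",
    "delong_ci",
    "delong_paired_test",
    "cohen_kappa",
    "mcnemar",
    "percent_agreement",
    "conditional_agreement",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


def round_percent(numerator: float, denominator: float) -> int:
    """Integer percent, rounding half away from zero (94.5 -> 95)."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _ratio(name: str, num: int, den: int) -> float:
    if den == 0:
        raise ZeroDivisionError(f"{name} undefined: zero denominator")
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Standard binary diagnostic metrics as proportions.

    Combine with :func:`round_percent` for integer-percent reporting.
    """
    c = counts
    return {
        "sensitivity": _ratio("sensitivity", c.tp, c.tp + c.fn),
        "specificity": _ratio("specificity", c.tn, c.tn + c.fp),
        "ppv": _ratio("ppv", c.tp, c.tp + c.fp),
        "npv": _ratio("npv", c.tn, c.tn + c.fn),
        "fp_rate": _ratio("fp_rate", c.fp, c.tn + c.fp),
        "fn_rate": _ratio("fn_rate", c.fn, c.tp + c.fn),
        "accuracy": _ratio("accuracy", c.tp + c.tn,
                           c.tp + c.fp + c.fn + c.tn),
    }


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong structural components

def _validate_binary(truth) -> np.ndarray:
    t = np.asarray(truth, dtype=int)
    if set(np.unique(t)) - {0, 1}:
        raise ValueError("truth must be binary 0/1")
    if t.sum() == 0 or t.sum() == t.size:
        raise ValueError("both classes must be present")
    return t

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(ratings, truth):
    """Structural components (V10 per positive, V01 per negative)."""
    r = np.asarray(ratings, dtype=float)
    t = _validate_binary(truth)
    pos, neg = r[t == 1], r[t == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def auc_ordinal(ratings, truth) -> float:
    """Mann-Whitney AUC with half credit for ties."""
    v10, _ = _delong_components(ratings, truth)
    return float(v10.mean())


def delong_ci(ratings, truth, level: float = 0.95):
    """(AUC, lower, upper) normal-approximation CI via DeLong variance."""
    v10, v01 = _delong_components(ratings, truth)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    se = math.sqrt(s10 / v10.size + s01 / v01.size)
    z = stats.norm.ppf(0.5 + level / 2)
    return auc, max(0.0, auc - z * se), min(1.0, auc + z * se)


def delong_paired_test(ratings_a, ratings_b, truth):
    """Two-sided paired DeLong test for correlated AUCs.

    Returns (z, p).  Identical rating vectors give z = 0, p = 1.
    """
    va10, va01 = _delong_components(ratings_a, truth)
    vb10, vb01 = _delong_components(ratings_b, truth)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = va10.size, va01.size

    def _cov(x, y):
        return np.cov(x, y, ddof=1)[0, 1] if x.size > 1 else 0.0

    var = (va10.var(ddof=1) + vb10.var(ddof=1) - 2 * _cov(va10, vb10)) / m \
        + (va01.var(ddof=1) + vb01.var(ddof=1) - 2 * _cov(va01, vb01)) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    z = diff / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(1.0, p))


# ---------------------------------------------------------------------------
# agreement

_BIN_EPS = 1e-9  # bin edges are inclusive despite float arithmetic


def kappa_bin(kappa: float) -> str:
    """Interpretation bins: 0.4-0.59 weak, 0.6-0.79 moderate,
    0.8-0.9 strong, above 0.9 perfect, below 0.4 unlabelled ("below
    weak")."""
    if kappa < 0.4 - _BIN_EPS:
        return "below weak"
    if kappa < 0.6 - _BIN_EPS:
        return "weak"
    if kappa < 0.8 - _BIN_EPS:
        return "moderate"
    if kappa <= 0.9 + _BIN_EPS:
        return "strong"
    return "perfect"


def cohen_kappa(table) -> tuple[float, str]:
    """Cohen's kappa of a square cross-tabulation, plus its bin."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    if np.any(t < 0):
        raise ValueError("agreement table must be non-negative")
    n = t.sum()
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = np.trace(t) / n
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n ** 2
    if abs(1 - p_e) < 1e-12:
        raise ValueError("degenerate marginals: chance agreement is 1")
    kappa = (p_o - p_e) / (1 - p_e)
    return float(kappa), kappa_bin(kappa)


def mcnemar(discordant_b: int, discordant_c: int) -> tuple[Optional[float], float]:
    """McNemar's test on the two discordant cell counts.

    Exact two-sided binomial for b + c < 25, else chi-square with
    continuity correction (|b - c| - 1)^2 / (b + c).  Returns
    (statistic or None for the exact branch, p).
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return None, 1.0  # degenerate input: no discordant pairs
    if n < 25:
        p = 2 * stats.binom.cdf(min(b, c), n, 0.5)
        return None, float(min(1.0, p))
    stat = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return stat, min(1.0, p)


def percent_agreement(labels_a: Sequence, labels_b: Sequence) -> int:
    """Overall agreement rate as an integer percent."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    if not labels_a:
        raise ValueError("empty label vectors")
    matches = sum(a == b for a, b in zip(labels_a, labels_b))
    return round_percent(matches, len(labels_a))


def conditional_agreement(labels_a: Sequence, labels_b: Sequence,
                          category) -> int:
    """Agreement (integer percent) among items rated ``category`` by A."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    stratum = [(a, b) for a, b in zip(labels_a, labels_b) if a == category]
    if not stratum:
        raise ValueError(f"no items rated {category!r} by the first rater")
    matches = sum(a == b for a, b in stratum)
    return round_percent(matches, len(stratum))
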