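"""Diagnostic-test evaluation of decoder predictions.

Disease is the positive class.  The five metrics are the standard
ratios:

    Se  = TP / (TP + FN)        sensitivity
    Sp  = TN / (TN + FP)        specificity
    PPV = TP / (TP + FP)        positive predictive value
    NPV = TN / (TN + FN)        negative predictive value
    Acc = (TP + TN) / total     accuracy

A zero denominator makes that metric undefined; it is reported as
missing with a warning, never silently as 0.  Decision-score separation
between groups is tested with the Mann-Whitney U: exact two-sided p by
enumeration for small samples, a tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .decoder import ScoreSet


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    def as_table(self) -> str:
        """Plain-text confusion table, disease rows first."""
        lines = [
            f"{'':>16}{'pred disease':>14}{'pred healthy':>14}{'total':>8}",
            f"{'true disease':>16}{self.TP:>14}{self.FN:>14}{self.TP + self.FN:>8}",
            f"{'true healthy':>16}{self.FP:>14}{self.TN:>14}{self.FP + self.TN:>8}",
            f"{'total':>16}{self.TP + self.FP:>14}{self.FN + self.TN:>14}{self.total:>8}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class Metrics:
    """The five diagnostic ratios; None marks an undefined metric."""

    Se: float | None
    Sp: float | None
    PPV: float | None
    NPV: float | None
    Acc: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {"Se": self.Se, "Sp": self.Sp, "PPV": self.PPV,
                "NPV": self.NPV, "Acc": self.Acc}

    def as_percent(self, decimals: int | None = None) -> dict[str, float | None]:
        """Percent view; decimals=None keeps full precision, 0/1 mimic
        the two printed conventions (nearest integer, one decimal)."""
        out = {}
        for k, v in self.as_dict().items():
            if v is None:
                out[k] = None
            else:
                pct = 100.0 * v
                out[k] = pct if decimals is None else round(pct, decimals)
        return out


def confusion(scoreset: ScoreSet) -> ConfusionMatrix:
    """Count predictions against truth with disease = positive."""
    if len(scoreset.subject_ids) == 0:
        raise ValueError("cannot build a confusion matrix from an empty score set")
    true = scoreset.true
    pred = scoreset.predicted
    return ConfusionMatrix(
        TP=int(np.sum((true == 1) & (pred == 1))),
        FN=int(np.sum((true == 1) & (pred == -1))),
        FP=int(np.sum((true == -1) & (pred == 1))),
        TN=int(np.sum((true == -1) & (pred == -1))),
    )


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as missing",
                      stacklevel=3)
        return None
    return num / den


def metrics(cm: ConfusionMatrix) -> Metrics:
    """The five diagnostic ratios from the confusion counts."""
    return Metrics(
        Se=_ratio(cm.TP, cm.TP + cm.FN, "Se"),
        Sp=_ratio(cm.TN, cm.TN + cm.FP, "Sp"),
        PPV=_ratio(cm.TP, cm.TP + cm.FP, "PPV"),
        NPV=_ratio(cm.TN, cm.TN + cm.FN, "NPV"),
        Acc=_ratio(cm.TP + cm.TN, cm.total, "Acc"),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: pairs with x > y, ties counted half."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(
    scores_a,
    scores_b,
    exact_max_n: int = 12,
) -> tuple[float, float, str]:
    """Mann-Whitney U of sample a versus sample b, two-sided p.

    For combined n <= exact_max_n the null distribution of U is built by
    enumerating every assignment of the pooled values to the two groups
    (ties handled naturally by the pooled multiset); otherwise a normal
    approximation with tie-corrected variance and continuity correction
    is used.  Returns (U, p_two_sided, method).
    """
    x = np.asarray(scores_a, dtype=float)
    y = np.asarray(scores_b, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return u, 1.0, "degenerate"

    if n + m <= exact_max_n:
        total = comb(n + m, n)
        lo = hi = 0
        idx = np.arange(n + m)
        for pick in combinations(idx, n):
            sel = np.zeros(n + m, dtype=bool)
            sel[list(pick)] = True
            u_perm = _u_statistic(pooled[sel], pooled[~sel])
            if u_perm <= u:
                lo += 1
            if u_perm >= u:
                hi += 1
        p = min(1.0, 2.0 * min(lo / total, hi / total))
        return u, p, "exact"

    # tie-corrected normal approximation with continuity correction
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        warnings.warn("zero variance under ties; p = 1", stacklevel=2)
        return u, 1.0, "degenerate"
    mu = n * m / 2.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    return u, p, "normal_approx"


def score_separation(scoreset: ScoreSet) -> tuple[float, float, str]:
    """Mann-Whitney comparison of disease vs healthy decision scores."""
    d = scoreset.scores[scoreset.true == 1]
    h = scoreset.scores[scoreset.true == -1]
    return mann_whitney(d, h)
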