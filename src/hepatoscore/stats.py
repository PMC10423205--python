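"""Statistical toolkit for the score comparisons.

Pearson correlation with Fisher-z confidence intervals and the weak /
moderate / strong interpretation bands; empirical ROC curves with
Mann-Whitney AUC (ties counted 1/2), Hanley-McNeil or DeLong confidence
intervals and the excellent..failed interpretation bands; Youden-index
cut-offs reported at midpoints between adjacent observed scores; the
closed-form binormal AUC; one-way ANOVA with Tukey HSD pairwise
comparisons; and the D'Agostino-Pearson omnibus normality test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multicomp import pairwise_tukeyhsd

Direction = Literal["higher", "lower"]


# ---------------------------------------------------------------- correlation

@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_two_tailed: float
    n: int
    interpretation: str


def interpret_correlation(r: float) -> str:
    """Band an absolute correlation: strong > 0.5, moderate (0.3, 0.5], else weak."""
    a = abs(r)
    if a > 0.5:
        return "strong"
    if a > 0.3:
        return "moderate"
    return "weak"


def pearson(x: Sequence[float], y: Sequence[float], confidence: float = 0.95) -> CorrelationResult:
    """Pearson r with a Fisher-z CI and a two-tailed t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise ValueError("at least 3 paired observations required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=confidence)
    return CorrelationResult(
        r=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_two_tailed=float(res.pvalue),
        n=len(x),
        interpretation=interpret_correlation(res.statistic),
    )


# ------------------------------------------------------------------------ ROC

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray  # fractions, parallel to thresholds
    specificities: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    cutoff_sensitivity: float  # percent
    cutoff_specificity: float  # percent
    youden_j: float
    interpretation: str
    direction: Direction
    n_positive: int
    n_negative: int


def interpret_auc(auc: float) -> str:
    """AUC bands: 0.9-1 excellent, 0.8-0.9 good, 0.7-0.8 fair, 0.6-0.7 poor,
    below 0.6 failed (bands left-closed, so 0.8 reads 'good')."""
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.8:
        return "good"
    if auc >= 0.7:
        return "fair"
    if auc >= 0.6:
        return "poor"
    return "failed"


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int,
                      confidence: float = 0.95) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc * auc)
           + (n_neg - 1) * (q2 - auc * auc)) / (n_pos * n_neg)
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return max(0.0, auc - half), min(1.0, auc + half)


def _delong_ci(scores_pos: np.ndarray, scores_neg: np.ndarray, auc: float,
               confidence: float = 0.95) -> tuple[float, float]:
    # placement values: for each positive, fraction of negatives it outranks
    m, n = len(scores_pos), len(scores_neg)
    v10 = np.array([(np.sum(scores_neg < s) + 0.5 * np.sum(scores_neg == s)) / n
                    for s in scores_pos])
    v01 = np.array([(np.sum(scores_pos > s) + 0.5 * np.sum(scores_pos == s)) / m
                    for s in scores_neg])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def youden_cutoff(scores: Sequence[float], labels: Sequence[bool],
                  direction: Direction = "higher") -> tuple[float, float, float, float]:
    """Youden-optimal cut-off over midpoints between adjacent distinct scores.

    Returns (cutoff, sensitivity %, specificity %, J).  Ties are broken
    toward higher sensitivity, then the lower threshold value.  With
    ``direction="higher"`` a case is called positive when its score exceeds
    the cut-off; with ``"lower"`` when it falls below.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    u = np.unique(scores)
    if len(u) == 1:
        return float(u[0]), 0.0, 100.0, 0.0
    candidates = (u[:-1] + u[1:]) / 2.0

    # counts above/below each candidate via sorted-array bisection; midpoints
    # between adjacent distinct scores never coincide with an observed score
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    if direction == "higher":
        sens = (n_pos - np.searchsorted(pos_sorted, candidates, side="right")) / n_pos
        spec = np.searchsorted(neg_sorted, candidates, side="right") / n_neg
    else:
        sens = np.searchsorted(pos_sorted, candidates, side="left") / n_pos
        spec = (n_neg - np.searchsorted(neg_sorted, candidates, side="left")) / n_neg
    j = sens + spec - 1.0
    # ties: higher sensitivity first, then the lower threshold value
    order = np.lexsort((-candidates, sens, j))
    k = order[-1]
    return float(candidates[k]), 100.0 * sens[k], 100.0 * spec[k], float(j[k])


def roc(scores: Sequence[float], labels: Sequence[bool],
        positive_direction: Direction = "higher",
        ci_method: Literal["hanley", "delong"] = "hanley",
        confidence: float = 0.95) -> RocResult:
    """Empirical ROC analysis of a score against a binary outcome.

    ``positive_direction`` states which end of the score indicates the
    positive class (MELIF: "lower" marks impairment; ALBI/MELD: "higher").
    AUC is the Mann-Whitney probability that a random positive outranks a
    random negative, ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present in the sample")

    oriented = scores if positive_direction == "higher" else -scores
    auc = float(roc_auc_score(labels, oriented))
    fpr, tpr, thr = roc_curve(labels, oriented, drop_intermediate=False)
    if positive_direction == "lower":
        thr = -thr

    if ci_method == "delong":
        lo, hi = _delong_ci(oriented[labels], oriented[~labels], auc, confidence)
    elif ci_method == "hanley":
        lo, hi = _hanley_mcneil_ci(auc, n_pos, n_neg, confidence)
    else:
        raise ValueError(f"unknown CI method {ci_method!r}")

    cutoff, sens, spec, j = youden_cutoff(scores, labels, positive_direction)
    return RocResult(
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=auc,
        auc_ci_low=lo,
        auc_ci_high=hi,
        cutoff=cutoff,
        cutoff_sensitivity=sens,
        cutoff_specificity=spec,
        youden_j=j,
        interpretation=interpret_auc(auc),
        direction=positive_direction,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def binormal_auc(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Closed-form AUC for two normal score distributions:
    Phi(|mean1 - mean2| / sqrt(sd1^2 + sd2^2))."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("at least one standard deviation must be positive")
    return float(sps.norm.cdf(abs(mean1 - mean2) / np.hypot(sd1, sd2)))


# ---------------------------------------------------------------------- ANOVA

@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    group_means: dict
    pairwise: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj, reject


def anova_oneway(groups: Sequence[Sequence[float]],
                 labels: Sequence[str] | None = None,
                 alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey-HSD-adjusted all-pairs comparisons."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    f, p = sps.f_oneway(*groups)
    if all(np.var(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        f, p = 0.0, 1.0  # identical constant groups: no variance anywhere
    data = np.concatenate(groups)
    tags = np.concatenate([[lab] * len(g) for lab, g in zip(labels, groups)])
    tk = pairwise_tukeyhsd(data, tags, alpha=alpha)
    pairs = list(zip(*np.triu_indices(len(tk.groupsunique), k=1)))
    pairwise = pd.DataFrame({
        "group1": [str(tk.groupsunique[i]) for i, _ in pairs],
        "group2": [str(tk.groupsunique[j]) for _, j in pairs],
        "mean_diff": np.asarray(tk.meandiffs, dtype=float),
        "p_adj": np.asarray(tk.pvalues, dtype=float),
        "reject": np.asarray(tk.reject, dtype=bool),
    })
    means = {lab: float(np.mean(g)) for lab, g in zip(labels, groups)}
    return AnovaResult(float(f), float(p), means, pairwise)


def dagostino_pearson(x: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson K^2 omnibus normality test (chi-square, 2 df)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 20:
        raise ValueError("D'Agostino-Pearson test needs n >= 20")
    if np.std(x) == 0:
        raise ValueError("degenerate input: zero variance")
    k2, p = sps.normaltest(x)
    return float(k2), float(p)
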