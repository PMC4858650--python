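"""The study's statistical battery.

Group comparisons use one-way fixed-effects ANOVA followed by a
Newman-Keuls stepwise post hoc on the studentized range; linear
association uses the Pearson coefficient with a two-tailed t test;
diagnostic performance uses the empirical ROC with midrank tie handling;
and paired AUC differences are tested with DeLong's nonparametric
placement-value method.  Results are expressed as mean +/- SEM.

No multiple-testing correction is applied across the correlation table;
reports flag this explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.stats as st

__all__ = [
    "CorrelationResult",
    "PosthocPair",
    "AnovaResult",
    "ROCResult",
    "AUCComparison",
    "GroupSummary",
    "pearson",
    "anova_nk",
    "roc",
    "delong_compare",
    "percent_change",
    "group_summary",
]


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_two_tailed: float


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-tailed test.

    The p-value comes from ``t = r sqrt((n-2) / (1-r^2))`` referred to the
    t distribution with ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = st.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=n, p_two_tailed=float(p))


# ---------------------------------------------------------------------------
# One-way ANOVA + Newman-Keuls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosthocPair:
    group_i: int
    group_j: int
    span: int
    q: float
    p_nk: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    posthoc: tuple


@lru_cache(maxsize=256)
def _q_crit(alpha: float, span: int, df: int) -> float:
    return float(st.studentized_range.ppf(1.0 - alpha, span, df))


def anova_nk(groups, alpha: float = 0.05, pair_pvalues: bool = True) -> AnovaResult:
    """One-way ANOVA with a Newman-Keuls stepwise post hoc.

    Groups are compared on the studentized range statistic
    ``q = |m_i - m_j| / sqrt(MSE / n_h)`` (``n_h`` the harmonic mean of the
    two group sizes) at span-dependent critical values, stepping from the
    widest span inward; a pair nested inside a non-significant span is
    never declared significant (the standard non-rejection blocking rule).

    ``pair_pvalues=False`` skips the per-pair studentized-range p-values
    (significance flags are unaffected); useful in tight Monte Carlo loops.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrs):
        if g.ndim != 1 or g.size < 2:
            raise ValueError(f"group {i} must have at least 2 observations")

    ns = np.array([g.size for g in arrs])
    means = np.array([g.mean() for g in arrs])
    N = int(ns.sum())
    df_b, df_w = k - 1, N - k
    ss_w = float(sum(((g - m) ** 2).sum() for g, m in zip(arrs, means)))
    grand = float(np.concatenate(arrs).mean())
    ss_b = float((ns * (means - grand) ** 2).sum())
    mse = ss_w / df_w
    if mse == 0.0:
        F = 0.0 if ss_b == 0.0 else math.inf
    else:
        F = (ss_b / df_b) / mse
    p = 1.0 if F == 0.0 else float(st.f.sf(F, df_b, df_w))

    # Newman-Keuls on means sorted ascending.
    order = np.argsort(means, kind="stable")
    sig = {}  # (lo, hi) in sorted order -> bool
    pairs = []
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            i, j = int(order[lo]), int(order[hi])
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            diff = abs(means[j] - means[i])
            q = diff / math.sqrt(mse / n_h) if mse > 0 else (math.inf if diff > 0 else 0.0)
            blocked = any(
                not sig[(lo2, hi2)]
                for (lo2, hi2) in sig
                if lo2 <= lo and hi <= hi2 and (lo2, hi2) != (lo, hi)
            )
            significant = (not blocked) and q > _q_crit(alpha, span, df_w)
            sig[(lo, hi)] = significant
            if pair_pvalues:
                p_nk = float(st.studentized_range.sf(q, span, df_w)) if np.isfinite(q) else 0.0
            else:
                p_nk = math.nan
            pairs.append(
                PosthocPair(group_i=min(i, j), group_j=max(i, j), span=span,
                            q=float(q), p_nk=p_nk, significant=bool(significant))
            )
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p,
                       posthoc=tuple(pairs))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    one_minus_specificities: np.ndarray
    auc: float
    direction: str
    positive_class_definition: str


def _oriented(scores, direction):
    scores = np.asarray(scores, dtype=float)
    if direction == "higher":
        return scores
    if direction == "lower":
        return -scores
    raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")


def _check_labels(labels):
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary (0/1)")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(bool)


def roc(
    scores,
    labels,
    direction: str = "higher",
    positive_class_definition: str = "positive",
) -> ROCResult:
    """Empirical ROC curve and AUC with midrank tie handling.

    ``direction='lower'`` declares that low scores indicate the positive
    class (the liver-uptake index falls with disease severity); scores are
    negated internally and the orientation is recorded in the result.  The
    trapezoidal area of the stored curve equals the Mann-Whitney AUC.
    """
    y = _check_labels(labels)
    s = _oriented(scores, direction)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")

    thresholds = np.unique(s)[::-1]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    tpr = [0.0]
    fpr = [0.0]
    for thr in thresholds:
        tpr.append(float((s[y] >= thr).sum()) / n_pos)
        fpr.append(float((s[~y] >= thr).sum()) / n_neg)
    tpr = np.asarray(tpr)
    fpr = np.asarray(fpr)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds,
        sensitivities=tpr,
        one_minus_specificities=fpr,
        auc=auc,
        direction=direction,
        positive_class_definition=positive_class_definition,
    )


# ---------------------------------------------------------------------------
# DeLong paired AUC comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AUCComparison:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_two_tailed: float


def _placements(scores, y):
    """AUC and DeLong placement values for one score vector."""
    x = scores[y]
    v = scores[~y]
    psi = (x[:, None] > v[None, :]).astype(float)
    psi += 0.5 * (x[:, None] == v[None, :])
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    return float(v10.mean()), v10, v01


def delong_compare(scores_a, scores_b, labels, direction: str = "higher") -> AUCComparison:
    """DeLong test for the difference of two correlated (paired) AUCs.

    Both score vectors must be measured on the same subjects.  The
    variance of ``auc_a - auc_b`` is estimated from the empirical
    covariance of the placement values; ``z`` is referred to the standard
    normal, two-tailed.  Swapping the two score vectors negates ``z`` and
    leaves the p-value unchanged.
    """
    y = _check_labels(labels)
    sa = _oriented(scores_a, direction)
    sb = _oriented(scores_b, direction)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length (paired)")

    auc_a, v10a, v01a = _placements(sa, y)
    auc_b, v10b, v01b = _placements(sb, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2.0 * s10[0, 1]) / m
    var += (s01[0, 0] + s01[1, 1] - 2.0 * s01[0, 1]) / n
    var = max(float(var), 0.0)
    diff = auc_a - auc_b
    if var == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if z == 0.0 else float(2.0 * st.norm.sf(abs(z)))
    return AUCComparison(auc_a=auc_a, auc_b=auc_b, var_diff=var, z=float(z),
                         p_two_tailed=p)


# ---------------------------------------------------------------------------
# Small helpers
# ---------------------------------------------------------------------------


def percent_change(reference: float, value: float) -> float:
    """Percent change relative to ``reference``; positive means a reduction."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (reference - value) / reference


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float
    sem_defined: bool


def group_summary(values_by_group) -> dict:
    """Mean and SEM (SD / sqrt(n), ddof=1) per group.

    A single-observation group gets ``sem = 0`` with ``sem_defined=False``.
    """
    out = {}
    for name, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        if v.size == 1:
            out[name] = GroupSummary(n=1, mean=float(v[0]), sem=0.0, sem_defined=False)
        else:
            sem = float(v.std(ddof=1) / math.sqrt(v.size))
            out[name] = GroupSummary(n=int(v.size), mean=float(v.mean()),
                                     sem=sem, sem_defined=True)
    return out
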