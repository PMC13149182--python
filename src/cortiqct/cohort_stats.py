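"""Cohort statistics: Levene, one-way ANOVA (raw and summary form) with LSD
post-hoc, empirical ROC with Youden cutoff, DeLong AUC variance/comparison,
and a closed-form binormal-mixture AUC.

Conventions
-----------
* Disease orientation: the morphometric markers *decrease* with disease, so
  the default ROC orientation is ``"lower"`` (a score at or below the cutoff
  flags disease).  ``"higher"`` is supported symmetrically.
* All p-values are two-sided; sensitivity/specificity are reported in percent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "RocResult",
    "DeLongResult",
    "levene_test",
    "anova_oneway",
    "anova_from_summary",
    "roc_points",
    "roc_youden",
    "delong_auc_variance",
    "delong_test",
    "binormal_auc",
]

_LSD_ALPHA = 0.05  # pairwise tests only follow a significant omnibus F


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, SD) triplet for one labelled group — the unit of the
    published summary tables and of summary-statistic ANOVA."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    lsd_pairs: tuple = ()   # (label_a, label_b, mean_diff, p) per pair
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.f_stat < 0:
            raise ValueError("F statistic must be non-negative")


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    orientation: str
    youden: float
    n_disease: int
    n_nondisease: int
    flags: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI does not bracket the AUC")


@dataclass(frozen=True)
class DeLongResult:
    z_stat: float
    p_value: float
    auc_a: float
    auc_b: float
    var_diff: float
    flags: tuple = ()


# ---------------------------------------------------------------------------
# Homoscedasticity and ANOVA
# ---------------------------------------------------------------------------

def levene_test(groups) -> tuple[float, float]:
    """Classic Levene test (absolute deviations from the group *means*).

    Returns ``(statistic, p)``.  Degenerate input where every group is
    constant yields ``(0.0, 1.0)`` rather than NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    if all(np.ptp(g) == 0 for g in arrays):
        return 0.0, 1.0
    stat, p = sps.levene(*arrays, center="mean")
    if not math.isfinite(stat):
        return 0.0, 1.0
    return float(stat), float(p)


def _lsd_pairs(labels, ns, means, msw, df_within):
    """Fisher LSD: unadjusted pairwise t-tests on the pooled within-group MS."""
    out = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        diff = means[i] - means[j]
        se = math.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = float(2.0 * sps.t.sf(abs(t), df_within))
        out.append((labels[i], labels[j], float(diff), p))
    return tuple(out)


def _anova_from_moments(labels, ns, means, ssw) -> AnovaResult:
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    k = len(ns)
    n_total = float(ns.sum())
    df_between = k - 1
    df_within = int(n_total) - k
    if df_within < 1:
        raise ValueError("need total n > number of groups")
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    msb = ssb / df_between
    msw = ssw / df_within
    flags = ()
    if msw == 0.0:
        if msb == 0.0:
            f, p = 0.0, 1.0
        else:
            f, p = math.inf, 0.0
            flags = ("degenerate_zero_within_variance",)
    else:
        f = msb / msw
        p = float(sps.f.sf(f, df_between, df_within))
    lsd = ()
    if p < _LSD_ALPHA and math.isfinite(msw):
        lsd = _lsd_pairs(labels, ns, means, msw, df_within)
    return AnovaResult(float(f), df_between, df_within, p, lsd, flags)


def anova_oneway(groups, labels=None) -> AnovaResult:
    """One-way ANOVA on raw per-group samples, with LSD pairwise comparisons
    when the omnibus test is significant at 0.05."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(arrays))]
    ns = [g.size for g in arrays]
    means = [float(g.mean()) for g in arrays]
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    return _anova_from_moments(list(labels), ns, means, ssw)


def anova_from_summary(summaries) -> AnovaResult:
    """One-way ANOVA from (n, mean, SD) triplets.

    F = [sum n_i (m_i - m)^2 / (k-1)] / [sum (n_i - 1) s_i^2 / (N-k)] with m
    the size-weighted grand mean; algebraically identical to the raw-data
    decomposition when the SDs use the n-1 denominator.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    for s in summaries:
        if s.n < 2:
            raise ValueError(f"group {s.label!r}: summary ANOVA needs n >= 2")
    labels = [s.label for s in summaries]
    ns = [s.n for s in summaries]
    means = [s.mean for s in summaries]
    ssw = float(sum((s.n - 1) * s.sd**2 for s in summaries))
    return _anova_from_moments(labels, ns, means, ssw)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def _validate_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be non-empty")
    return scores, labels


def _mann_whitney_auc(pos, neg) -> float:
    """AUC = P(pos > neg) + 0.5 P(pos == neg), via midranks."""
    combined = np.concatenate([pos, neg])
    ranks = sps.rankdata(combined)
    m, n = pos.size, neg.size
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def roc_points(scores, labels, orientation: str = "lower"):
    """Empirical ROC operating points over every distinct threshold.

    Returns ``(thresholds, sensitivity, specificity)`` as fractions, where a
    subject is called diseased when ``score <= threshold`` (orientation
    ``"lower"``) or ``score >= threshold`` (``"higher"``).
    """
    scores, labels = _validate_binary(scores, labels)
    if orientation not in ("lower", "higher"):
        raise ValueError(f"unknown orientation {orientation!r}")
    thresholds = np.unique(scores)
    dis = scores[labels]
    non = scores[~labels]
    if orientation == "lower":
        sens = (dis[None, :] <= thresholds[:, None]).mean(axis=1)
        spec = (non[None, :] > thresholds[:, None]).mean(axis=1)
    else:
        sens = (dis[None, :] >= thresholds[:, None]).mean(axis=1)
        spec = (non[None, :] < thresholds[:, None]).mean(axis=1)
    return thresholds, sens, spec


def roc_youden(scores, labels, orientation: str = "lower") -> RocResult:
    """Empirical ROC analysis with the Youden-optimal cutoff.

    AUC comes from the Mann-Whitney identity (ties counted 1/2); the 95% CI
    uses the DeLong single-AUC variance with a normal approximation,
    truncated to [0, 1].  Youden ties are broken toward higher sensitivity,
    then toward the lower threshold.
    """
    scores, labels = _validate_binary(scores, labels)
    dis = scores[labels]
    non = scores[~labels]
    oriented_dis = -dis if orientation == "lower" else dis
    oriented_non = -non if orientation == "lower" else non
    auc = _mann_whitney_auc(oriented_dis, oriented_non)

    thresholds, sens, spec = roc_points(scores, labels, orientation)
    youden = sens + spec - 1.0
    # lexicographic argmax: youden, then sensitivity, then prefer lower cutoff
    order = np.lexsort((-thresholds, sens, youden))
    best = order[-1]
    flags = ()
    ties = np.isclose(youden, youden[best]).sum()
    if ties > 1:
        flags = (f"youden_tie_{ties}",)

    var = delong_auc_variance(scores, labels, orientation=orientation)
    se = math.sqrt(max(var, 0.0))
    ci_low = max(0.0, auc - 1.959963984540054 * se)
    ci_high = min(1.0, auc + 1.959963984540054 * se)
    return RocResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        cutoff=float(thresholds[best]),
        sensitivity=float(sens[best] * 100.0),
        specificity=float(spec[best] * 100.0),
        orientation=orientation,
        youden=float(youden[best]),
        n_disease=int(labels.sum()),
        n_nondisease=int((~labels).sum()),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# DeLong structural components
# ---------------------------------------------------------------------------

def _placements(dis, non):
    """Placement values (structural components) of the Mann-Whitney AUC.

    ``v10[i]`` is the fraction of non-diseased scores beaten by diseased
    score i (ties 1/2); ``v01[j]`` symmetrically.  Their means both equal
    the AUC.
    """
    dis = np.asarray(dis, dtype=float)
    non = np.asarray(non, dtype=float)
    cmp = (dis[:, None] > non[None, :]).astype(float)
    cmp += 0.5 * (dis[:, None] == non[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_auc_variance(scores, labels, orientation: str = "lower") -> float:
    """DeLong variance estimate of a single empirical AUC."""
    scores, labels = _validate_binary(scores, labels)
    s = -scores if orientation == "lower" else scores
    v10, v01 = _placements(s[labels], s[~labels])
    m, n = v10.size, v01.size
    var10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    var01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return var10 / m + var01 / n


def delong_test(scores_a, scores_b, labels, orientation: str = "lower") -> DeLongResult:
    """Paired comparison of two correlated AUCs on the same subjects.

    Z = (AUC_a - AUC_b) / sqrt(Var(AUC_a - AUC_b)) with the covariance
    estimated from placement values; two-sided p from the standard normal.
    Degenerate variance (e.g. a marker compared with itself) yields
    Z = 0, p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("markers must be paired (same subjects)")
    scores_a, labels = _validate_binary(scores_a, labels)
    if orientation == "lower":
        scores_a, scores_b = -scores_a, -scores_b
    dis = labels
    v10_a, v01_a = _placements(scores_a[dis], scores_a[~dis])
    v10_b, v01_b = _placements(scores_b[dis], scores_b[~dis])
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m, n = v10_a.size, v01_a.size

    def _cov(x, y):
        if x.size < 2:
            return 0.0
        return float(np.cov(x, y, ddof=1)[0, 1])

    var_diff = (
        (_cov(v10_a, v10_a) + _cov(v10_b, v10_b) - 2 * _cov(v10_a, v10_b)) / m
        + (_cov(v01_a, v01_a) + _cov(v01_b, v01_b) - 2 * _cov(v01_a, v01_b)) / n
    )
    flags = ()
    if var_diff <= 1e-15:
        z, p = 0.0, 1.0
        flags = ("degenerate_variance",)
        var_diff = max(var_diff, 0.0)
    else:
        z = (auc_a - auc_b) / math.sqrt(var_diff)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return DeLongResult(float(z), p, auc_a, auc_b, float(var_diff), flags)


# ---------------------------------------------------------------------------
# Binormal working model
# ---------------------------------------------------------------------------

def binormal_auc(disease: GroupSummary, nondisease) -> float:
    """Closed-form AUC of a Gaussian diseased group against a Gaussian-mixture
    non-diseased group, lower-is-disease orientation.

    AUC = sum_j w_j Phi((mu_j - mu_d) / sqrt(sigma_j^2 + sigma_d^2)) with
    mixture weights w_j proportional to group sizes.  A component with zero
    variance on both sides degenerates to a step function (1, 1/2 or 0 by
    mean ordering).
    """
    components = list(nondisease)
    if not components:
        raise ValueError("need at least one non-diseased component")
    weights = np.array([c.n for c in components], dtype=float)
    weights /= weights.sum()
    total = 0.0
    for w, c in zip(weights, components):
        pooled = math.hypot(c.sd, disease.sd)
        if pooled == 0.0:
            term = 1.0 if c.mean > disease.mean else (0.5 if c.mean == disease.mean else 0.0)
        else:
            term = float(sps.norm.cdf((c.mean - disease.mean) / pooled))
        total += w * term
    return total
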