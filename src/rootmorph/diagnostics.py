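"""Diagnostic statistics: group comparison, ROC/AUC, Youden cut-offs, 2x2
accuracy metrics, test-retest ICC and the two-group sample-size formula.

Orientation convention throughout: CRT (conical) is the positive class and
*lower* metric values indicate CRT, so a tooth is classified positive when
its value falls strictly below the cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DiagnosticReport",
    "ContingencyMetrics",
    "SampleSizeSpec",
    "roc_curve",
    "roc_auc",
    "youden_cutoff",
    "classify",
    "contingency_metrics",
    "sample_size",
    "icc",
    "group_compare",
]


@dataclass
class ContingencyMetrics:
    """Standard 2x2 accuracy metrics; a ``None`` field means the denominator
    was zero and the metric is undefined (never silently reported as 0)."""

    Se: float | None
    Sp: float | None
    PV_pos: float | None
    PV_neg: float | None
    YI: float | None
    LR_pos: float | None
    LR_neg: float | None

    def as_dict(self) -> dict:
        return {
            "Se": self.Se, "Sp": self.Sp, "PV_pos": self.PV_pos,
            "PV_neg": self.PV_neg, "YI": self.YI,
            "LR_pos": self.LR_pos, "LR_neg": self.LR_neg,
        }


@dataclass
class DiagnosticReport:
    """Per-parameter ROC analysis with the Youden-optimal operating point."""

    parameter: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float | None = None
    se_at_cutoff: float | None = None
    sp_at_cutoff: float | None = None
    direction: str = "below_is_CRT"
    accuracy: ContingencyMetrics | None = None


def _curve_points(crt_values, nrt_values):
    crt = np.asarray(crt_values, dtype=np.float64)
    nrt = np.asarray(nrt_values, dtype=np.float64)
    if crt.size == 0 or nrt.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.unique(np.concatenate([crt, nrt]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    # rule: value < threshold -> positive (CRT)
    tpr = np.array([(crt < t).mean() for t in thresholds])
    fpr = np.array([(nrt < t).mean() for t in thresholds])
    return crt, nrt, thresholds, fpr, tpr


def roc_curve(crt_values, nrt_values, parameter: str = "") -> DiagnosticReport:
    """Empirical ROC with candidate thresholds at midpoints between adjacent
    distinct pooled values (plus sentinels at +-inf)."""
    crt, nrt, thresholds, fpr, tpr = _curve_points(crt_values, nrt_values)
    auc = float(np.trapezoid(tpr, fpr))
    return DiagnosticReport(
        parameter=parameter, fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc
    )


def roc_auc(crt_values, nrt_values, parameter: str = "") -> DiagnosticReport:
    """ROC report whose AUC equals the Mann-Whitney probability
    ``P(CRT < NRT) + 0.5 * P(tie)`` (the trapezoidal curve area agrees)."""
    return roc_curve(crt_values, nrt_values, parameter)


def mann_whitney_auc(crt_values, nrt_values) -> float:
    """Rank-based AUC, identical to the trapezoidal ROC area (tie-corrected)."""
    crt = np.asarray(crt_values, dtype=np.float64)
    nrt = np.asarray(nrt_values, dtype=np.float64)
    if crt.size == 0 or nrt.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([crt, nrt])
    ranks = stats.rankdata(pooled)
    r_crt = ranks[: crt.size].sum()
    # P(CRT < NRT) + 0.5 P(=) via the rank-sum identity
    u = r_crt - crt.size * (crt.size + 1) / 2.0
    return float(1.0 - u / (crt.size * nrt.size))


def youden_cutoff(report: DiagnosticReport, crt_values, nrt_values) -> DiagnosticReport:
    """Choose the threshold maximising YI = Se + Sp - 1; ties resolved to the
    smallest finite cut-off.  Fills the report's operating-point fields."""
    crt, nrt, thresholds, fpr, tpr = _curve_points(crt_values, nrt_values)
    yi = tpr - fpr
    qualifying = np.flatnonzero(yi >= yi.max() - 1e-15)
    # thresholds ascend, so the first qualifier is the smallest cut-off;
    # prefer a finite threshold over the -inf sentinel when YI ties
    finite = qualifying[np.isfinite(thresholds[qualifying])]
    best = int(finite[0] if finite.size else qualifying[0])
    report.cutoff = float(thresholds[best])
    report.se_at_cutoff = float(tpr[best])
    report.sp_at_cutoff = float(1.0 - fpr[best])
    return report


def classify(values, cutoff: float) -> np.ndarray:
    """Label values by the strict rule ``value < cutoff -> 'CRT'`` (boundary
    values are NRT)."""
    values = np.asarray(values, dtype=np.float64)
    return np.where(values < cutoff, "CRT", "NRT")


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def contingency_metrics(tp: int, fp: int, fn: int, tn: int) -> ContingencyMetrics:
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    yi = se + sp - 1.0 if se is not None and sp is not None else None
    lr_pos = None
    if se is not None and sp is not None and sp < 1.0:
        lr_pos = se / (1.0 - sp)
    lr_neg = None
    if se is not None and sp is not None and sp > 0.0:
        lr_neg = (1.0 - se) / sp
    return ContingencyMetrics(
        Se=se,
        Sp=sp,
        PV_pos=_ratio(tp, tp + fp),
        PV_neg=_ratio(tn, tn + fn),
        YI=yi,
        LR_pos=lr_pos,
        LR_neg=lr_neg,
    )


@dataclass(frozen=True)
class SampleSizeSpec:
    """Two-group mean-difference design with allocation ratio n1:n2 = 1:k."""

    k: float
    alpha: float = 0.05
    beta: float = 0.20
    sigma: float = 1.0
    delta: float = 1.0

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("allocation ratio k must be positive")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.sigma <= 0 or self.delta <= 0:
            raise ValueError("sigma and delta must be positive")


def sample_size(spec: SampleSizeSpec) -> tuple[int, int]:
    """n1 = ceil(((k+1)/k) * ((z_{a/2} + z_b) * sigma / delta)^2), n2 = ceil(k*n1);
    both floored at 2 per group."""
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0) + stats.norm.ppf(1.0 - spec.beta)
    n1 = math.ceil((spec.k + 1.0) / spec.k * (z * spec.sigma / spec.delta) ** 2)
    n1 = max(n1, 2)
    n2 = max(math.ceil(spec.k * n1), 2)
    return n1, n2


def second_group_size(k: float, n1: int) -> int:
    """n2 = ceil(k * n1) for a fixed first-group size."""
    if k <= 0 or n1 <= 0:
        raise ValueError("k and n1 must be positive")
    return math.ceil(k * n1)


def icc(occasion1, occasion2) -> float:
    """Two-way random-effects, absolute-agreement, single-measure ICC(2,1)
    for a test-retest design with two occasions.

    Computed from the ANOVA mean squares:
    ``(MS_rows - MS_err) / (MS_rows + (k-1) MS_err + k (MS_cols - MS_err)/n)``.
    """
    x = np.column_stack([np.asarray(occasion1, float), np.asarray(occasion2, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if np.isnan(x).any():
        raise ValueError("missing values are not supported")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom <= 0 or ms_rows <= 1e-30:
        raise ValueError("between-subject variance is zero; ICC undefined")
    return float((ms_rows - ms_err) / denom)


def group_compare(a_values, b_values, welch: bool = False) -> dict:
    """Two-sided two-sample t-test (pooled variance unless ``welch``) and
    Mann-Whitney rank-sum test."""
    a = np.asarray(a_values, dtype=np.float64)
    b = np.asarray(b_values, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t_stat):  # zero pooled variance
        if a.mean() == b.mean():
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = math.inf if a.mean() > b.mean() else -math.inf, 0.0
    u_stat, u_p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "t": float(t_stat),
        "t_p": float(t_p),
        "rank_stat": float(u_stat),
        "rank_p": float(u_p),
    }
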