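"""Discrimination, calibration, clinical-utility, reliability and survival
analyses.

AUCs use the Mann-Whitney estimator with half credit for ties; variances and
paired comparisons use the DeLong structural-component decomposition.
Survival uses the product-limit estimator and the two-group log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "SurvivalCurve",
    "ICCResult",
    "roc_auc_delong",
    "delong_paired_test",
    "performance_at_cutoff",
    "hosmer_lemeshow",
    "decision_curve",
    "icc_agreement",
    "km_curve",
    "logrank_test",
]


@dataclass
class ROCResult:
    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass
class SurvivalCurve:
    times: np.ndarray  # distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    median: float  # NaN when S never reaches 0.5
    q25: float  # first time S <= 0.75
    q75: float  # first time S <= 0.25

    def probability_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "ICC(2,1) two-way random, absolute agreement, single rater"
    flag: str | None = None


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), average over ties."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components V10 (cases), V01 (controls)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return float(auc), v10, v01


def roc_auc_delong(scores, labels, level: float = 0.95) -> ROCResult:
    """AUC with tie correction and a Wald DeLong confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(max(var, 0.0))
    return ROCResult(
        auc=auc,
        variance=float(var),
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        n_pos=m,
        n_neg=n,
    )


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided paired DeLong z-test for the difference of two AUCs.

    Returns ``(z, p)``.  A zero-variance difference (e.g. identical scores)
    yields ``(0.0, 1.0)``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have the same length")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-16:
        return (0.0, 1.0)
    z = diff / math.sqrt(var)
    return (float(z), float(2 * stats.norm.sf(abs(z))))


def performance_at_cutoff(scores, labels, cutoff: float) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) for ``score >= cutoff`` positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores >= cutoff
    tp = int((pos & (labels == 1)).sum())
    fn = int((~pos & (labels == 1)).sum())
    tn = int((~pos & (labels == 0)).sum())
    fp = int((pos & (labels == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    return (tp / (tp + fn), tn / (tn + fp), (tp + tn) / len(labels))


# ---------------------------------------------------------------------------
# Calibration and clinical utility
# ---------------------------------------------------------------------------


def hosmer_lemeshow(probs, labels, g: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow chi-square over g risk-quantile bins.

    Ties are kept in a single bin.  Returns ``(chi2, df, p)`` with
    ``df = n_bins - 2``; if binning degenerates to fewer than 3 distinct
    bins the statistic is still summed and compared on 1 df (or declared
    perfectly calibrated when chi2 is 0).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(probs) < g:
        raise ValueError(f"need at least g={g} observations")
    if np.any((probs <= 0) | (probs >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    try:
        bins = np.asarray(pd.qcut(probs, g, labels=False, duplicates="drop"), dtype=float)
        # constant input collapses every edge; qcut then leaves all bins NaN
        bins = np.nan_to_num(bins, nan=0.0).astype(int)
    except ValueError:
        bins = np.zeros(len(probs), dtype=int)
    chi2 = 0.0
    n_bins = 0
    for b in np.unique(bins):
        sel = bins == b
        e1 = probs[sel].sum()
        e0 = (1.0 - probs[sel]).sum()
        if e1 <= 0 or e0 <= 0:
            raise ValueError("a bin has zero expected count; reduce g")
        o1 = labels[sel].sum()
        o0 = sel.sum() - o1
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        n_bins += 1
    df = n_bins - 2
    if df < 1:
        return (float(chi2), df, 1.0 if chi2 < 1e-9 else float("nan"))
    return (float(chi2), df, float(stats.chi2.sf(chi2, df)))


def decision_curve(probs, labels, thresholds) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none.

    ``NB(pt) = TP/n - FP/n * pt / (1 - pt)`` with positives defined by
    ``prob >= pt``.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        w = pt / (1.0 - pt)
        pos = probs >= pt
        tp = (pos & (labels == 1)).sum()
        fp = (pos & (labels == 0)).sum()
        rows.append(
            {
                "threshold": pt,
                "net_benefit_model": tp / n - fp / n * w,
                "net_benefit_all": prevalence - (1 - prevalence) * w,
                "net_benefit_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------


def icc_agreement(ratings, level: float = 0.95) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is an ``n subjects x k raters`` array without missing cells.
    The confidence interval follows the standard F-based formulation with a
    Satterthwaite approximation for the lower/upper degrees of freedom.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be 2D (subjects x raters)")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite ratings are not supported")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or msr <= 1e-300:
        return ICCResult(icc=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                         flag="zero between-subject variance")
    icc = (msr - mse) / denom
    alpha = 1.0 - level
    if mse <= 0:  # identical raters: perfect agreement, degenerate F
        return ICCResult(icc=float(icc), ci_low=float(icc), ci_high=float(icc))
    a = k * icc / (n * (1.0 - icc)) if icc < 1 else float("inf")
    b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else float("inf")
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return ICCResult(icc=float(icc), ci_low=float(lower), ci_high=float(upper))


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def _first_time_below(times, surv, level) -> float:
    for t, s in zip(times, surv):
        if s <= level + 1e-12:
            return float(t)
    return float("nan")


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    The median (and quartile landmarks) are the first event times at which
    the survival curve drops to or below 0.5 (0.75 / 0.25); NaN when the
    curve never crosses.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if len(times) == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    if set(np.unique(events)) - {0, 1}:
        raise ValueError("event indicators must be 0/1")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    n = len(times)
    surv_vals, at_risk_vals, event_vals = [], [], []
    s = 1.0
    for t in uniq:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / at_risk
        surv_vals.append(s)
        at_risk_vals.append(at_risk)
        event_vals.append(d)
    surv = np.array(surv_vals)
    return SurvivalCurve(
        times=uniq,
        survival=surv,
        at_risk=np.array(at_risk_vals, dtype=int),
        events=np.array(event_vals, dtype=int),
        median=_first_time_below(uniq, surv, 0.5),
        q25=_first_time_below(uniq, surv, 0.75),
        q75=_first_time_below(uniq, surv, 0.25),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value.

    With no events in either group the test is undefined and ``(0.0, 1.0)``
    is returned.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a).astype(int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b).astype(int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("each group must be non-empty")
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta), int), np.ones(len(tb), int)])
    event_times = np.unique(all_times[all_events == 1])
    if len(event_times) == 0:
        return (0.0, 1.0)
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_times >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & (group == 0)).sum())
        d = int(((all_times == t) & (all_events == 1)).sum())
        d1 = int(((all_times == t) & (all_events == 1) & (group == 0)).sum())
        if n_tot < 2:
            continue
        o_minus_e += d1 - d * n1 / n_tot
        var += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    if var <= 0:
        return (0.0, 1.0)
    chi2 = o_minus_e**2 / var
    return (float(chi2), float(stats.chi2.sf(chi2, 1)))
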