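"""Clinical association statistics for a candidate expression marker:
two-sample t and one-way ANOVA computable from (n, mean, SD) group summaries,
ROC/AUC with a Hanley-McNeil interval, and Kaplan-Meier / log-rank survival
comparison with an O/E hazard ratio.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ArmSummary, ValidationError

Z95 = 1.959963984540054


@dataclass(frozen=True)
class AssocResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    kind: str  # "t" | "F"


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class SurvivalResult:
    hr: float
    ci_low: float
    ci_high: float
    chisq: float
    p: float
    curves: dict[str, pd.DataFrame]  # group -> (time, survival) step function


def t_from_summaries(a: ArmSummary, b: ArmSummary, method: str = "pooled") -> AssocResult:
    """Two-sample t test from group summaries; statistic oriented as a - b.

    ``pooled`` uses the classical equal-variance t with df = n_a + n_b - 2;
    ``welch`` uses the Welch-Satterthwaite approximation.
    """
    diff = a.mean - b.mean
    if a.sd == 0 and b.sd == 0:
        if diff == 0:
            return AssocResult(statistic=0.0, df=a.n + b.n - 2, p=1.0, kind="t")
        raise ValidationError("zero variance in both arms with unequal means: t is infinite")
    if method == "pooled":
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = a.n + b.n - 2
    elif method == "welch":
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        raise ValidationError(f"unknown t method {method!r}")
    t = diff / se
    return AssocResult(
        statistic=float(t), df=float(df), p=float(2 * stats.t.sf(abs(t), df)), kind="t"
    )


def anova_from_summaries(groups: list[ArmSummary]) -> AssocResult:
    """One-way ANOVA F from per-group (n, mean, SD) summaries."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)
    N, g = n.sum(), len(groups)
    grand = np.sum(n * m) / N
    ssb = float(np.sum(n * (m - grand) ** 2))
    ssw = float(np.sum((n - 1) * s**2))
    if ssw == 0:
        if ssb == 0:
            return AssocResult(statistic=0.0, df=(g - 1, N - g), p=1.0, kind="F")
        raise ValidationError("zero within-group variance with distinct means: F is infinite")
    F = (ssb / (g - 1)) / (ssw / (N - g))
    return AssocResult(
        statistic=float(F),
        df=(float(g - 1), float(N - g)),
        p=float(stats.f.sf(F, g - 1, N - g)),
        kind="F",
    )


def roc_auc(scores, labels, auto_orient: bool = False) -> RocResult:
    """AUC by the midrank (Mann-Whitney) estimator with the Hanley-McNeil SE.

    ``labels`` are truthy for cases; higher scores predict case status.  With
    ``auto_orient`` the reported AUC is max(auc, 1 - auc).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present for a ROC curve")
    ranks = stats.rankdata(scores)  # midranks handle ties
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    if auto_orient:
        auc = max(auc, 1.0 - auc)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    se = np.sqrt(
        (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2))
        / (n_pos * n_neg)
    )
    return RocResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - Z95 * se)),
        ci_high=float(min(1.0, auc + Z95 * se)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def roc_curve_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR) coordinates at every distinct threshold, for plotting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    keep = np.r_[np.diff(s) != 0, True]
    tpr = np.r_[0.0, tps[keep] / max(1, y.sum())]
    fpr = np.r_[0.0, fps[keep] / max(1, (~y).sum())]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def median_split(values, quantile: float = 0.5) -> np.ndarray:
    """Dichotomize a continuous marker at a quantile (default the median);
    returns 'high'/'low' labels with values above the cut labeled high."""
    values = np.asarray(values, dtype=float)
    cut = np.quantile(values, quantile)
    return np.where(values > cut, "high", "low")


def _km_curve(times, events) -> pd.DataFrame:
    order = np.argsort(times, kind="mergesort")
    t, e = np.asarray(times)[order], np.asarray(events)[order].astype(bool)
    surv, rows = 1.0, [(0.0, 1.0)]
    uniq = np.unique(t[e]) if e.any() else np.array([])
    for ti in uniq:
        at_risk = np.sum(t >= ti)
        d = np.sum((t == ti) & e)
        surv *= 1.0 - d / at_risk
        rows.append((float(ti), float(surv)))
    return pd.DataFrame(rows, columns=["time", "survival"])


def km_logrank(times, events, group_labels) -> SurvivalResult:
    """Kaplan-Meier curves plus the two-group log-rank test.

    The hazard ratio is the classical O/E estimate (O1/E1)/(O2/E2) with a
    log-scale CI using variance 1/E1 + 1/E2.  Tied event times use the
    hypergeometric variance of the shared risk set.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    group_labels = np.asarray(group_labels)
    labels = sorted(set(group_labels.tolist()))
    if len(labels) != 2:
        raise ValidationError(f"log-rank comparison needs exactly 2 groups, got {labels}")
    if not events.any():
        raise ValidationError("no events observed")
    g1 = group_labels == labels[0]

    O1 = E1 = O2 = E2 = V = 0.0
    for ti in np.unique(times[events]):
        at = times >= ti
        n, n1 = at.sum(), (at & g1).sum()
        d = ((times == ti) & events).sum()
        d1 = ((times == ti) & events & g1).sum()
        e1 = d * n1 / n
        O1, E1 = O1 + d1, E1 + e1
        O2, E2 = O2 + (d - d1), E2 + (d - e1)
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chisq = (O1 - E1) ** 2 / V if V > 0 else 0.0
    if E1 == 0 or E2 == 0 or O1 == 0 or O2 == 0:
        raise ValidationError("a group has no (expected) events; hazard ratio undefined")
    hr = (O1 / E1) / (O2 / E2)
    se_log = np.sqrt(1.0 / E1 + 1.0 / E2)
    curves = {
        lab: _km_curve(times[group_labels == lab], events[group_labels == lab])
        for lab in labels
    }
    return SurvivalResult(
        hr=float(hr),
        ci_low=float(hr * np.exp(-Z95 * se_log)),
        ci_high=float(hr * np.exp(Z95 * se_log)),
        chisq=float(chisq),
        p=float(stats.chi2.sf(chisq, 1)),
        curves=curves,
    )
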