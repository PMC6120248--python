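"""Continuous-outcome meta-analysis: SMD effect sizes, fixed and
DerSimonian-Laird random-effects pooling, heterogeneity statistics, the
fixed-vs-random model-selection rule, subgroup analyses and Deeks's
funnel-plot asymmetry test.

Conventions
-----------
Effect sizes are standardized mean differences (SMD).  The default flavor is
Cohen's d,

    d = (mean_case - mean_control) / s_p,
    var(d) = (n1 + n2) / (n1 n2) + d^2 / (2 (n1 + n2)),

with s_p the pooled SD.  Hedges' g applies the small-sample factor
J = 1 - 3 / (4 (n1 + n2) - 9).  Confidence intervals are z-based (normal),
matching the output of the classical inverse-variance machinery.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import ArmSummary, Diag2x2, EffectSize, StudyRow, ValidationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class HeterogeneityStats:
    Q: float
    df: int
    p_Q: float
    I2: float       # percent, in [0, 100]
    tau2: float     # DerSimonian-Laird between-study variance, >= 0


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    model: str                      # "fixed" | "random"
    het: HeterogeneityStats | None
    weights: np.ndarray             # normalized, sum to 1


@dataclass(frozen=True)
class DeeksResult:
    slope: float
    p: float
    ess: np.ndarray
    lndor: np.ndarray


def smd(case: ArmSummary, control: ArmSummary, flavor: str = "cohen") -> EffectSize:
    """Standardized mean difference (case minus control) from arm summaries."""
    n1, n2 = case.n, control.n
    sp2 = ((n1 - 1) * case.sd**2 + (n2 - 1) * control.sd**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValidationError("pooled SD is zero; SMD undefined")
    d = (case.mean - control.mean) / np.sqrt(sp2)
    var = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))
    if flavor == "cohen":
        return EffectSize(d=float(d), var=float(var), flavor="cohen")
    if flavor == "hedges":
        J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
        return EffectSize(d=float(J * d), var=float(J**2 * var), flavor="hedges")
    raise ValidationError(f"unknown SMD flavor {flavor!r}")


def effects_from_rows(rows: list[StudyRow], flavor: str = "cohen") -> list[EffectSize]:
    return [smd(r.case, r.control, flavor=flavor) for r in rows]


def _as_arrays(effects: list[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    if not effects:
        raise ValidationError("need at least one effect size")
    d = np.array([e.d for e in effects], dtype=float)
    v = np.array([e.var for e in effects], dtype=float)
    return d, v


def _result(d, w, model, het) -> MetaResult:
    pooled = float(np.sum(w * d) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / se
    return MetaResult(
        pooled=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        p=float(2 * stats.norm.sf(abs(z))),
        model=model,
        het=het,
        weights=w / np.sum(w),
    )


def heterogeneity(effects: list[EffectSize]) -> HeterogeneityStats:
    """Cochran's Q, I-squared and the DerSimonian-Laird tau-squared."""
    d, v = _as_arrays(effects)
    if len(d) < 2:
        raise ValidationError("heterogeneity needs >= 2 studies")
    w = 1.0 / v
    pooled = np.sum(w * d) / np.sum(w)
    Q = float(np.sum(w * (d - pooled) ** 2))
    df = len(d) - 1
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / denom) if denom > 0 else 0.0
    return HeterogeneityStats(Q=Q, df=df, p_Q=float(stats.chi2.sf(Q, df)), I2=I2, tau2=tau2)


def pool_fixed(effects: list[EffectSize]) -> MetaResult:
    """Fixed-effect inverse-variance pooling."""
    d, v = _as_arrays(effects)
    het = heterogeneity(effects) if len(d) >= 2 else None
    return _result(d, 1.0 / v, "fixed", het)


def pool_random_dl(effects: list[EffectSize]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling (weights 1/(var + tau^2))."""
    d, v = _as_arrays(effects)
    het = heterogeneity(effects)
    return _result(d, 1.0 / (v + het.tau2), "random", het)


def select_model(het: HeterogeneityStats) -> str:
    """Heterogeneity rule: random effects iff p_Q < 0.1 or I^2 > 50% (strict)."""
    return "random" if (het.p_Q < 0.1 or het.I2 > 50.0) else "fixed"


def pool_auto(effects: list[EffectSize]) -> MetaResult:
    """Pool with the model chosen by the heterogeneity rule."""
    if len(effects) < 2:
        return pool_fixed(effects)
    model = select_model(heterogeneity(effects))
    return pool_random_dl(effects) if model == "random" else pool_fixed(effects)


def subgroup_pool(
    rows: list[StudyRow], by: str = "sample_type", flavor: str = "cohen"
) -> dict[str, MetaResult]:
    """Pool independently within each level of a study-level attribute,
    selecting fixed vs random per subgroup.  Singleton subgroups are reported
    with their single-study effect."""
    groups: dict[str, list[StudyRow]] = {}
    for r in rows:
        groups.setdefault(getattr(r, by), []).append(r)
    return {
        key: pool_auto(effects_from_rows(members, flavor=flavor))
        for key, members in sorted(groups.items())
    }


def forest_table(rows: list[StudyRow], flavor: str = "cohen") -> pd.DataFrame:
    """Per-study effect, 95% CI and random/fixed-agnostic raw weight (1/var),
    the coordinates a forest plot is drawn from."""
    effs = effects_from_rows(rows, flavor=flavor)
    return pd.DataFrame(
        {
            "study": [r.study_id for r in rows],
            "effect": [e.d for e in effs],
            "ci_low": [e.d - Z95 * e.se for e in effs],
            "ci_high": [e.d + Z95 * e.se for e in effs],
            "weight": [1.0 / e.var for e in effs],
        }
    )


def funnel_table(effects: list[EffectSize]) -> pd.DataFrame:
    return pd.DataFrame({"effect": [e.d for e in effects], "se": [e.se for e in effects]})


# -- publication bias -------------------------------------------------------

def deeks_test(diag_studies: list[Diag2x2]) -> DeeksResult:
    """Deeks's funnel-plot asymmetry test for diagnostic meta-analyses.

    Regresses the log diagnostic odds ratio on 1/sqrt(ESS) with weights ESS,
    where ESS = 4 n1 n2 / (n1 + n2) is the effective sample size; the slope's
    two-sided t test (k - 2 df) is the asymmetry p-value.  Zero cells receive
    a 0.5 continuity correction applied to all four cells of that study.
    """
    if len(diag_studies) < 3:
        raise ValidationError("Deeks's test needs >= 3 studies")
    tp = np.array([s.tp for s in diag_studies], dtype=float)
    fp = np.array([s.fp for s in diag_studies], dtype=float)
    fn = np.array([s.fn for s in diag_studies], dtype=float)
    tn = np.array([s.tn for s in diag_studies], dtype=float)
    zero = (tp == 0) | (fp == 0) | (fn == 0) | (tn == 0)
    tp, fp, fn, tn = (x + 0.5 * zero for x in (tp, fp, fn, tn))
    lndor = np.log(tp * tn / (fp * fn))
    n1 = np.array([s.n_diseased for s in diag_studies], dtype=float)
    n2 = np.array([s.n_healthy for s in diag_studies], dtype=float)
    ess = 4.0 * n1 * n2 / (n1 + n2)
    x = 1.0 / np.sqrt(ess)
    if np.ptp(x) == 0 or np.ptp(lndor) == 0:
        # no spread in size or in effect: a flat funnel, no asymmetry signal
        return DeeksResult(slope=0.0, p=1.0, ess=ess, lndor=lndor)
    X = sm.add_constant(x)
    fit = sm.WLS(lndor, X, weights=ess).fit()
    return DeeksResult(
        slope=float(fit.params[1]), p=float(fit.pvalues[1]), ess=ess, lndor=lndor
    )
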