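"""Diagnostic test-accuracy meta-analysis.

Per-study sensitivity/specificity are taken to the logit scale with
within-study variances 1/tp + 1/fn (resp. 1/tn + 1/fp); studies with any zero
cell receive a 0.5 continuity correction on all four cells.  Pooling of
sensitivity and specificity uses DerSimonian-Laird random effects on each
logit separately.  The summary ROC comes from a bivariate normal model on
(logit sens, logit spec): between-study means, SDs and correlation are
estimated by maximizing the marginal Gaussian likelihood (within-study
variances held fixed), and the SROC curve is the implied regression of
logit sensitivity on logit false-positive rate through the summary point.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .datatypes import Diag2x2, EffectSize, ValidationError
from .meta import pool_random_dl


@dataclass(frozen=True)
class AccuracyPair:
    sens: float
    spec: float
    logit_sens: float
    logit_spec: float
    var_logit_sens: float
    var_logit_spec: float


@dataclass(frozen=True)
class BivariateParams:
    mu_sens: float       # mean logit sensitivity
    mu_spec: float       # mean logit specificity
    sigma_sens: float    # between-study SD of logit sensitivity
    sigma_spec: float
    rho: float           # between-study correlation, |rho| <= 0.999
    loglik: float
    converged: bool


@dataclass(frozen=True)
class PooledAccuracy:
    sens: float
    sens_ci: tuple[float, float]
    spec: float
    spec_ci: tuple[float, float]


@dataclass(frozen=True)
class SrocResult:
    curve: pd.DataFrame          # columns fpr, sens on a uniform grid
    auc: float
    pooled: PooledAccuracy
    params: BivariateParams | None


class BivariateFitError(RuntimeError):
    """Optimizer failed; carries the best parameters seen so far."""

    def __init__(self, msg: str, best: BivariateParams):
        super().__init__(msg)
        self.best = best


def accuracy_from_counts(x: Diag2x2, cc: float = 0.5) -> AccuracyPair:
    """Sensitivity/specificity and logit variances from a 2x2 table.

    If any cell is zero, ``cc`` is added to all four cells of that study
    before anything is computed.
    """
    tp, fp, fn, tn = float(x.tp), float(x.fp), float(x.fn), float(x.tn)
    if 0 in (tp, fp, fn, tn):
        tp, fp, fn, tn = tp + cc, fp + cc, fn + cc, tn + cc
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return AccuracyPair(
        sens=sens,
        spec=spec,
        logit_sens=float(logit(sens)),
        logit_spec=float(logit(spec)),
        var_logit_sens=1.0 / tp + 1.0 / fn,
        var_logit_spec=1.0 / tn + 1.0 / fp,
    )


def _logit_effects(studies: list[Diag2x2]) -> tuple[list[EffectSize], list[EffectSize]]:
    pairs = [accuracy_from_counts(s) for s in studies]
    sens = [EffectSize(p.logit_sens, p.var_logit_sens) for p in pairs]
    spec = [EffectSize(p.logit_spec, p.var_logit_spec) for p in pairs]
    return sens, spec


def pool_accuracy(studies: list[Diag2x2]) -> PooledAccuracy:
    """DL random-effects pooling of logit sens and logit spec separately,
    back-transformed to the probability scale."""
    if len(studies) < 2:
        raise ValidationError("pooling needs >= 2 studies")
    sens_eff, spec_eff = _logit_effects(studies)
    rs, rp = pool_random_dl(sens_eff), pool_random_dl(spec_eff)
    return PooledAccuracy(
        sens=float(expit(rs.pooled)),
        sens_ci=(float(expit(rs.ci_low)), float(expit(rs.ci_high))),
        spec=float(expit(rp.pooled)),
        spec_ci=(float(expit(rp.ci_low)), float(expit(rp.ci_high))),
    )


def _neg_loglik(theta: np.ndarray, y: np.ndarray, v: np.ndarray) -> float:
    mu_s, mu_p, log_ss, log_sp, zrho = theta
    ss, sp = np.exp(log_ss), np.exp(log_sp)
    rho = 0.999 * np.tanh(zrho)
    nll = 0.0
    for i in range(y.shape[0]):
        c11 = ss**2 + v[i, 0]
        c22 = sp**2 + v[i, 1]
        c12 = rho * ss * sp
        det = c11 * c22 - c12**2
        if det <= 0:
            return np.inf
        r1, r2 = y[i, 0] - mu_s, y[i, 1] - mu_p
        quad = (c22 * r1**2 - 2 * c12 * r1 * r2 + c11 * r2**2) / det
        nll += 0.5 * (np.log(det) + quad)
    return float(nll + y.shape[0] * np.log(2 * np.pi))


def fit_bivariate(studies: list[Diag2x2]) -> BivariateParams:
    """Fit the bivariate normal model by Nelder-Mead from a moment start.

    Within-study logit variances are fixed at their estimates; between-study
    SDs are kept nonnegative via a log parameterization and |rho| <= 0.999 via
    a tanh map.
    """
    if len(studies) < 4:
        raise ValidationError("bivariate fit needs >= 4 studies")
    pairs = [accuracy_from_counts(s) for s in studies]
    y = np.array([[p.logit_sens, p.logit_spec] for p in pairs])
    v = np.array([[p.var_logit_sens, p.var_logit_spec] for p in pairs])

    # moment start: marginal variances minus mean within-study variance, floored
    mu0 = y.mean(axis=0)
    s2 = np.maximum(y.var(axis=0, ddof=1) - v.mean(axis=0), 1e-4)
    r0 = np.corrcoef(y[:, 0], y[:, 1])[0, 1]
    r0 = 0.0 if not np.isfinite(r0) else np.clip(r0, -0.9, 0.9)
    theta0 = np.array(
        [mu0[0], mu0[1], 0.5 * np.log(s2[0]), 0.5 * np.log(s2[1]), np.arctanh(r0 / 0.999)]
    )

    res = optimize.minimize(
        _neg_loglik, theta0, args=(y, v), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    mu_s, mu_p, log_ss, log_sp, zrho = res.x
    params = BivariateParams(
        mu_sens=float(mu_s),
        mu_spec=float(mu_p),
        sigma_sens=float(np.exp(log_ss)),
        sigma_spec=float(np.exp(log_sp)),
        rho=float(0.999 * np.tanh(zrho)),
        loglik=float(-res.fun),
        converged=bool(res.success),
    )
    if not res.success:
        raise BivariateFitError(f"bivariate fit did not converge: {res.message}", params)
    return params


def sroc_auc(
    params: BivariateParams,
    studies: list[Diag2x2] | None = None,
    n_grid: int = 512,
) -> SrocResult:
    """SROC curve and its trapezoid-rule AUC from a bivariate fit.

    The curve is the regression line of logit sensitivity on logit FPR implied
    by the between-study covariance, through the summary point; sensitivities
    are clipped to the unit square.  A degenerate specificity variance yields
    a vertical-line ROC, handled as a step at the summary FPR.
    """
    fpr = (np.arange(n_grid) + 0.5) / n_grid
    fpr0 = float(expit(-params.mu_spec))
    if params.sigma_spec < 1e-6:
        sens = np.where(fpr >= fpr0, 1.0, 0.0)
        auc = 1.0 - fpr0
    else:
        # cov(logit sens, logit fpr) = -rho ss sp; var(logit fpr) = sp^2
        slope = -params.rho * params.sigma_sens / params.sigma_spec
        sens = expit(params.mu_sens + slope * (logit(fpr) + params.mu_spec))
        sens = np.clip(sens, 0.0, 1.0)
        auc = float(np.trapezoid(sens, fpr))
    pooled = pool_accuracy(studies) if studies else PooledAccuracy(
        sens=float(expit(params.mu_sens)), sens_ci=(np.nan, np.nan),
        spec=float(expit(params.mu_spec)), spec_ci=(np.nan, np.nan),
    )
    curve = pd.DataFrame({"fpr": fpr, "sens": sens})
    return SrocResult(curve=curve, auc=float(np.clip(auc, 0.0, 1.0)), pooled=pooled, params=params)


def sroc_from_counts(studies: list[Diag2x2], n_grid: int = 512) -> SrocResult:
    """Convenience: fit the bivariate model and trace the SROC in one call."""
    return sroc_auc(fit_bivariate(studies), studies=studies, n_grid=n_grid)
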