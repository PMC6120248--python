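"""Synthetic generators for every input the pipeline consumes.

Each generator emulates the statistical structure the analysis assumes:
log-scale expression with additive group shifts (exponentiated so values are
positive like RPM), heterogeneous two-arm study summaries with a true effect
drawn per study from Normal(smd_true, tau^2), bivariate logit-normal
sensitivity/specificity with binomial counts, exponential survival with a
hazard ratio between marker-defined groups, and binary evidence/edge
structures for the consensus and network stages.

One global integer seed drives everything; each generator derives its own
stream from (seed, stream id) so adding a generator never shifts the draws of
another.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import ArmSummary, Diag2x2, ExpressionCohort, StudyRow, ValidationError

_STREAMS = {
    "expression": 1,
    "meta": 2,
    "diag": 3,
    "survival": 4,
    "evidence": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated expression cohort.

    ``group_labels[0]`` is the control/normal group; the first ``n_de``
    features are shifted by ``lfc_true`` (log2 units) in every other group.
    ``sigma`` is the log2-scale residual SD.  ``arm_fraction`` of feature
    names carry a -5p/-3p mature-arm suffix.  Paired designs add a shared
    per-subject intercept giving within-pair correlation ``pair_rho``.
    """

    n_features: int
    n_per_group: dict[str, int]
    n_de: int
    lfc_true: float
    sigma: float
    paired: bool = False
    pair_rho: float = 0.5
    arm_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or any(n < 1 for n in self.n_per_group.values()):
            raise ValidationError("all counts must be >= 1")
        if not 0 <= self.n_de <= self.n_features:
            raise ValidationError("n_de must lie in [0, n_features]")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.paired and len(set(self.n_per_group.values())) != 1:
            raise ValidationError("paired designs need equal group sizes")
        if not 0 <= self.pair_rho < 1:
            raise ValidationError("pair_rho must lie in [0, 1)")

    @property
    def group_labels(self) -> list[str]:
        return list(self.n_per_group)


@dataclass(frozen=True)
class MetaSimSpec:
    """Between-study model for simulated two-arm summary studies: per-study
    true SMD ~ Normal(smd_true, tau^2), arm sizes uniform over n_range."""

    k_studies: int
    smd_true: float
    tau: float
    n_range: tuple[int, int] = (20, 80)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValidationError("k_studies must be >= 1")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if len(self.n_range) != 2 or self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValidationError("n_range must be (lo, hi) with 2 <= lo <= hi")


@dataclass(frozen=True)
class DiagSimSpec:
    """Bivariate logit-normal model for simulated diagnostic 2x2 studies."""

    k_studies: int
    mu_logit_sens: float
    mu_logit_spec: float
    sigma_sens: float = 0.5
    sigma_spec: float = 0.5
    rho: float = -0.4
    n_diseased_range: tuple[int, int] = (20, 100)
    n_healthy_range: tuple[int, int] = (20, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ValidationError("k_studies must be >= 1")
        if self.sigma_sens < 0 or self.sigma_spec < 0:
            raise ValidationError("between-study SDs must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [-1, 1]")
        for rng_ in (self.n_diseased_range, self.n_healthy_range):
            if len(rng_) != 2 or rng_[0] < 1 or rng_[1] < rng_[0]:
                raise ValidationError("sample-size ranges must be (lo, hi) with 1 <= lo <= hi")


def gen_expression_cohort(spec: CohortSpec) -> ExpressionCohort:
    """Simulate a features x samples expression matrix.

    Baseline log2 abundances are uniform on [2, 10]; tumor (non-first) groups
    shift the first ``n_de`` features by ``lfc_true``; values are
    2**(log2-signal) so the matrix is strictly positive.  The names of the
    truly shifted features are recorded in ``cohort.metadata["de_features"]``.
    """
    rng = _rng(spec.seed, "expression")
    labels = spec.group_labels
    base = rng.uniform(2.0, 10.0, size=spec.n_features)

    feature_names = []
    n_arm = int(round(spec.arm_fraction * spec.n_features))
    for i in range(spec.n_features):
        stem = f"sim-miR-{i + 1}"
        if i < n_arm:
            feature_names.append(stem + ("-5p" if i % 2 == 0 else "-3p"))
        else:
            feature_names.append(stem)

    cols, mats = [], []
    subj_sd = spec.sigma * np.sqrt(spec.pair_rho) if spec.paired else 0.0
    resid_sd = spec.sigma * np.sqrt(1 - spec.pair_rho) if spec.paired else spec.sigma
    n_subjects = next(iter(spec.n_per_group.values()))
    subj_intercepts = (
        rng.normal(0.0, subj_sd, size=(spec.n_features, n_subjects))
        if spec.paired
        else None
    )
    for gi, g in enumerate(labels):
        n = spec.n_per_group[g]
        mu = base[:, None] * np.ones((1, n))
        if gi > 0:
            mu[: spec.n_de, :] += spec.lfc_true
        noise = rng.normal(0.0, resid_sd, size=(spec.n_features, n))
        log2sig = mu + noise
        if subj_intercepts is not None:
            log2sig = log2sig + subj_intercepts
        mats.append(log2sig)
        cols += [f"{g}_{j + 1}" for j in range(n)]
    values = pd.DataFrame(
        np.power(2.0, np.hstack(mats)), index=feature_names, columns=cols
    )
    groups = pd.Series(
        [c.rsplit("_", 1)[0] for c in cols], index=cols, name="group"
    )
    return ExpressionCohort(
        values=values,
        sample_groups=groups,
        metadata={"de_features": feature_names[: spec.n_de], "control_group": labels[0]},
    )


def gen_meta_studies(spec: MetaSimSpec) -> list[StudyRow]:
    """Simulate two-arm studies: draw a true SMD per study, then per-arm raw
    normal samples (control mean 0, case mean theta_i, unit SD), summarized to
    (n, mean, SD) rows."""
    rng = _rng(spec.seed, "meta")
    rows = []
    for i in range(spec.k_studies):
        theta = rng.normal(spec.smd_true, spec.tau)
        n1, n2 = rng.integers(spec.n_range[0], spec.n_range[1] + 1, size=2)
        case = rng.normal(theta, 1.0, size=n1)
        control = rng.normal(0.0, 1.0, size=n2)
        rows.append(
            StudyRow(
                study_id=f"sim{i + 1:03d}",
                case=ArmSummary(int(n1), float(case.mean()), float(case.std(ddof=1))),
                control=ArmSummary(int(n2), float(control.mean()), float(control.std(ddof=1))),
                sample_type="tissue",
                source="simulated",
            )
        )
    return rows


def gen_diag_studies(spec: DiagSimSpec) -> list[Diag2x2]:
    """Simulate 2x2 diagnostic tables from the bivariate logit-normal model."""
    rng = _rng(spec.seed, "diag")
    cov = np.array(
        [
            [spec.sigma_sens**2, spec.rho * spec.sigma_sens * spec.sigma_spec],
            [spec.rho * spec.sigma_sens * spec.sigma_spec, spec.sigma_spec**2],
        ]
    )
    mean = np.array([spec.mu_logit_sens, spec.mu_logit_spec])
    out = []
    for i in range(spec.k_studies):
        ls, lp = rng.multivariate_normal(mean, cov)
        n1 = int(rng.integers(spec.n_diseased_range[0], spec.n_diseased_range[1] + 1))
        n2 = int(rng.integers(spec.n_healthy_range[0], spec.n_healthy_range[1] + 1))
        tp = int(rng.binomial(n1, expit(ls)))
        tn = int(rng.binomial(n2, expit(lp)))
        out.append(Diag2x2(f"sim{i + 1:03d}", tp=tp, fp=n2 - tn, fn=n1 - tp, tn=tn))
    return out


def gen_survival(
    n: int,
    hr_true: float,
    median_split_covariate: bool = True,
    seed: int = 0,
    base_rate: float = 0.1,
    censor_rate: float = 0.05,
) -> pd.DataFrame:
    """Exponential survival with rate ratio ``hr_true`` between groups.

    With ``median_split_covariate`` a continuous marker is drawn and the
    'high' group (above the median) carries the elevated hazard; otherwise
    samples are split at random.  Censoring is independent exponential.
    Returns columns sample, time, event, group, marker.
    """
    if hr_true <= 0:
        raise ValidationError("hr_true must be > 0")
    if n < 2:
        raise ValidationError("need n >= 2 subjects")
    rng = _rng(seed, "survival")
    marker = rng.normal(0.0, 1.0, size=n)
    if median_split_covariate:
        high = marker > np.median(marker)
    else:
        high = rng.random(n) < 0.5
    rate = np.where(high, base_rate * hr_true, base_rate)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(1.0 / censor_rate, size=n)
    time = np.minimum(event_time, censor_time)
    return pd.DataFrame(
        {
            "sample": [f"s{i + 1:04d}" for i in range(n)],
            "time": time,
            "event": (event_time <= censor_time).astype(int),
            "group": np.where(high, "high", "low"),
            "marker": marker,
        }
    )


def gen_evidence_and_network(
    n_genes: int,
    n_sources: int = 12,
    membership_prob: float = 0.4,
    edge_prob: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Binary gene x source evidence table plus an Erdos-Renyi-style simple
    edge list over the same genes."""
    if not 0 <= membership_prob <= 1 or not 0 <= edge_prob <= 1:
        raise ValidationError("probabilities must lie in [0, 1]")
    rng = _rng(seed, "evidence")
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    sources = [f"db{j + 1:02d}" for j in range(n_sources)]
    membership = rng.random((n_genes, n_sources)) < membership_prob
    evidence = pd.DataFrame(membership.astype(int), index=genes, columns=sources)
    iu, ju = np.triu_indices(n_genes, k=1)
    keep = rng.random(iu.size) < edge_prob
    edges = [(genes[a], genes[b]) for a, b in zip(iu[keep], ju[keep])]
    return evidence, edges
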