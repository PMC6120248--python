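"""Differential-expression screening and cross-cohort candidate selection.

The screen tests each feature between two groups with a Welch t on
log2(x + pseudocount), computes the log2 fold change of group means, and
retains features with |log2FC| strictly above a threshold and p strictly below
a threshold.  Microarray cohorts are ranked by the signal-to-noise ratio
SNR = (mean_case - mean_control) / (sd_case + sd_control), with the top k
features in each direction carried forward.  Candidates from multiple cohorts
are intersected after collapsing the -5p/-3p mature-arm suffixes, because
hairpin-level identifiers do not distinguish arms.
"""
from __future__ import annotations

import re
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionCohort, ValidationError

_ARM_RE = re.compile(r"-(5p|3p)$", re.IGNORECASE)


def _group_matrix(cohort: ExpressionCohort, group: str) -> np.ndarray:
    cols = cohort.samples_in(group)
    if len(cols) < 2:
        raise ValidationError(f"group {group!r} needs >= 2 samples, found {len(cols)}")
    return cohort.values[cols].to_numpy(dtype=float)


def log2fc_screen(
    cohort: ExpressionCohort,
    group_a: str,
    group_b: str,
    lfc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    pseudocount: float = 1.0,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Fold-change + Welch-test screen of group_b (cases) over group_a.

    Returns one row per feature with columns feature, log2fc, p, q, direction
    and a boolean ``retained`` implementing |log2fc| > lfc_thresh AND
    p (or BH q with ``use_fdr``) < p_thresh, both strict.
    """
    a = _group_matrix(cohort, group_a)
    b = _group_matrix(cohort, group_b)
    c = pseudocount
    log2fc = np.log2((b.mean(axis=1) + c) / (a.mean(axis=1) + c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(np.log2(b + c), np.log2(a + c), axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance features are untestable
    q = multipletests(p, method="fdr_bh")[1]
    crit = q if use_fdr else p
    out = pd.DataFrame(
        {
            "feature": cohort.values.index,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "retained": (np.abs(log2fc) > lfc_thresh) & (crit < p_thresh),
        }
    ).reset_index(drop=True)
    return out


def retained_features(de_table: pd.DataFrame) -> set[str]:
    return set(de_table.loc[de_table["retained"], "feature"])


def snr_rank(cohort: ExpressionCohort, group_a: str, group_b: str) -> pd.DataFrame:
    """Signal-to-noise ratio of group_b over group_a per feature, sorted
    descending (ties broken lexicographically by feature name).

    SNR = (mean_b - mean_a) / (sd_b + sd_a) with sample (n-1) SDs.  Features
    whose SDs are both zero get SNR 0 and a ``degenerate`` flag.
    """
    a = _group_matrix(cohort, group_a)
    b = _group_matrix(cohort, group_b)
    denom = b.std(axis=1, ddof=1) + a.std(axis=1, ddof=1)
    degenerate = denom == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with zero SD in both groups; SNR set to 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(degenerate, 0.0, (b.mean(axis=1) - a.mean(axis=1)) / denom)
    out = pd.DataFrame(
        {"feature": cohort.values.index, "snr": snr, "degenerate": degenerate}
    )
    return out.sort_values(
        ["snr", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def top_k_bidirectional(scores: pd.DataFrame, k: int = 250) -> set[str]:
    """Union of the k highest- and k lowest-SNR features.

    With fewer than 2k features everything is returned.  Ties at the rank-k
    boundary are resolved lexicographically so the output is deterministic.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    df = scores[["feature", "snr"]]
    if len(df) <= 2 * k:
        return set(df["feature"])
    top = df.sort_values(["snr", "feature"], ascending=[False, True], kind="mergesort")
    bottom = df.sort_values(["snr", "feature"], ascending=[True, True], kind="mergesort")
    return set(top["feature"].head(k)) | set(bottom["feature"].head(k))


def collapse_arms(feature_names) -> tuple[set[str], dict[str, str]]:
    """Strip -5p/-3p mature-arm suffixes, merging both arms of a hairpin.

    Returns the canonical name set and the original -> canonical mapping.
    """
    names = list(feature_names)
    if not names:
        raise ValidationError("no feature names given")
    mapping = {n: _ARM_RE.sub("", n) for n in names}
    return set(mapping.values()), mapping


def intersect_cohorts(per_cohort_feature_sets) -> dict:
    """Intersect per-cohort candidate sets after arm collapsing.

    Accepts a dict name -> set or a list of sets.  Returns the common set,
    per-set (collapsed) sizes, and for up to 4 sets the full Venn region
    counts keyed by membership tuples like ("A", "B").
    """
    if isinstance(per_cohort_feature_sets, dict):
        named = {k: set(v) for k, v in per_cohort_feature_sets.items()}
    else:
        named = {f"set{i + 1}": set(s) for i, s in enumerate(per_cohort_feature_sets)}
    if len(named) < 2:
        raise ValidationError("need >= 2 feature sets to intersect")
    collapsed = {k: collapse_arms(v)[0] if v else set() for k, v in named.items()}
    common = set.intersection(*collapsed.values())
    report = {
        "intersection": common,
        "set_sizes": {k: len(v) for k, v in collapsed.items()},
    }
    if len(collapsed) <= 4:
        keys = sorted(collapsed)
        union = set.union(*collapsed.values())
        venn: dict[tuple[str, ...], int] = {}
        for r in range(1, len(keys) + 1):
            for members in combinations(keys, r):
                inside = set.intersection(*(collapsed[k] for k in members))
                outside = set.union(
                    set(), *(collapsed[k] for k in keys if k not in members)
                )
                venn[members] = len(inside - outside)
        assert sum(venn.values()) == len(union)
        report["venn"] = venn
    return report


def stage_stratified_screen(
    cohort: ExpressionCohort,
    control_group: str,
    case_groups: list[str] | None = None,
    **screen_kwargs,
) -> dict:
    """Screen the control group against each case stratum, then intersect the
    retained sets (arm-collapsed).  Mirrors a normal-vs-each-stage design."""
    if case_groups is None:
        case_groups = [g for g in cohort.groups if g != control_group]
    if len(case_groups) < 2:
        raise ValidationError("stage-stratified screening needs >= 2 case groups")
    per_stage = {
        g: retained_features(log2fc_screen(cohort, control_group, g, **screen_kwargs))
        for g in case_groups
    }
    report = intersect_cohorts(per_stage)
    report["per_stage"] = per_stage
    return report
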