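"""Target-gene consensus and over-representation analysis.

Predicted-target evidence is a binary gene x source table (up to a dozen
prediction databases); the consensus keeps genes supported by at least
``min_votes`` sources.  Candidates are then intersected with disease-associated
genes and tested for over-representation against gene-set collections with the
hypergeometric upper tail (or the more conservative EASE variant) and
Benjamini-Hochberg FDR control.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError


def normalize_symbols(genes) -> set[str]:
    return {str(g).strip().upper() for g in genes}


def vote_count(evidence: pd.DataFrame, min_votes: int = 6) -> set[str]:
    """Genes supported by >= min_votes prediction sources.

    ``evidence`` is a binary DataFrame indexed by gene with one column per
    source.  The default of 6 reads a 'more than five databases' rule
    literally.
    """
    n_sources = evidence.shape[1]
    if min_votes > n_sources:
        raise ValidationError(
            f"min_votes={min_votes} exceeds the {n_sources} available sources"
        )
    votes = evidence.astype(bool).sum(axis=1)
    return set(votes.index[votes >= min_votes])


def intersect_with_disease_genes(candidates, disease_genes) -> set[str]:
    """Case-insensitive intersection of candidate targets with disease genes."""
    a, b = normalize_symbols(candidates), normalize_symbols(disease_genes)
    if not a or not b:
        raise ValidationError("both gene sets must be nonempty")
    out = a & b
    if not out:
        warnings.warn("no overlap between candidate and disease gene sets", stacklevel=2)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(
    study_set,
    gene_set_collection: dict,
    universe,
    method: str = "hypergeometric",
) -> pd.DataFrame:
    """Over-representation of a study gene set in each term of a collection.

    For a universe of size N containing K term genes and a study set of size n
    with k overlapping genes, p = P[X >= k] under Hypergeom(N, K, n).  The
    ``ease`` method substitutes k - 1 (p = 1 when k <= 1), mirroring the EASE
    score.  Terms are intersected with the universe before testing; q is the
    BH-adjusted p across all tested terms.
    """
    universe = normalize_symbols(universe)
    if not universe:
        raise ValidationError("empty universe")
    study = normalize_symbols(study_set) & universe
    if method not in ("hypergeometric", "ease"):
        raise ValidationError(f"unknown ORA method {method!r}")
    rows = []
    for term in sorted(gene_set_collection):
        members = normalize_symbols(gene_set_collection[term]) & universe
        k = len(study & members)
        k_eff = k - 1 if method == "ease" else k
        if method == "ease" and k <= 1:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k_eff - 1, len(universe), len(members), len(study)))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "set_size": len(members),
                "study_size": len(study),
                "universe": len(universe),
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return out
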