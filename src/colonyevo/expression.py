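"""Differential-expression screen, overlap/enrichment tests and PCA trajectories.

The screen follows the conventions of the colony transcriptome analysis it
supports: per-gene two-sided Mann-Whitney U tests on normalized expression,
Benjamini-Hochberg adjustment across genes, and a fold-change gate (default
2-fold, i.e. |log2 FC| >= 1).  Set overlap and regulon enrichment use
two-sided Fisher's exact tests; expression trajectories are summarized by
PCA of gene-centered profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from colonyevo.regulon import RegulonSet

__all__ = [
    "DEResult",
    "PCAResult",
    "de_screen",
    "overlap_fisher",
    "regulon_enrichment",
    "pca_profiles",
]


@dataclass
class DEResult:
    """Per-gene differential-expression table.

    ``table`` columns: ``lfc`` (difference of group means of log2-normalized
    expression, i.e. log2 fold change of geometric means on the pseudocounted
    scale), ``p`` (two-sided Mann-Whitney U), ``p_adj`` (Benjamini-Hochberg),
    ``significant`` (|lfc| >= lfc_min and p_adj < alpha).
    """

    table: pd.DataFrame
    lfc_min: float
    alpha: float

    @property
    def significant_genes(self) -> List[str]:
        return list(self.table.index[self.table["significant"]])


@dataclass
class PCAResult:
    """PCA of expression profiles: samples x components scores, gene loadings."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray


def de_screen(
    normalized: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> DEResult:
    """Screen genes for differential expression between two sample groups.

    ``normalized`` is the log2-normalized matrix (genes x samples); ``lfc``
    is reported as mean(group_b) - mean(group_a) on that scale, so a gene
    doubling its normalized expression in B has lfc = +1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = normalized[group_a].to_numpy(dtype=float)
    b = normalized[group_b].to_numpy(dtype=float)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    # exact two-sided MWU where SciPy supports it (no ties), else normal approx
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "p": pvals,
            "p_adj": p_adj,
            "significant": (np.abs(lfc) >= lfc_min) & (p_adj < alpha),
        },
        index=normalized.index,
    )
    return DEResult(table=table, lfc_min=lfc_min, alpha=alpha)


def overlap_fisher(
    set_a: Set[str], set_b: Set[str], universe: Set[str]
) -> Dict[str, float]:
    """Two-sided Fisher's exact test of overlap between two gene sets.

    Reports the odds ratio, the two-sided p-value, the overlap count and
    the overlap percentage under both common denominators: the union
    (``overlap_pct_union``) and the smaller set (``overlap_pct_min``).
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n_both = len(set_a & set_b)
    n_a_only = len(set_a - set_b)
    n_b_only = len(set_b - set_a)
    n_neither = len(universe) - n_both - n_a_only - n_b_only
    odds, p = stats.fisher_exact(
        [[n_both, n_a_only], [n_b_only, n_neither]], alternative="two-sided"
    )
    union = len(set_a | set_b)
    smaller = min(len(set_a), len(set_b))
    return {
        "odds_ratio": float(odds),
        "p": float(p),
        "overlap": n_both,
        "overlap_pct_union": 100.0 * n_both / union if union else float("nan"),
        "overlap_pct_min": 100.0 * n_both / smaller if smaller else float("nan"),
    }


def regulon_enrichment(
    de_genes: Set[str],
    regulons: RegulonSet,
    universe: Set[str],
    alpha: float = 0.05,
    k_largest: Optional[int] = 40,
) -> pd.DataFrame:
    """Fisher enrichment of each (large) regulon among differentially
    expressed genes, BH-adjusted across regulons.

    Restricting to the ``k_largest`` regulons by target count mirrors the
    convention of testing only well-annotated regulons.
    """
    tested = regulons.largest(k_largest) if k_largest else regulons
    rows = []
    for reg in tested:
        targets = set(reg.targets) & universe
        res = overlap_fisher(targets, de_genes, universe)
        rows.append(
            {
                "regulator": reg.regulator,
                "n_targets": len(targets),
                "overlap": res["overlap"],
                "odds_ratio": res["odds_ratio"],
                "p": res["p"],
            }
        )
    out = pd.DataFrame(rows).set_index("regulator")
    _, p_adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["p_adj"] = p_adj
    out["enriched"] = (out["p_adj"] < alpha) & (out["odds_ratio"] > 1)
    return out


def pca_profiles(
    normalized: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
    n_components: Optional[int] = None,
) -> PCAResult:
    """PCA of expression profiles (samples as observations, genes centered).

    Variance fractions are relative to the total gene-centered variance and
    sum to 1 when all components are kept.
    """
    if samples is None:
        samples = list(normalized.columns)
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = normalized[samples].to_numpy(dtype=float).T  # samples x genes
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=samples, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_.T, index=normalized.index, columns=comp_names
        ),
        variance_fraction=pca.explained_variance_ratio_.copy(),
    )
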