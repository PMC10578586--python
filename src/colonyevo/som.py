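"""Self-organizing expression maps ("meta-genes") and operon-coherence statistics.

Genes with similar expression profiles are mapped onto a small hexagonal
Kohonen grid; each unit ("meta-gene") summarizes the genes assigned to it.
Because bacterial operons are co-transcribed, genes from the same operon
should land on the same unit far more often than chance — quantified here by
a relative Shannon diversity index per unit (0 = all genes from one operon,
1 = all from different operons), by the converse per-operon meta-gene
diversity, by observed vs label-permuted start-codon distances within
units, and by a permutation test of same-operon co-assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from colonyevo.expression import PCAResult
from colonyevo.regulon import RegulonSet

__all__ = [
    "SOMMap",
    "MetaGeneStats",
    "OperonCoherence",
    "hex_positions",
    "train_som",
    "operon_coherence",
    "metagene_summaries",
    "relative_shannon",
]


@dataclass
class SOMMap:
    """A trained self-organizing map over gene expression profiles."""

    shape: Tuple[int, int]
    positions: np.ndarray  # n_units x 2 cartesian hex-grid coordinates
    codebooks: np.ndarray  # n_units x n_features
    bmu: pd.Series  # gene id -> unit index
    feature_names: List[str]
    quantization_errors: List[float]
    epochs: int
    seed: int

    @property
    def n_units(self) -> int:
        return self.codebooks.shape[0]

    def unit_genes(self, unit: int) -> List[str]:
        return list(self.bmu.index[self.bmu == unit])


@dataclass
class MetaGeneStats:
    """Per-unit summaries of a trained map."""

    summary: pd.DataFrame  # n_genes, expression SD, PC loadings
    unit_mean_expression: pd.DataFrame  # units x samples
    category_fractions: Optional[pd.DataFrame] = None
    regulon_fractions: Optional[pd.DataFrame] = None


@dataclass
class OperonCoherence:
    """Operon structure of the map: diversity indices and distance tests."""

    unit_stats: pd.DataFrame  # unit, n_genes, operon_diversity
    operon_stats: pd.DataFrame  # operon, n_genes, metagene_diversity
    observed_distances: Dict[str, np.ndarray]
    expected_distances: Dict[str, np.ndarray]
    co_assignment_observed: float
    co_assignment_null: np.ndarray
    co_assignment_p: float
    skipped_units: List[int] = field(default_factory=list)


def hex_positions(h: int, w: int) -> np.ndarray:
    """Cartesian centers of an h x w hexagonal grid (odd rows offset)."""
    pos = np.empty((h * w, 2))
    for i in range(h):
        for j in range(w):
            pos[i * w + j] = (j + 0.5 * (i % 2), i * np.sqrt(3) / 2)
    return pos


def train_som(
    profiles: pd.DataFrame,
    grid: Tuple[int, int] = (10, 10),
    epochs: int = 50,
    seed: int = 0,
    sigma_start: Optional[float] = None,
    sigma_end: float = 0.5,
) -> SOMMap:
    """Batch-train a Kohonen map on gene profiles (genes x features).

    Each epoch assigns every gene to its best-matching unit (BMU) and
    replaces each codebook by the Gaussian-neighborhood-weighted mean of
    the data, with the neighborhood radius shrinking linearly from
    ``sigma_start`` (default: half the grid diameter) to ``sigma_end``.
    Fully deterministic for a given seed; codebooks are initialized from
    randomly drawn gene profiles.
    """
    h, w = grid
    if h < 1 or w < 1:
        raise ValueError("grid dimensions must be >= 1")
    X = profiles.to_numpy(dtype=float)
    n_genes, n_feat = X.shape
    n_units = h * w
    if n_units > n_genes:
        import warnings

        warnings.warn(
            f"more units ({n_units}) than genes ({n_genes}); "
            "some units will stay empty",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(n_genes, size=n_units, replace=n_units > n_genes)
    codebooks = X[init_idx].copy()
    pos = hex_positions(h, w)
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    if sigma_start is None:
        sigma_start = max(np.sqrt(grid_d2.max()) / 2, sigma_end)
    qes: List[float] = []
    bmu = np.zeros(n_genes, dtype=int)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma_start + frac * (sigma_end - sigma_start)
        d2 = (
            (X**2).sum(1)[:, None]
            - 2 * X @ codebooks.T
            + (codebooks**2).sum(1)[None, :]
        )
        bmu = d2.argmin(axis=1)
        qes.append(float(np.sqrt(np.maximum(d2[np.arange(n_genes), bmu], 0)).mean()))
        H = np.exp(-grid_d2[:, bmu] / (2 * sigma**2))  # units x genes
        wsum = H.sum(axis=1)
        num = H @ X
        nonempty = wsum > 1e-12
        codebooks[nonempty] = num[nonempty] / wsum[nonempty, None]
    d2 = (
        (X**2).sum(1)[:, None]
        - 2 * X @ codebooks.T
        + (codebooks**2).sum(1)[None, :]
    )
    bmu = d2.argmin(axis=1)
    qes.append(float(np.sqrt(np.maximum(d2[np.arange(n_genes), bmu], 0)).mean()))
    return SOMMap(
        shape=(h, w),
        positions=pos,
        codebooks=codebooks,
        bmu=pd.Series(bmu, index=profiles.index, name="unit"),
        feature_names=list(profiles.columns),
        quantization_errors=qes,
        epochs=epochs,
        seed=seed,
    )


def relative_shannon(labels: Sequence) -> float:
    """Shannon entropy of label composition normalized by ln(group size).

    0 when all members share one label; 1 when all labels are distinct.
    Undefined (ValueError) for groups of fewer than 2 members.
    """
    labels = list(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("relative Shannon index needs at least 2 members")
    _, counts = np.unique(np.asarray(labels, dtype=object), return_counts=True)
    p = counts / n
    H = float(-(p * np.log(p)).sum())
    return H / np.log(n)


def _pair_distances(
    genes: Sequence[str],
    starts: Mapping[str, Tuple[int, str]],
    strand: str,
) -> List[int]:
    ss = sorted(starts[g][0] for g in genes if g in starts and starts[g][1] == strand)
    return [abs(a - b) for i, a in enumerate(ss) for b in ss[i + 1 :]]


def operon_coherence(
    som: SOMMap,
    operon_map: Mapping[str, str],
    gene_starts: Optional[Mapping[str, Tuple[int, str]]] = None,
    n_perm: int = 200,
    seed: int = 0,
) -> OperonCoherence:
    """Quantify how strongly map units respect operon structure.

    Per unit with >= 2 annotated genes, the relative Shannon operon
    diversity; per operon with >= 2 mapped genes, the converse meta-gene
    diversity.  If ``gene_starts`` is given, observed within-unit same-strand
    start-codon distances are compared to distances under random permutation
    of the unit labels.  The co-assignment test permutes unit labels and
    asks how often a same-operon gene pair shares a unit.
    """
    annotated = [g for g in som.bmu.index if g in operon_map]
    if len(annotated) < 2:
        raise ValueError("fewer than 2 genes carry operon annotation")
    units = som.bmu[annotated].to_numpy()
    operons = np.asarray([operon_map[g] for g in annotated], dtype=object)
    rng = np.random.default_rng(seed)

    unit_rows, skipped = [], []
    for u in np.unique(units):
        labs = operons[units == u]
        if len(labs) < 2:
            skipped.append(int(u))
            continue
        unit_rows.append((int(u), len(labs), relative_shannon(labs)))
    unit_stats = pd.DataFrame(
        unit_rows, columns=["unit", "n_genes", "operon_diversity"]
    ).set_index("unit")

    op_rows = []
    for op in pd.unique(operons):
        labs = units[operons == op]
        if len(labs) < 2:
            continue
        op_rows.append((op, len(labs), relative_shannon(labs)))
    operon_stats = pd.DataFrame(
        op_rows, columns=["operon", "n_genes", "metagene_diversity"]
    ).set_index("operon")

    observed_d: Dict[str, np.ndarray] = {}
    expected_d: Dict[str, np.ndarray] = {}
    if gene_starts is not None:
        for strand in ("+", "-"):
            obs: List[int] = []
            for u in np.unique(units):
                genes_u = [g for g, uu in zip(annotated, units) if uu == u]
                obs.extend(_pair_distances(genes_u, gene_starts, strand))
            observed_d[strand] = np.asarray(obs)
            exp: List[int] = []
            for _ in range(max(n_perm // 10, 1)):
                perm = rng.permutation(units)
                for u in np.unique(perm):
                    genes_u = [g for g, uu in zip(annotated, perm) if uu == u]
                    exp.extend(_pair_distances(genes_u, gene_starts, strand))
            expected_d[strand] = np.asarray(exp)

    # same-operon pairs sharing a unit, vs permuted unit labels
    same_operon = operons[:, None] == operons[None, :]
    iu = np.triu_indices(len(annotated), k=1)
    so = same_operon[iu]
    n_pairs = int(so.sum())
    if n_pairs == 0:
        raise ValueError("no same-operon gene pair among annotated genes")
    obs_frac = float((units[:, None] == units[None, :])[iu][so].mean())
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(units)
        null[b] = (perm[:, None] == perm[None, :])[iu][so].mean()
    p = float((1 + np.sum(null >= obs_frac)) / (n_perm + 1))
    return OperonCoherence(
        unit_stats=unit_stats,
        operon_stats=operon_stats,
        observed_distances=observed_d,
        expected_distances=expected_d,
        co_assignment_observed=obs_frac,
        co_assignment_null=null,
        co_assignment_p=p,
        skipped_units=skipped,
    )


def metagene_summaries(
    som: SOMMap,
    normalized: pd.DataFrame,
    pca: Optional[PCAResult] = None,
    categories: Optional[Mapping[str, str]] = None,
    regulons: Optional[RegulonSet] = None,
) -> MetaGeneStats:
    """Summarize each meta-gene: size, mean profile, SD, PC loadings,
    and the fraction of member genes in each functional category / regulon."""
    units = sorted(som.bmu.unique())
    mean_expr = {}
    rows = []
    for u in units:
        genes = som.unit_genes(u)
        prof = normalized.loc[genes].mean(axis=0)
        mean_expr[u] = prof
        row = {"unit": u, "n_genes": len(genes), "expr_sd": float(prof.std(ddof=0))}
        if pca is not None:
            for pc in pca.loadings.columns:
                row[f"loading_{pc}"] = float(pca.loadings.loc[genes, pc].mean())
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("unit")
    unit_mean = pd.DataFrame(mean_expr).T
    unit_mean.index.name = "unit"

    cat_fr = None
    if categories is not None:
        cats = sorted(set(categories.values()))
        data = {}
        for u in units:
            genes = som.unit_genes(u)
            n = len(genes)
            data[u] = [
                sum(categories.get(g) == c for g in genes) / n for c in cats
            ]
        cat_fr = pd.DataFrame(data, index=cats).T
        cat_fr.index.name = "unit"

    reg_fr = None
    if regulons is not None:
        data = {}
        for u in units:
            genes = set(som.unit_genes(u))
            n = len(genes)
            data[u] = [len(genes & set(r.targets)) / n for r in regulons]
        reg_fr = pd.DataFrame(data, index=regulons.regulators).T
        reg_fr.index.name = "unit"

    return MetaGeneStats(
        summary=summary,
        unit_mean_expression=unit_mean,
        category_fractions=cat_fr,
        regulon_fractions=reg_fr,
    )
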