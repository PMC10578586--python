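"""Regulator-activity inference, coactivation and activity-module detection.

A regulator's *activity* is inferred from its target genes, not from its own
transcript: an activator is considered active in samples where its targets
are highly expressed, a repressor where its targets are lowly expressed.
Concretely, counts are normalized (median-of-ratios size factors, log2),
each target gene is z-scored across a reference sample set, and the activity
of a regulator in a sample is the mean target z-score, sign-flipped for
repressors.  Pairwise Pearson correlation of activities across samples
("coactivation") is then clustered (average linkage on distance
``1 - r``) to find modules of regulators that rise and fall together —
e.g. a vegetative-growth module and a dormancy module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "Regulon",
    "RegulonSet",
    "ActivityMatrix",
    "CoactivationMatrix",
    "ModulePartition",
    "size_factors",
    "normalize_log",
    "regulator_activity",
    "coactivation",
    "partition_modules",
    "activity_fits",
]

MODES = ("activator", "repressor")

REQUIRED_SAMPLE_COLUMNS = ("day", "position", "genotype", "replicate")


@dataclass
class ExpressionMatrix:
    """Gene-level counts (genes x samples) with per-sample metadata.

    ``counts`` is a DataFrame indexed by gene id with sample ids as columns;
    ``samples`` is a DataFrame indexed by sample id with at least the columns
    ``day``, ``position`` (edge|center), ``genotype`` and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in counts")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in counts")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("counts contain non-finite values")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
            if self.samples.loc[list(self.counts.columns), col].isna().any():
                raise ValueError(f"incomplete sample metadata in column {col!r}")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class Regulon:
    """One regulator with its mode and target genes."""

    regulator: str
    mode: str
    targets: Tuple[str, ...]
    regulator_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if len(self.targets) < 1:
            raise ValueError(f"regulon {self.regulator!r} has no targets")

    @property
    def mode_sign(self) -> int:
        return 1 if self.mode == "activator" else -1


@dataclass
class RegulonSet:
    """A collection of regulons (regulator -> targets with mode)."""

    regulons: List[Regulon]

    def __post_init__(self) -> None:
        names = [r.regulator for r in self.regulons]
        if len(set(names)) != len(names):
            raise ValueError("duplicate regulator ids")

    def __iter__(self):
        return iter(self.regulons)

    def __len__(self) -> int:
        return len(self.regulons)

    def __getitem__(self, regulator: str) -> Regulon:
        for r in self.regulons:
            if r.regulator == regulator:
                return r
        raise KeyError(regulator)

    @property
    def regulators(self) -> List[str]:
        return [r.regulator for r in self.regulons]

    def largest(self, k: int) -> "RegulonSet":
        """The k largest regulons by target count (ties broken by name)."""
        ranked = sorted(self.regulons, key=lambda r: (-len(r.targets), r.regulator))
        return RegulonSet(ranked[:k])

    def validate_universe(self, gene_ids: Sequence[str]) -> None:
        universe = set(gene_ids)
        for r in self.regulons:
            unknown = set(r.targets) - universe
            if unknown:
                raise ValueError(
                    f"regulon {r.regulator!r} has targets outside the gene "
                    f"universe: {sorted(unknown)[:5]}"
                )


@dataclass
class ActivityMatrix:
    """Regulator activities (regulators x samples, z-score units).

    ``undefined`` lists regulators whose regulon had no usable target in the
    reference set (their rows are absent from ``activities``).
    """

    activities: pd.DataFrame
    provenance: Dict[str, object] = field(default_factory=dict)
    undefined: List[str] = field(default_factory=list)


@dataclass
class CoactivationMatrix:
    """Symmetric Pearson-correlation matrix between regulator activities."""

    corr: pd.DataFrame
    n_samples: int
    masked: List[str] = field(default_factory=list)


@dataclass
class ModulePartition:
    """Assignment of each regulator to one activity module."""

    labels: Dict[str, int]
    k: int
    silhouette_by_k: Dict[int, float]
    degenerate: bool = False
    linkage_method: str = "average"

    def module(self, label: int) -> List[str]:
        return sorted(r for r, l in self.labels.items() if l == label)


def size_factors(
    counts: pd.DataFrame, pseudocount: float = 0.0
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The per-gene reference is the geometric mean across samples over genes
    positive in every sample; each sample's factor is the median ratio of
    its counts to that reference.  Set ``pseudocount`` > 0 to rescue data
    sets in which no gene is positive everywhere.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    x = counts.to_numpy(dtype=float) + pseudocount
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "pass pseudocount > 0 to enable a pseudocount mode"
        )
    xp = x[all_positive]
    log_geomean = np.mean(np.log(xp), axis=1)
    log_ratios = np.log(xp) - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Depth-normalized log2 expression: log2(count/factor + 1)."""
    f = factors.reindex(counts.columns)
    if (f <= 0).any() or f.isna().any():
        raise ValueError("size factors must be positive for every sample")
    return np.log2(counts.div(f, axis=1) + 1.0)


def _zscore_genes(
    normalized: pd.DataFrame, sample_subset: Sequence[str]
) -> pd.DataFrame:
    sub = normalized[list(sample_subset)]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    keep = sd > 0
    return sub.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)


def regulator_activity(
    normalized: pd.DataFrame,
    regulons: RegulonSet,
    sample_subset: Optional[Sequence[str]] = None,
    statistic: str = "mean",
) -> ActivityMatrix:
    """Infer per-sample regulator activities from target-gene expression.

    Each target gene is z-scored across ``sample_subset`` (default: all
    samples); the activity of a regulator in a sample is the mean (or
    median) z-score of its surviving targets, multiplied by -1 for
    repressors.  Targets missing from the matrix or with zero variance are
    dropped with a log line; a regulon losing all targets is reported as
    undefined rather than set to 0.
    """
    if sample_subset is None:
        sample_subset = list(normalized.columns)
    sample_subset = list(sample_subset)
    if len(sample_subset) < 3:
        raise ValueError("activity inference needs at least 3 samples")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    z = _zscore_genes(normalized, sample_subset)
    rows = {}
    undefined: List[str] = []
    for reg in regulons:
        present = [t for t in reg.targets if t in z.index]
        dropped = len(reg.targets) - len(present)
        if dropped:
            logger.info(
                "regulon %s: dropped %d/%d targets (missing or zero variance)",
                reg.regulator, dropped, len(reg.targets),
            )
        if not present:
            undefined.append(reg.regulator)
            continue
        zsub = z.loc[present]
        agg = zsub.mean(axis=0) if statistic == "mean" else zsub.median(axis=0)
        rows[reg.regulator] = reg.mode_sign * agg
    activities = pd.DataFrame(rows).T
    activities.index.name = "regulator"
    return ActivityMatrix(
        activities=activities,
        provenance={
            "sample_subset": sample_subset,
            "statistic": statistic,
            "normalization": "median-of-ratios log2",
        },
        undefined=undefined,
    )


def coactivation(
    activity: ActivityMatrix, sample_subset: Optional[Sequence[str]] = None
) -> CoactivationMatrix:
    """Pairwise Pearson correlation between regulator activities.

    Regulators with zero activity variance over the subset are masked
    (dropped from the matrix and reported in ``masked``).
    """
    acts = activity.activities
    if sample_subset is None:
        sample_subset = list(acts.columns)
    sample_subset = list(sample_subset)
    if len(sample_subset) < 3:
        raise ValueError("coactivation needs at least 3 samples")
    sub = acts[sample_subset]
    sd = sub.std(axis=1, ddof=0)
    masked = list(sub.index[sd == 0])
    if masked:
        logger.warning("masking zero-variance regulators: %s", masked)
    sub = sub.loc[sd > 0]
    corr = pd.DataFrame(
        np.corrcoef(sub.to_numpy()), index=sub.index, columns=sub.index
    )
    np.fill_diagonal(corr.values, 1.0)
    return CoactivationMatrix(corr=corr, n_samples=len(sample_subset), masked=masked)


def partition_modules(
    coact: CoactivationMatrix,
    k: Optional[int] = None,
    k_range: Sequence[int] = range(2, 7),
    degenerate_silhouette: float = 0.1,
) -> ModulePartition:
    """Cut an average-linkage dendrogram of regulators into activity modules.

    Distance is ``1 - r`` (Pearson coactivation).  If ``k`` is not given it
    is chosen to maximize the mean silhouette over ``k_range`` (ties toward
    smaller k); a best silhouette below ``degenerate_silhouette`` flags the
    partition as degenerate (no real module structure).
    """
    if coact.masked:
        raise ValueError(
            f"coactivation matrix has masked regulators: {coact.masked}"
        )
    corr = coact.corr
    n = corr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 regulators to partition")
    d = 1.0 - corr.to_numpy()
    d = np.clip((d + d.T) / 2, 0.0, None)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    sil_by_k: Dict[int, float] = {}
    labels_by_k: Dict[int, np.ndarray] = {}
    for kk in k_range:
        if kk >= n:
            continue
        lab = fcluster(Z, t=kk, criterion="maxclust")
        labels_by_k[kk] = lab
        if len(np.unique(lab)) < 2:
            sil_by_k[kk] = float("-inf")
        else:
            sil_by_k[kk] = float(silhouette_score(d, lab, metric="precomputed"))
    if k is None:
        best = max(sorted(sil_by_k), key=lambda kk: (sil_by_k[kk], -kk))
        chosen, auto = best, True
    else:
        chosen, auto = int(k), False
        if chosen not in labels_by_k:
            labels_by_k[chosen] = fcluster(Z, t=chosen, criterion="maxclust")
    degenerate = auto and sil_by_k[chosen] < degenerate_silhouette
    if degenerate:
        logger.warning(
            "silhouette %.3f at k=%d indicates no clear module structure",
            sil_by_k[chosen], chosen,
        )
    lab = labels_by_k[chosen]
    return ModulePartition(
        labels=dict(zip(corr.index, (int(l) for l in lab))),
        k=int(len(np.unique(lab))),
        silhouette_by_k={kk: v for kk, v in sil_by_k.items() if np.isfinite(v)},
        degenerate=degenerate,
    )


def activity_fits(
    activity: ActivityMatrix,
    covariate: pd.Series,
) -> pd.DataFrame:
    """Simple OLS of each regulator's activity on a per-sample covariate.

    ``covariate`` is indexed by sample id (e.g. the regulator-independent
    sporulating-cell fraction, or — passed per regulator via
    :func:`own_expression_covariates` — the regulator's own expression).
    Returns a DataFrame with columns ``slope``, ``intercept``, ``r2`` and
    an ``undefined`` flag for constant covariates; attaches the mean R^2
    and its standard error across regulators as ``DataFrame.attrs``.
    """
    acts = activity.activities
    missing = set(acts.columns) - set(covariate.index)
    if missing:
        raise ValueError(f"covariate missing for samples: {sorted(missing)[:5]}")
    x = covariate.reindex(acts.columns).to_numpy(dtype=float)
    rows = []
    for reg in acts.index:
        y = acts.loc[reg].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((reg, np.nan, np.nan, np.nan, True))
            continue
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = np.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot
        rows.append((reg, slope, intercept, r2, False))
    out = pd.DataFrame(
        rows, columns=["regulator", "slope", "intercept", "r2", "undefined"]
    ).set_index("regulator")
    r2s = out["r2"].dropna()
    out.attrs["mean_r2"] = float(r2s.mean()) if len(r2s) else float("nan")
    out.attrs["se_r2"] = (
        float(r2s.std(ddof=1) / np.sqrt(len(r2s))) if len(r2s) > 1 else float("nan")
    )
    return out


def own_expression_fits(
    activity: ActivityMatrix,
    normalized: pd.DataFrame,
    regulons: RegulonSet,
) -> pd.DataFrame:
    """OLS of each regulator's activity on its own gene's expression.

    Regulators without an annotated ``regulator_gene`` present in the
    matrix are flagged undefined.  Activity need not track the regulator's
    own transcript (post-transcriptional control), so low R^2 here is a
    meaningful result, not a failure.
    """
    acts = activity.activities
    rows = []
    for reg in acts.index:
        gene = regulons[reg].regulator_gene
        if gene is None or gene not in normalized.index:
            rows.append((reg, np.nan, np.nan, np.nan, True))
            continue
        x = normalized.loc[gene, acts.columns].to_numpy(dtype=float)
        y = acts.loc[reg].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((reg, np.nan, np.nan, np.nan, True))
            continue
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = np.nan if ss_tot == 0 else 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
        rows.append((reg, slope, intercept, r2, False))
    out = pd.DataFrame(
        rows, columns=["regulator", "slope", "intercept", "r2", "undefined"]
    ).set_index("regulator")
    r2s = out["r2"].dropna()
    out.attrs["mean_r2"] = float(r2s.mean()) if len(r2s) else float("nan")
    out.attrs["se_r2"] = (
        float(r2s.std(ddof=1) / np.sqrt(len(r2s))) if len(r2s) > 1 else float("nan")
    )
    return out
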