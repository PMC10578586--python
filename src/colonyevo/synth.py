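"""Ground-truthed synthetic data for every stage of the pipeline.

Transcriptomes are generated from an explicit latent model: each sample has
a dormancy coordinate ``d`` in [0, 1] (low during early vegetative growth at
the colony edge, high late and at the colony center).  Regulators belong to
a vegetative or a dormancy module; their true activity is ``-(2d-1)`` or
``+(2d-1)`` respectively.  Target-gene log2 means are the gene baseline plus
``beta * mode_sign * activity`` summed over the gene's regulons, and counts
are drawn negative-binomially (variance mu + phi mu^2) at a fixed depth.
Genes are organized into operons with sequential coordinates so that
operon-coherence statistics have a planted signal.

Colony images are shaded, blurred disks with known radii, and cell-type
composition tables map ``d`` onto the 4-simplex (filamentous, vegetative,
sporulating, spores) with sporulation peaking at intermediate ``d`` and
spores accumulating monotonically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import erfc

from colonyevo.regulon import ActivityMatrix, ExpressionMatrix, Regulon, RegulonSet

__all__ = [
    "SynthesisConfig",
    "SyntheticAnnotation",
    "TranscriptomeTruth",
    "ImageTruth",
    "gen_regulons_operons",
    "gen_transcriptome",
    "gen_composition",
    "gen_colony_image",
    "gen_image_series",
    "default_config",
]


@dataclass(frozen=True)
class SynthesisConfig:
    """Knobs of the synthetic transcriptome generator.

    Defaults emulate the ancestral colony time course: 17 regulators split
    into a vegetative and a dormancy module, samples from days 1/2/4/7 at
    colony edge and center with 2 replicates.
    """

    seed: int = 0
    n_genes: int = 600
    mean_operon_size: float = 3.0
    max_operon_size: int = 10
    n_regulators: int = 17
    n_vegetative: int = 8  # remaining regulators form the dormancy module
    target_operons_per_regulon: int = 8
    p_within: float = 0.9
    beta: float = 1.0  # log2-scale activity -> expression coupling
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.05  # NB: var = mu + phi mu^2
    depth: int = 300_000
    days: Tuple[int, ...] = (1, 2, 4, 7)
    positions: Tuple[str, ...] = ("edge", "center")
    genotypes: Tuple[str, ...] = ("ancestor",)
    replicates: int = 2
    genotype_effect: float = 0.4  # delta: dormancy suppression in evolved samples
    d_jitter_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_regulators < 1:
            raise ValueError("n_genes and n_regulators must be positive")
        if not (0 < self.n_vegetative < self.n_regulators):
            raise ValueError("n_vegetative must split the regulators in two")
        if self.dispersion <= 0 or self.depth <= 0:
            raise ValueError("dispersion and depth must be positive")
        if not (self.days and self.positions and self.genotypes and self.replicates):
            raise ValueError("design grid must be non-empty")
        if not 0 <= self.p_within <= 1:
            raise ValueError("p_within must be in [0, 1]")


@dataclass
class SyntheticAnnotation:
    """Planted regulon/operon structure with genomic coordinates."""

    regulons: RegulonSet
    modules: Dict[str, str]  # regulator -> vegetative|dormancy
    operon_map: Dict[str, str]
    gene_starts: Dict[str, Tuple[int, str]]
    gene_ids: List[str]


@dataclass
class TranscriptomeTruth:
    """Everything the generator knows that the pipeline must recover."""

    activity: ActivityMatrix
    d: pd.Series  # per-sample latent dormancy coordinate
    composition: pd.DataFrame
    modules: Dict[str, str]


@dataclass(frozen=True)
class ImageTruth:
    """Ground truth of one generated colony image."""

    radius_px: float
    center: Tuple[float, float]
    dish_radius_px: float
    edge_sigma_px: float
    shading_amplitude: float
    noise_sd: float


def default_config(seed: int = 0) -> SynthesisConfig:
    return SynthesisConfig(seed=seed)


def gen_regulons_operons(config: SynthesisConfig) -> SyntheticAnnotation:
    """Plant operons (geometric sizes) and operon-structured regulons.

    Regulon targets are drawn operon-wise: a regulator picks whole operons
    and includes each member gene with probability ``p_within``, so operon
    members tend to share regulons.  Coordinates are sequential along a
    synthetic chromosome (1 kb per gene, one strand per operon).
    """
    if config.n_genes < 10 * config.n_regulators:
        import warnings

        warnings.warn(
            "fewer than 10 genes per regulator; regulons will be small",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]

    operon_map: Dict[str, str] = {}
    gene_starts: Dict[str, Tuple[int, str]] = {}
    operons: List[List[str]] = []
    i = 0
    pos = 100
    while i < config.n_genes:
        size = min(
            1 + rng.geometric(1.0 / config.mean_operon_size),
            config.max_operon_size,
            config.n_genes - i,
        )
        members = gene_ids[i : i + size]
        op_id = f"op{len(operons):04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        for g in members:
            operon_map[g] = op_id
            gene_starts[g] = (pos, strand)
            pos += 1000
        pos += 500  # intergenic gap between operons
        operons.append(members)
        i += size

    modes = ["activator", "repressor"]
    regs: List[Regulon] = []
    modules: Dict[str, str] = {}
    for r in range(config.n_regulators):
        name = f"reg{r:02d}"
        module = "vegetative" if r < config.n_vegetative else "dormancy"
        mode = modes[r % 2]
        n_ops = min(config.target_operons_per_regulon, len(operons))
        chosen = rng.choice(len(operons), size=n_ops, replace=False)
        targets: List[str] = []
        for oi in chosen:
            for g in operons[oi]:
                if rng.random() < config.p_within:
                    targets.append(g)
        if not targets:  # guarantee a non-empty regulon
            targets = list(operons[int(chosen[0])][:1])
        reg_gene = gene_ids[int(rng.integers(config.n_genes))]
        regs.append(
            Regulon(
                regulator=name,
                mode=mode,
                targets=tuple(dict.fromkeys(targets)),
                regulator_gene=reg_gene,
            )
        )
        modules[name] = module
    return SyntheticAnnotation(
        regulons=RegulonSet(regs),
        modules=modules,
        operon_map=operon_map,
        gene_starts=gene_starts,
        gene_ids=gene_ids,
    )


def _latent_d(
    day: int, position: str, genotype: str, config: SynthesisConfig,
    rng: np.random.Generator,
) -> float:
    base = {1: 0.10, 2: 0.25, 4: 0.45, 7: 0.70}.get(day, min(day / 10.0, 0.75))
    d = base + (0.25 if position == "center" else 0.0)
    if genotype != config.genotypes[0]:
        d *= 1.0 - config.genotype_effect
    d += rng.normal(0.0, config.d_jitter_sd)
    return float(np.clip(d, 0.0, 1.0))


def gen_transcriptome(
    config: SynthesisConfig, annotation: Optional[SyntheticAnnotation] = None
) -> Tuple[ExpressionMatrix, TranscriptomeTruth]:
    """Draw negative-binomial counts from the latent dormancy-axis model."""
    if annotation is None:
        annotation = gen_regulons_operons(config)
    rng = np.random.default_rng((config.seed, 1))
    genes = annotation.gene_ids
    n_genes = len(genes)

    meta_rows = []
    for genotype in config.genotypes:
        for day in config.days:
            for position in config.positions:
                for rep in range(1, config.replicates + 1):
                    sid = f"{genotype}_d{day}_{position}_r{rep}"
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "day": day,
                            "position": position,
                            "genotype": genotype,
                            "lineage": genotype,
                            "replicate": rep,
                        }
                    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    d_vals = pd.Series(
        [
            _latent_d(row.day, row.position, row.genotype, config, rng)
            for row in meta.itertuples()
        ],
        index=meta.index,
        name="d",
    )

    regulators = annotation.regulons.regulators
    axis = 2.0 * d_vals.to_numpy() - 1.0
    sign = np.array(
        [1.0 if annotation.modules[r] == "dormancy" else -1.0 for r in regulators]
    )
    true_act = pd.DataFrame(
        np.outer(sign, axis), index=regulators, columns=meta.index.rename(None)
    )

    baseline = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n_genes
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    effect = np.zeros((n_genes, len(meta)))
    for reg in annotation.regulons:
        rows = [gene_index[t] for t in reg.targets]
        effect[rows] += (
            config.beta * reg.mode_sign * true_act.loc[reg.regulator].to_numpy()
        )
    log2_mu = np.clip(baseline[:, None] + effect, -5.0, 25.0)
    mu = np.exp2(log2_mu)
    mu *= config.depth / mu.sum(axis=0, keepdims=True)
    size = 1.0 / config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    expr = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=meta.index.rename(None)),
        samples=meta,
    )
    composition = gen_composition(d_vals)
    truth = TranscriptomeTruth(
        activity=ActivityMatrix(
            activities=true_act, provenance={"source": "synthetic ground truth"}
        ),
        d=d_vals,
        composition=composition.join(meta),
        modules=dict(annotation.modules),
    )
    return expr, truth


def gen_composition(d: pd.Series) -> pd.DataFrame:
    """Map the dormancy coordinate onto cell-type fractions on the 4-simplex.

    Filamentous and vegetative cells decline with ``d``, sporulating cells
    peak at intermediate ``d``, spores rise monotonically and dominate at
    ``d = 1``; every row sums to 1 exactly.
    """
    dv = np.asarray(d, dtype=float)
    if ((dv < 0) | (dv > 1)).any():
        raise ValueError("d must lie in [0, 1]")
    w = np.column_stack(
        [
            0.5 * (1.0 - dv),  # filamentous
            1.0 - dv,  # vegetative
            1.2 * dv * (1.0 - dv),  # sporulating, peaks at d = 0.5
            dv**2,  # spores
        ]
    )
    w /= w.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        w,
        index=d.index if isinstance(d, pd.Series) else None,
        columns=["filamentous", "vegetative", "sporulating", "spores"],
    )


def gen_colony_image(
    radius_px: float,
    center: Optional[Tuple[float, float]] = None,
    dish_radius_px: float = 220.0,
    shape: Tuple[int, int] = (512, 512),
    edge_sigma_px: float = 2.0,
    shading_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 0.10,
    dish_level: float = 0.45,
    colony_level: float = 0.85,
) -> Tuple[np.ndarray, ImageTruth]:
    """Render a shaded, blurred colony disk on a Petri dish.

    The colony edge is an error-function profile centered at the true radius
    (its half-height crossing *is* the ground-truth boundary); the whole
    frame is multiplied by a linear shading field ``1 +/- amplitude/2`` and
    Gaussian noise is added.  Returns a float image in roughly [0, 1] and
    the ground truth.
    """
    h, w = shape
    if center is None:
        center = (w / 2.0, h / 2.0)
    if not 0 < radius_px < dish_radius_px < min(h, w) / 2.0:
        raise ValueError("need 0 < colony radius < dish radius < frame half-size")
    yy, xx = np.mgrid[:h, :w]
    r = np.hypot(xx - center[0], yy - center[1])
    dish = (r <= dish_radius_px).astype(float)
    if edge_sigma_px > 0:
        colony = 0.5 * erfc((r - radius_px) / (math.sqrt(2) * edge_sigma_px))
    else:
        colony = (r <= radius_px).astype(float)
    img = background + (dish_level - background) * dish
    img += (colony_level - dish_level) * colony * dish
    shading = 1.0 + shading_amplitude * (xx / (w - 1) - 0.5)
    img *= shading
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    truth = ImageTruth(
        radius_px=float(radius_px),
        center=(float(center[0]), float(center[1])),
        dish_radius_px=float(dish_radius_px),
        edge_sigma_px=float(edge_sigma_px),
        shading_amplitude=float(shading_amplitude),
        noise_sd=float(noise_sd),
    )
    return img, truth


def gen_image_series(
    radii_px: Sequence[float],
    out_dir,
    times_h: Optional[Sequence[float]] = None,
    pixel_size_mm: Optional[float] = None,
    seed: int = 0,
    **image_kwargs,
) -> Tuple[pd.DataFrame, List[ImageTruth]]:
    """Write one 16-bit PNG per time point plus a manifest CSV.

    Radii must be non-decreasing (a growing colony); the dish and center are
    shared across the series.  Returns the manifest and the ground truths.
    """
    import imageio.v3 as iio

    radii = [float(r) for r in radii_px]
    if any(b < a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be non-decreasing")
    if times_h is None:
        times_h = [24.0 * (i + 1) for i in range(len(radii))]
    if len(times_h) != len(radii):
        raise ValueError("times_h must match radii length")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, truths = [], []
    for i, (radius, t) in enumerate(zip(radii, times_h)):
        img, truth = gen_colony_image(radius, seed=seed + i, **image_kwargs)
        arr = np.clip(img, 0.0, 1.2) / 1.2
        path = out_dir / f"colony_{i:03d}.png"
        iio.imwrite(path, (arr * 65535).astype(np.uint16))
        row = {"path": str(path), "time_h": float(t)}
        if pixel_size_mm is not None:
            row["pixel_size_mm"] = pixel_size_mm
        rows.append(row)
        truths.append(truth)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, truths
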