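"""Readers and writers for the tabular formats the pipeline consumes.

Counts come as TSV (first column gene id) or MatrixMarket (.mtx plus row and
column label files); regulons as a 4-column TSV or as GMT (mode encoded in
the description field); operon/coordinate and category annotations as TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from colonyevo.regulon import ExpressionMatrix, Regulon, RegulonSet

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_counts_mtx",
    "write_counts_mtx",
    "read_sample_meta",
    "write_sample_meta",
    "read_expression",
    "read_regulons_tsv",
    "write_regulons_tsv",
    "read_regulons_gmt",
    "write_regulons_gmt",
    "read_operon_table",
    "write_operon_table",
    "read_categories",
]


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.rename_axis(index=None)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(mtx_path, genes_path=None, samples_path=None) -> pd.DataFrame:
    """Read a MatrixMarket count matrix with sidecar row/column label files.

    Label files default to ``<stem>.genes.txt`` and ``<stem>.samples.txt``
    next to the .mtx file, one label per line.
    """
    mtx_path = Path(mtx_path)
    stem = mtx_path.with_suffix("")
    genes_path = genes_path or stem.with_suffix(".genes.txt")
    samples_path = samples_path or stem.with_suffix(".samples.txt")
    mat = sio.mmread(mtx_path)
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    dense = np.asarray(mat.todense() if sp.issparse(mat) else mat)
    return pd.DataFrame(dense, index=genes, columns=samples)


def write_counts_mtx(counts: pd.DataFrame, mtx_path) -> None:
    mtx_path = Path(mtx_path)
    sio.mmwrite(str(mtx_path), sp.csr_matrix(counts.to_numpy()))
    stem = mtx_path.with_suffix("")
    stem.with_suffix(".genes.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    stem.with_suffix(".samples.txt").write_text(
        "\n".join(map(str, counts.columns)) + "\n"
    )


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    return meta


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(counts_path, meta_path) -> ExpressionMatrix:
    """Load counts (TSV or .mtx, by extension) and sample metadata."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        counts = read_counts_mtx(counts_path)
    else:
        counts = read_counts_tsv(counts_path)
    return ExpressionMatrix(counts=counts, samples=read_sample_meta(meta_path))


def read_regulons_tsv(path) -> RegulonSet:
    """Columns: regulator, mode, regulator_gene (may be empty), targets
    (comma-separated gene ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    regs = []
    for row in df.itertuples(index=False):
        targets = tuple(t for t in row.targets.split(",") if t)
        regs.append(
            Regulon(
                regulator=row.regulator,
                mode=row.mode,
                targets=targets,
                regulator_gene=row.regulator_gene or None,
            )
        )
    return RegulonSet(regs)


def write_regulons_tsv(regulons: RegulonSet, path) -> None:
    rows = [
        {
            "regulator": r.regulator,
            "mode": r.mode,
            "regulator_gene": r.regulator_gene or "",
            "targets": ",".join(r.targets),
        }
        for r in regulons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_regulons_gmt(regulons: RegulonSet, path) -> None:
    """GMT export: name <tab> description <tab> genes...; the description
    field carries ``mode=...`` (and the regulator gene when annotated)."""
    lines = []
    for r in regulons:
        desc = f"mode={r.mode}"
        if r.regulator_gene:
            desc += f";gene={r.regulator_gene}"
        lines.append("\t".join([r.regulator, desc, *r.targets]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_regulons_gmt(path) -> RegulonSet:
    regs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        name, desc, targets = fields[0], fields[1], tuple(fields[2:])
        mode, gene = "activator", None
        for part in desc.split(";"):
            if part.startswith("mode="):
                mode = part[5:]
            elif part.startswith("gene="):
                gene = part[5:]
        regs.append(
            Regulon(regulator=name, mode=mode, targets=targets, regulator_gene=gene)
        )
    return RegulonSet(regs)


def read_operon_table(path) -> Tuple[Dict[str, str], Dict[str, Tuple[int, str]]]:
    """TSV with columns gene_id, operon_id, start_bp, strand -> (operon map,
    gene start/strand map)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "operon_id": str})
    if not {"gene_id", "operon_id", "start_bp", "strand"} <= set(df.columns):
        raise ValueError("operon table needs gene_id, operon_id, start_bp, strand")
    operon_map = dict(zip(df.gene_id, df.operon_id))
    starts = {
        g: (int(s), st) for g, s, st in zip(df.gene_id, df.start_bp, df.strand)
    }
    return operon_map, starts


def write_operon_table(
    operon_map: Mapping[str, str],
    gene_starts: Mapping[str, Tuple[int, str]],
    path,
) -> None:
    rows = [
        {
            "gene_id": g,
            "operon_id": op,
            "start_bp": gene_starts[g][0],
            "strand": gene_starts[g][1],
        }
        for g, op in operon_map.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_categories(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "category"} <= set(df.columns):
        raise ValueError("category table needs gene_id and category columns")
    return dict(zip(df.gene_id, df.category))
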