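"""Readers and writers for the flat-file formats the pipeline exchanges.

FPKM matrices and DEG tables travel as TSV, gene sets as GMT, spatial counts
as dense CSV or MatrixMarket triplets with index sidecars, cell metadata and
clinical cohorts as CSV, and gene positions as BED-like TSV (chrom, start,
end, gene_id; 0-based half-open).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .bulk import BulkExpressionMatrix

__all__ = [
    "read_bulk_matrix",
    "read_gene_positions",
    "read_gmt",
    "read_spatial",
    "write_bulk_matrix",
    "write_gene_positions",
    "write_gmt",
    "write_spatial",
]

OBS_COLUMNS = [
    "tissue_id",
    "fov",
    "x_slide_mm",
    "y_slide_mm",
    "cd45_intensity",
    "cd68_intensity",
    "doublet_flag",
    "cell_label",
]


# -- bulk FPKM bundles -------------------------------------------------------


def write_bulk_matrix(matrix: BulkExpressionMatrix, out_dir: str | Path) -> None:
    """FPKM TSV (genes x samples) + sample-group CSV + gene-annotation TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(out / "fpkm.tsv", sep="\t", index_label="gene_id")
    matrix.sample_groups.rename("group").to_csv(
        out / "sample_groups.csv", index_label="sample_id"
    )
    if matrix.gene_biotype is not None:
        matrix.gene_biotype.rename("biotype").to_csv(
            out / "gene_annotation.tsv", sep="\t", index_label="gene_id"
        )


def read_bulk_matrix(in_dir: str | Path) -> BulkExpressionMatrix:
    src = Path(in_dir)
    values = pd.read_csv(src / "fpkm.tsv", sep="\t", index_col="gene_id")
    groups = pd.read_csv(src / "sample_groups.csv", index_col="sample_id")["group"]
    biotype = None
    anno = src / "gene_annotation.tsv"
    if anno.exists():
        biotype = pd.read_csv(anno, sep="\t", index_col="gene_id")["biotype"]
    return BulkExpressionMatrix(values, groups, biotype)


# -- gene sets ---------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set]:
    """GMT gene sets: name <tab> description <tab> gene ids."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


def write_gmt(sets: dict[str, set], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- gene positions ----------------------------------------------------------


def write_gene_positions(positions: pd.DataFrame, path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, gene_id (0-based half-open)."""
    out = positions.reset_index()[["chrom", "start", "end", "gene_id"]]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    pos = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "gene_id"], header=None
    )
    return pos.set_index("gene_id")


# -- spatial cell tables -----------------------------------------------------


def write_spatial(adata: ad.AnnData, out_dir: str | Path, fmt: str = "csv") -> None:
    """Cell metadata CSV + counts (dense CSV or MTX triplet + index files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adata.obs[OBS_COLUMNS].to_csv(out / "cell_metadata.csv", index_label="cell_id")
    write_gene_positions(adata.var, out / "gene_positions.bed")
    X = np.asarray(adata.X)
    if fmt == "csv":
        pd.DataFrame(X, index=adata.obs_names, columns=adata.var_names).to_csv(
            out / "counts.csv", index_label="cell_id"
        )
    elif fmt == "mtx":
        spio.mmwrite(out / "counts.mtx", sparse.csr_matrix(X))
        (out / "cells.txt").write_text("\n".join(adata.obs_names) + "\n")
        (out / "genes.txt").write_text("\n".join(adata.var_names) + "\n")
    else:
        raise ValueError(f"unknown format: {fmt!r}")


def read_spatial(in_dir: str | Path) -> ad.AnnData:
    src = Path(in_dir)
    obs = pd.read_csv(src / "cell_metadata.csv", index_col="cell_id")
    obs["doublet_flag"] = obs["doublet_flag"].astype(bool)
    var = read_gene_positions(src / "gene_positions.bed")
    if (src / "counts.csv").exists():
        counts = pd.read_csv(src / "counts.csv", index_col="cell_id")
        X = counts.loc[obs.index, var.index].to_numpy(np.int64)
    else:
        X = np.asarray(spio.mmread(src / "counts.mtx").todense(), dtype=np.int64)
        cells = (src / "cells.txt").read_text().splitlines()
        genes = (src / "genes.txt").read_text().splitlines()
        X = pd.DataFrame(X, index=cells, columns=genes).loc[
            obs.index, var.index
        ].to_numpy()
    return ad.AnnData(X=X, obs=obs, var=var)
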