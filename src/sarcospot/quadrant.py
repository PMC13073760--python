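"""Quadrant-spotlight cross-dataset integration.

Two independently normalized expression datasets (patient tissues and cell
lines) are compared gene-by-gene without shared normalization factors: the
tissue axis is the tumor-minus-normal difference of per-gene medians on the
log2(FPKM + 1) scale (dNT), the cell-line axis is the median within-sample
ECDF percentile of each gene among a fixed DEG subset.  The "spotlight"
quadrant keeps genes with dNT > 0 whose median percentile reaches the upper
quantile of the subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bulk import NORMAL, TUMOR, BulkExpressionMatrix

__all__ = [
    "build_quadrant_table",
    "compute_cell_percentiles",
    "compute_delta_nt",
    "select_quadrant_genes",
]


def compute_delta_nt(matrix: BulkExpressionMatrix, genes) -> pd.Series:
    """dNT = median(log2 FPKM+1, tumor) - median(log2 FPKM+1, normal)."""
    genes = pd.Index(genes)
    missing = genes.difference(matrix.gene_ids)
    if len(missing):
        raise KeyError(f"genes absent from matrix: {list(missing)[:5]}")
    log2 = matrix.log2().loc[genes]
    t_cols = matrix.group_columns(TUMOR)
    n_cols = matrix.group_columns(NORMAL)
    if len(t_cols) == 0 or len(n_cols) == 0:
        raise ValueError("both tumor and normal groups must be non-empty")
    return log2[t_cols].median(axis=1) - log2[n_cols].median(axis=1)


def compute_cell_percentiles(
    cell_matrix: BulkExpressionMatrix | pd.DataFrame, gene_subset
) -> pd.Series:
    """Median within-sample ECDF percentile of each gene among a subset.

    Within each sample the percentile of gene g is midrank(g) / subset size
    computed over log2(FPKM + 1) values of the subset, giving values in
    (0, 1]; ties share their midrank. The per-gene output is the median
    percentile across samples.
    """
    gene_subset = pd.Index(gene_subset)
    if len(gene_subset) == 0:
        raise ValueError("empty gene subset")
    values = (
        cell_matrix.log2()
        if isinstance(cell_matrix, BulkExpressionMatrix)
        else np.log2(cell_matrix + 1.0)
    )
    missing = gene_subset.difference(values.index)
    if len(missing):
        raise KeyError(f"genes absent from cell matrix: {list(missing)[:5]}")
    sub = values.loc[gene_subset]
    n = len(gene_subset)
    pct = sub.apply(lambda col: rankdata(col, method="average") / n, axis=0)
    pct = pd.DataFrame(pct, index=gene_subset, columns=sub.columns)
    return pct.median(axis=1)


def build_quadrant_table(
    tissue_matrix: BulkExpressionMatrix,
    cell_matrix: BulkExpressionMatrix | pd.DataFrame,
    gene_subset,
) -> pd.DataFrame:
    """Merge dNT and median cell-line percentiles for a DEG subset."""
    delta = compute_delta_nt(tissue_matrix, gene_subset)
    pct = compute_cell_percentiles(cell_matrix, gene_subset)
    return pd.DataFrame({"delta_nt": delta, "cell_pct_median": pct})


def select_quadrant_genes(
    records: pd.DataFrame, pct_quantile: float = 0.8
) -> pd.Index:
    """Spotlight selection: dNT > 0 and percentile >= the subset quantile.

    The threshold is the empirical ``pct_quantile`` quantile (linear
    interpolation of order statistics) of ``cell_pct_median`` over all
    records; selection requires strictly positive ``delta_nt``.
    """
    if len(records) < 2:
        raise ValueError("need >= 2 records to define the quantile threshold")
    threshold = float(
        np.quantile(records["cell_pct_median"].to_numpy(float), pct_quantile)
    )
    selected = (records["delta_nt"] > 0) & (records["cell_pct_median"] >= threshold)
    return records.index[selected]
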