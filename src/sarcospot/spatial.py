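"""Spatial single-cell preprocessing.

Per-cell QC (FOV restriction, CD45-negativity, minimum detected genes,
singlet retention), CPM / log1p normalization with optional trimmed-mean-of-
M-values (TMM) composition factors, and SNN-graph clustering on batch-centered
principal components.

Cell tables are AnnData objects: ``obs`` holds cell metadata (``tissue_id``,
``fov``, ``x_slide_mm``, ``y_slide_mm``, ``cd45_intensity``,
``cd68_intensity``, ``doublet_flag``, ``cell_label``), ``var`` holds gene
metadata (``chrom``, ``start``, ``end``), and ``X`` the raw counts.
"""

from __future__ import annotations

import warnings

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .bulk import EmptyResultError

__all__ = [
    "SNNCluster",
    "cluster_cells",
    "cpm_log1p",
    "n_features",
    "normalize_counts",
    "qc_filter_cells",
    "tmm_factors",
]


def n_features(adata: ad.AnnData) -> np.ndarray:
    """Number of detected genes (count > 0) per cell."""
    X = np.asarray(adata.X)
    return (X > 0).sum(axis=1)


def qc_filter_cells(
    adata: ad.AnnData,
    selected_fovs=None,
    min_features: int = 20,
    cd45_threshold: float | None = None,
) -> ad.AnnData:
    """Retain singlet, CD45-negative cells with enough detected genes.

    ``selected_fovs=None`` keeps all FOVs. ``cd45_threshold=None`` picks an
    Otsu split of the CD45 intensity histogram (the intensities are bimodal:
    immune high, tumor low).
    """
    if cd45_threshold is None:
        cd45_threshold = float(threshold_otsu(adata.obs["cd45_intensity"].to_numpy()))
    elif not np.isfinite(cd45_threshold):
        raise ValueError("cd45_threshold must be finite")
    keep = (
        (adata.obs["cd45_intensity"].to_numpy() < cd45_threshold)
        & (n_features(adata) >= min_features)
        & ~adata.obs["doublet_flag"].to_numpy().astype(bool)
    )
    if selected_fovs is not None:
        keep &= adata.obs["fov"].isin(list(selected_fovs)).to_numpy()
    if not keep.any():
        raise EmptyResultError("QC removed every cell")
    out = adata[keep].copy()
    out.uns["qc"] = {
        "cd45_threshold": float(cd45_threshold),
        "min_features": int(min_features),
        "n_input": int(adata.n_obs),
        "n_retained": int(out.n_obs),
    }
    return out


def tmm_factors(
    counts: np.ndarray,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values composition factors, one per cell.

    Reference = the cell whose upper-quartile count fraction is closest to the
    mean upper quartile. Per cell, M (log2 ratio of count fractions vs the
    reference) and A (mean log2 abundance) are computed over genes detected in
    both; M is trimmed by ``logratio_trim`` and A by ``sum_trim`` on each
    tail; the factor is 2**(precision-weighted trimmed mean of M). Factors
    are rescaled so their log-mean is 0.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    if (lib <= 0).any():
        raise ValueError("every cell must have a positive total count")
    frac = counts / lib[:, None]
    uq = np.array([np.quantile(f[f > 0], 0.75) if (f > 0).any() else 0 for f in frac])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    f_ref = frac[ref_idx]
    lib_ref = lib[ref_idx]
    log_factors = np.zeros(len(counts))
    for c in range(len(counts)):
        ok = (counts[c] > 0) & (counts[ref_idx] > 0)
        if ok.sum() < 2 or c == ref_idx:
            continue
        m = np.log2(frac[c, ok] / f_ref[ok])
        a = 0.5 * np.log2(frac[c, ok] * f_ref[ok])
        # asymptotic (delta-method) binomial variances as weights
        v = (lib[c] - counts[c, ok]) / (lib[c] * counts[c, ok])
        v += (lib_ref - counts[ref_idx, ok]) / (lib_ref * counts[ref_idx, ok])
        n = ok.sum()
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - np.floor(n * logratio_trim) - 1
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - np.floor(n * sum_trim) - 1
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.any():
            log_factors[c] = np.average(m[keep], weights=1.0 / v[keep])
    log_factors -= log_factors.mean()  # geometric mean 1
    return 2.0 ** log_factors


def cpm_log1p(
    counts: np.ndarray, factors: np.ndarray | None = None
) -> np.ndarray:
    """log1p of counts-per-million, optionally divided by TMM factors."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    if (lib <= 0).any():
        raise ValueError("zero-count cell (should have failed QC)")
    cpm = counts / lib[:, None] * 1e6
    if factors is not None:
        cpm = cpm / np.asarray(factors)[:, None]
    return np.log1p(cpm)


def normalize_counts(adata: ad.AnnData, use_tmm: bool = False) -> ad.AnnData:
    """Attach ``layers["log1p_cpm"]`` and ``obs["tmm_factor"]`` in place."""
    counts = np.asarray(adata.X, dtype=float)
    factors = tmm_factors(counts) if use_tmm else np.ones(adata.n_obs)
    adata.obs["tmm_factor"] = factors
    adata.layers["log1p_cpm"] = cpm_log1p(counts, factors if use_tmm else None)
    return adata


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _batch_center(pcs: np.ndarray, batch: np.ndarray) -> np.ndarray:
    """Linear batch correction: subtract per-batch means in PC space."""
    out = pcs.copy()
    for b in np.unique(batch):
        mask = batch == b
        out[mask] -= out[mask].mean(axis=0)
    return out


def _snn_graph(pcs: np.ndarray, n_neighbors: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = len(pcs)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    idx = nn.kneighbors(return_distance=False)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            shared = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            edges.append((i, int(j)))
            weights.append(shared / union)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_cells(
    log1p_cpm: np.ndarray,
    batch=None,
    n_pcs: int = 30,
    k_clusters: int | None = None,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Cluster cells on batch-centered principal components.

    Genes are z-scaled, PCA reduces to ``n_pcs`` components (capped at the
    matrix rank with a warning), per-batch means are removed in PC space, and
    cells are clustered by Leiden community detection on an SNN graph; a
    forced cluster count ``k_clusters`` falls back to k-means. Deterministic
    under a fixed ``seed``.
    """
    X = np.asarray(log1p_cpm, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 cells and >= 1 gene")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    max_rank = min(X.shape) - 1
    if n_pcs > max_rank:
        warnings.warn(f"n_pcs={n_pcs} exceeds rank; capped to {max_rank}")
        n_pcs = max_rank
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(Xs)
    if batch is not None:
        pcs = _batch_center(pcs, np.asarray(batch))
    if k_clusters is not None:
        km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed).fit(pcs)
        return km.labels_
    g = _snn_graph(pcs, n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


class SNNCluster(BaseEstimator, ClusterMixin):
    """sklearn-style clusterer over :func:`cluster_cells`.

    ``fit(X)`` expects a cells x genes log1p-CPM matrix; pass batch labels via
    ``fit(X, batch=...)``. Fitted labels live in ``labels_``.
    """

    def __init__(
        self,
        n_pcs: int = 30,
        k_clusters: int | None = None,
        n_neighbors: int = 15,
        resolution: float = 1.0,
        seed: int = 0,
    ):
        self.n_pcs = n_pcs
        self.k_clusters = k_clusters
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.seed = seed

    def fit(self, X, y=None, batch=None) -> "SNNCluster":
        self.labels_ = cluster_cells(
            X,
            batch=batch,
            n_pcs=self.n_pcs,
            k_clusters=self.k_clusters,
            n_neighbors=self.n_neighbors,
            resolution=self.resolution,
            seed=self.seed,
        )
        return self
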