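"""Two-pass self-referencing CNV inference from smoothed expression.

Copy-number variation is inferred per tissue from log1p-CPM expression alone:
a first pass uses the tissue-wide mean profile as the baseline to score each
cell's deviation from copy neutrality; the lowest-deviation cells (excluding
mitotic-high cells) become internal references for a second pass, which
yields per-cell genome-bin log2 ratios, a CNV_level (median inferred copy
number, diploid = 2), a CNV_score (upper-tail deviation from neutrality),
optional distance-weighted kNN smoothing of scores in slide space, and a
tissue-wise CNV-high call at mean + 1 sd.

Cell-type annotations never enter reference selection or scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CNVProfile",
    "TwoPassCNV",
    "call_cnv_high",
    "infer_cnv_second_pass",
    "knn_smooth_scores",
    "mitotic_scores",
    "score_cnv_deviation",
    "select_reference_cells",
    "smooth_expression_genome",
]

LN2 = np.log(2.0)


def _genome_order(positions: pd.DataFrame) -> pd.Index:
    """Gene ids sorted by (chrom, start)."""
    if (positions["start"] >= positions["end"]).any():
        raise ValueError("positions must satisfy start < end")
    return positions.sort_values(["chrom", "start"]).index


def _running_mean(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking edge windows."""
    n = block.shape[1]
    half = window // 2
    cs = np.cumsum(block, axis=1)
    cs = np.concatenate([np.zeros((block.shape[0], 1)), cs], axis=1)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def smooth_expression_genome(
    log1p_cpm: pd.DataFrame,
    positions: pd.DataFrame,
    baseline: pd.Series,
    window: int = 25,
    clamp: float = 3.0,
) -> pd.DataFrame:
    """Cells x genes log2 ratios to a baseline, smoothed along the genome.

    Per gene the raw ratio is (log1p_cpm - baseline) / ln 2, clamped to
    +/- ``clamp``; a centered moving average over ``window`` genes ordered by
    (chrom, start) runs within each chromosome (edges shrink); finally each
    cell's median ratio is subtracted so the per-cell median is 0.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd count >= 1")
    unknown = log1p_cpm.columns.difference(positions.index)
    if len(unknown):
        raise ValueError(f"genes without positions: {list(unknown)[:5]}")
    order = _genome_order(positions.loc[log1p_cpm.columns])
    X = log1p_cpm[order].to_numpy(float)
    base = baseline.loc[order].to_numpy(float)
    ratios = np.clip((X - base[None, :]) / LN2, -clamp, clamp)
    chroms = positions.loc[order, "chrom"].to_numpy()
    smoothed = np.empty_like(ratios)
    for chrom in pd.unique(chroms):
        cols = np.where(chroms == chrom)[0]
        if window > len(cols):
            raise ValueError(
                f"window {window} exceeds the {len(cols)} genes on {chrom}"
            )
        smoothed[:, cols] = _running_mean(ratios[:, cols], window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    return pd.DataFrame(smoothed, index=log1p_cpm.index, columns=order)


def score_cnv_deviation(ratios: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-cell deviation from copy neutrality: mean of squared log2 ratios."""
    r = np.asarray(ratios, dtype=float)
    if not np.isfinite(r).all():
        raise ValueError("ratios must be finite")
    return (r ** 2).mean(axis=1)


def mitotic_scores(log1p_cpm: pd.DataFrame, cycle_genes) -> np.ndarray:
    """Mean log1p-CPM over a cell-cycle gene list present on the panel."""
    genes = [g for g in cycle_genes if g in log1p_cpm.columns]
    if not genes:
        raise ValueError("no cell-cycle genes found on the panel")
    return log1p_cpm[genes].to_numpy(float).mean(axis=1)


def select_reference_cells(
    deviations: np.ndarray,
    mitotic: np.ndarray,
    tissue_ids: np.ndarray,
    frac_range: tuple[float, float] = (0.2, 0.4),
    min_pool: int = 200,
) -> np.ndarray:
    """Boolean mask of reference-like cells, selected per tissue.

    Mitotic-high cells (score > tissue mean + 1 sd) are excluded; then the
    lowest-deviation fraction f of the remaining cells is taken, with f the
    smallest value in ``frac_range`` whose pool reaches ``min_pool`` cells
    (capped at the upper bound when the tissue is too small).
    """
    deviations = np.asarray(deviations, float)
    mitotic = np.asarray(mitotic, float)
    tissue_ids = np.asarray(tissue_ids)
    lo, hi = frac_range
    mask = np.zeros(len(deviations), dtype=bool)
    for tissue in np.unique(tissue_ids):
        cells = np.where(tissue_ids == tissue)[0]
        if len(cells) < 10:
            raise ValueError(f"tissue {tissue!r} has fewer than 10 cells")
        m = mitotic[cells]
        eligible = cells[m <= m.mean() + m.std(ddof=1)]
        if len(eligible) == 0:
            raise ValueError(f"tissue {tissue!r}: empty pool after exclusions")
        frac = min(max(lo, min_pool / len(eligible)), hi)
        n_sel = max(1, int(np.ceil(frac * len(eligible))))
        chosen = eligible[np.argsort(deviations[eligible], kind="stable")[:n_sel]]
        mask[chosen] = True
    return mask


@dataclass
class CNVProfile:
    """Per-cell CNV inference output of the second pass."""

    ratios: pd.DataFrame  # cells x genome-ordered genes, log2 ratio (0 = neutral)
    cnv_level: pd.Series  # median inferred copy number (diploid = 2)
    cnv_score: pd.Series  # upper-tail mean |log2 ratio|
    is_reference: pd.Series
    cnv_score_smoothed: pd.Series | None = None
    cnv_class: pd.Series | None = None


def infer_cnv_second_pass(
    log1p_cpm: pd.DataFrame,
    positions: pd.DataFrame,
    references: np.ndarray,
    window: int = 25,
    upper_tail_q: float = 0.9,
    clamp: float = 3.0,
) -> CNVProfile:
    """Second pass: ratios against the reference baseline plus CNV metrics.

    Baseline = mean log1p-CPM over the reference cells. Inferred copy number
    per bin is 2 * 2**ratio, CNV_level its per-cell median; CNV_score is the
    mean |ratio| over each cell's top (1 - ``upper_tail_q``) fraction of bins
    by |ratio|.
    """
    references = np.asarray(references, dtype=bool)
    if not references.any():
        raise ValueError("references must be non-empty")
    baseline = pd.Series(
        log1p_cpm.to_numpy(float)[references].mean(axis=0), index=log1p_cpm.columns
    )
    ratios = smooth_expression_genome(log1p_cpm, positions, baseline, window, clamp)
    r = ratios.to_numpy(float)
    copy_number = 2.0 * 2.0 ** r
    cnv_level = pd.Series(np.median(copy_number, axis=1), index=ratios.index)
    a = np.abs(r)
    thr = np.quantile(a, upper_tail_q, axis=1, keepdims=True)
    tail = a >= thr
    cnv_score = pd.Series((a * tail).sum(axis=1) / tail.sum(axis=1), index=ratios.index)
    return CNVProfile(
        ratios=ratios,
        cnv_level=cnv_level,
        cnv_score=cnv_score,
        is_reference=pd.Series(references, index=ratios.index),
    )


def knn_smooth_scores(
    scores: np.ndarray,
    coords: np.ndarray,
    tissue_ids: np.ndarray,
    k: int = 10,
    epsilon: float = 5e-3,
) -> np.ndarray:
    """Distance-weighted kNN propagation of per-cell scores in slide space.

    smoothed(c) = sum over c's k nearest same-tissue neighbors plus c itself
    of w * score / sum w, with w = 1 / (distance + epsilon). ``k=0`` is the
    identity; tissues with fewer than k other cells use all available.
    """
    scores = np.asarray(scores, float)
    coords = np.asarray(coords, float)
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    if k == 0:
        return scores.copy()
    tissue_ids = np.asarray(tissue_ids)
    out = np.empty_like(scores)
    for tissue in np.unique(tissue_ids):
        cells = np.where(tissue_ids == tissue)[0]
        kk = min(k, len(cells) - 1)
        if kk == 0:
            out[cells] = scores[cells]
            continue
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(coords[cells])
        dist, idx = nn.kneighbors(coords[cells])
        w = 1.0 / (dist + epsilon)
        out[cells] = (w * scores[cells][idx]).sum(axis=1) / w.sum(axis=1)
    return out


def call_cnv_high(scores: np.ndarray, tissue_ids: np.ndarray) -> np.ndarray:
    """Tissue-wise call: CNV-high iff score > tissue mean + 1 sd (sample sd)."""
    scores = np.asarray(scores, float)
    tissue_ids = np.asarray(tissue_ids)
    out = np.full(len(scores), "CNV-other", dtype=object)
    for tissue in np.unique(tissue_ids):
        cells = np.where(tissue_ids == tissue)[0]
        if len(cells) < 2:
            raise ValueError(f"tissue {tissue!r} has fewer than 2 cells")
        s = scores[cells]
        out[cells[s > s.mean() + s.std(ddof=1)]] = "CNV-high"
    return out.astype(str)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _depth_standardize(
    dev: np.ndarray, totals: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Z-score deviations within depth-decile strata of the total counts."""
    ranks = np.argsort(np.argsort(totals))
    bins = np.minimum(ranks * n_bins // len(totals), n_bins - 1)
    out = np.empty_like(dev, dtype=float)
    for b in np.unique(bins):
        m = bins == b
        out[m] = _zscore(dev[m])
    return out


class TwoPassCNV(BaseEstimator):
    """Full two-pass self-referencing CNV pipeline, applied per tissue.

    Parameters
    ----------
    window : odd int
        Moving-average width in genes along the genome.
    clamp : float
        Symmetric log2-ratio clamp applied before smoothing.
    upper_tail_q : float
        Quantile defining the upper-tail CNV_score.
    frac_range, min_pool
        Adaptive reference-fraction rule of pass 1.
    knn_k, epsilon
        Spatial smoothing of CNV scores; ``knn_k=0`` disables it.

    Attributes (per cell, aligned to the input rows)
    ----------
    ratios_, cnv_level_, cnv_score_, cnv_score_smoothed_, is_reference_,
    cnv_class_
    """

    def __init__(
        self,
        window: int = 25,
        clamp: float = 3.0,
        upper_tail_q: float = 0.9,
        frac_range: tuple[float, float] = (0.2, 0.4),
        min_pool: int = 200,
        knn_k: int = 0,
        epsilon: float = 5e-3,
    ):
        self.window = window
        self.clamp = clamp
        self.upper_tail_q = upper_tail_q
        self.frac_range = frac_range
        self.min_pool = min_pool
        self.knn_k = knn_k
        self.epsilon = epsilon

    def fit(
        self,
        log1p_cpm: pd.DataFrame,
        y=None,
        *,
        positions: pd.DataFrame,
        tissue_ids: np.ndarray,
        coords: np.ndarray | None = None,
        mitotic: np.ndarray | None = None,
        total_counts: np.ndarray | None = None,
    ) -> "TwoPassCNV":
        tissue_ids = np.asarray(tissue_ids)
        if mitotic is None:
            mitotic = np.zeros(len(log1p_cpm))
        n = len(log1p_cpm)
        ratios = pd.DataFrame(index=log1p_cpm.index, columns=None, dtype=float)
        cnv_level = np.empty(n)
        cnv_score = np.empty(n)
        is_ref = np.zeros(n, dtype=bool)
        blocks = []
        for tissue in np.unique(tissue_ids):
            rows = np.where(tissue_ids == tissue)[0]
            sub = log1p_cpm.iloc[rows]
            # pass 1: tissue-wide mean as provisional baseline
            base1 = pd.Series(sub.to_numpy(float).mean(axis=0), index=sub.columns)
            r1 = smooth_expression_genome(
                sub, positions, base1, self.window, self.clamp
            )
            dev = score_cnv_deviation(r1)
            # sampling noise shrinks with depth, so absolute deviations of
            # deep cells undercut noisy neutral cells; rank within depth
            # strata instead of globally
            if total_counts is not None:
                dev = _depth_standardize(dev, np.asarray(total_counts)[rows])
            if self.knn_k > 0 and coords is not None:
                # a reference must look neutral both on its own profile and in
                # its spatial context: combine the standardized raw and
                # kNN-smoothed deviations conservatively (elementwise max)
                dev_sm = knn_smooth_scores(
                    dev,
                    np.asarray(coords)[rows],
                    np.repeat(tissue, len(rows)),
                    self.knn_k,
                    self.epsilon,
                )
                dev = np.maximum(_zscore(dev), _zscore(dev_sm))
            refs = select_reference_cells(
                dev,
                np.asarray(mitotic)[rows],
                np.repeat(tissue, len(rows)),
                self.frac_range,
                self.min_pool,
            )
            profile = infer_cnv_second_pass(
                sub, positions, refs, self.window, self.upper_tail_q, self.clamp
            )
            blocks.append((rows, profile.ratios))
            cnv_level[rows] = profile.cnv_level.to_numpy()
            cnv_score[rows] = profile.cnv_score.to_numpy()
            is_ref[rows] = refs
        cols = blocks[0][1].columns
        full = np.empty((n, len(cols)))
        for rows, block in blocks:
            full[rows] = block[cols].to_numpy()
        self.ratios_ = pd.DataFrame(full, index=log1p_cpm.index, columns=cols)
        self.cnv_level_ = cnv_level
        self.cnv_score_ = cnv_score
        self.is_reference_ = is_ref
        if self.knn_k > 0:
            if coords is None:
                raise ValueError("knn_k > 0 requires coordinates")
            self.cnv_score_smoothed_ = knn_smooth_scores(
                cnv_score, coords, tissue_ids, self.knn_k, self.epsilon
            )
        else:
            self.cnv_score_smoothed_ = cnv_score.copy()
        self.cnv_class_ = call_cnv_high(self.cnv_score_smoothed_, tissue_ids)
        return self

    def to_frame(self) -> pd.DataFrame:
        """Per-cell CNV table (level, score, smoothed, reference, class)."""
        return pd.DataFrame(
            {
                "cnv_level": self.cnv_level_,
                "cnv_score": self.cnv_score_,
                "cnv_score_smoothed": self.cnv_score_smoothed_,
                "is_reference": self.is_reference_,
                "cnv_class": self.cnv_class_,
            },
            index=self.ratios_.index,
        )
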