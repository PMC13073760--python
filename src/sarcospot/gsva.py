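"""Single-sample pathway activity scores (GSVA-style).

Gene-set variation analysis over log2(FPKM + 1) values: a per-gene Gaussian
kernel CDF estimates each gene's expression level relative to the cohort,
genes are ranked within each sample, and a weighted Kolmogorov-Smirnov-like
random walk over the ranked list yields one score per (gene set, sample).
Gene sets are first restricted to tumor-upregulated genes present in the
matrix; undersized sets are dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .bulk import EmptyResultError, moderated_ttest

__all__ = [
    "GSVA",
    "compute_gsva",
    "restrict_genesets",
    "row_zscores",
    "test_pathways",
]


def restrict_genesets(
    collection: dict[str, set],
    up_genes: set,
    expressed_genes: set,
    min_size: int = 10,
) -> dict[str, set]:
    """Intersect each set with up_genes and expressed_genes; drop small sets.

    Sets retaining fewer than ``min_size`` genes are excluded.
    """
    universe = set(up_genes) & set(expressed_genes)
    out = {}
    for name, genes in collection.items():
        kept = set(genes) & universe
        if len(kept) >= min_size:
            out[name] = kept
    if not out:
        raise EmptyResultError("no gene set survives restriction")
    return out


def _kernel_cdf(expr: np.ndarray, bandwidth_factor: float) -> np.ndarray:
    """Gaussian-kernel CDF statistic per gene, evaluated at observed points.

    ``expr`` is genes x samples; bandwidth per gene = sd / bandwidth_factor.
    Constant genes get a flat statistic (0.5), carrying no rank information.
    """
    p, n = expr.shape
    sd = expr.std(axis=1, ddof=1)
    z = np.empty_like(expr, dtype=float)
    flat = sd <= 0
    z[flat] = 0.5
    idx = np.where(~flat)[0]
    for i in idx:
        h = sd[i] / bandwidth_factor
        z[i] = stats.norm.cdf((expr[i][:, None] - expr[i][None, :]) / h).mean(axis=1)
    return z


def _walk_scores(
    order: np.ndarray, rank_weight: np.ndarray, in_set: np.ndarray, tau: float
) -> tuple[float, float]:
    """Max positive / max negative deviation of the weighted KS walk.

    ``order`` lists gene indices by decreasing kernel-CDF statistic for one
    sample; ``rank_weight`` is the symmetric rank statistic |p/2 - position|
    scattered back to gene index.
    """
    w = rank_weight[order] ** tau
    inside = in_set[order]
    denom_in = w[inside].sum()
    n_out = (~inside).sum()
    step_in = np.where(inside, w / (denom_in if denom_in > 0 else 1.0), 0.0)
    step_out = np.where(inside, 0.0, 1.0 / n_out if n_out > 0 else 0.0)
    v = np.cumsum(step_in - step_out)
    return float(v.max()), float(v.min())


def compute_gsva(
    expr_log2: pd.DataFrame,
    sets: dict[str, set],
    tau: float = 1.0,
    kernel_bandwidth_factor: float = 4.0,
    method: str = "mx_diff",
) -> pd.DataFrame:
    """GSVA scores, gene sets x samples.

    ``method="mx_diff"`` scores each (set, sample) as the maximum positive
    deviation of the random walk minus the magnitude of the maximum negative
    deviation; ``method="max_dev"`` takes the single largest-magnitude
    deviation. Scores are bounded in [-1, 1].
    """
    if method not in ("mx_diff", "max_dev"):
        raise ValueError(f"unknown method: {method!r}")
    if expr_log2.shape[1] < 3:
        raise ValueError("GSVA needs >= 3 samples")
    genes = expr_log2.index
    for name, members in sets.items():
        missing = set(members) - set(genes)
        if missing:
            raise ValueError(
                f"set {name!r} has genes absent from the matrix: {sorted(missing)[:5]}"
            )
    p, n = expr_log2.shape
    z = _kernel_cdf(expr_log2.to_numpy(float), kernel_bandwidth_factor)
    # decreasing order of the kernel statistic per sample; symmetric rank weight
    orders = np.argsort(-z, axis=0, kind="stable")
    positions = np.arange(1, p + 1, dtype=float)
    weight_by_pos = np.abs(positions - p / 2.0)
    rank_weight = np.empty((p, n))
    for j in range(n):
        rank_weight[orders[:, j], j] = weight_by_pos
    gene_pos = {g: i for i, g in enumerate(genes)}
    scores = np.zeros((len(sets), n))
    for si, (name, members) in enumerate(sets.items()):
        in_set = np.zeros(p, dtype=bool)
        in_set[[gene_pos[g] for g in members]] = True
        for j in range(n):
            if np.ptp(z[:, j]) == 0:
                # no expression discrimination: the ranking is arbitrary
                scores[si, j] = 0.0
                continue
            vmax, vmin = _walk_scores(orders[:, j], rank_weight[:, j], in_set, tau)
            if method == "mx_diff":
                scores[si, j] = max(vmax, 0.0) + min(vmin, 0.0)
            else:
                scores[si, j] = vmax if vmax >= -vmin else vmin
    return pd.DataFrame(scores, index=list(sets), columns=expr_log2.columns)


def test_pathways(
    scores: pd.DataFrame, groups: pd.Series, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Moderated differential pathway activity between tumor and normal.

    Reuses the moderated two-group test on the score matrix; adds a
    ``significant`` flag at FDR < ``fdr_threshold`` and row-wise z-scores of
    the input (columns ``z_<sample>``) for visualization.
    """
    groups = pd.Series(groups).loc[scores.columns]
    if groups.nunique() < 2:
        raise ValueError("both groups must be present")
    table = moderated_ttest(scores, groups)
    table = table.rename(columns={"log2fc": "delta"})
    table["significant"] = table["fdr"] < fdr_threshold
    zs = row_zscores(scores)
    for col in scores.columns:
        table[f"z_{col}"] = zs[col]
    return table


def row_zscores(scores: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a score matrix (mean 0, sd 1 per row)."""
    mu = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1).replace(0.0, 1.0)
    return scores.sub(mu, axis=0).div(sd, axis=0)


class GSVA(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: expression matrix -> pathway score matrix.

    Parameters mirror :func:`compute_gsva`; ``gene_sets`` must already be
    restricted (see :func:`restrict_genesets`).
    """

    def __init__(
        self,
        gene_sets: dict[str, set] | None = None,
        tau: float = 1.0,
        kernel_bandwidth_factor: float = 4.0,
        method: str = "mx_diff",
    ):
        self.gene_sets = gene_sets
        self.tau = tau
        self.kernel_bandwidth_factor = kernel_bandwidth_factor
        self.method = method

    def fit(self, X: pd.DataFrame, y=None) -> "GSVA":
        if not self.gene_sets:
            raise ValueError("gene_sets must be provided")
        self.set_sizes_ = {k: len(v) for k, v in self.gene_sets.items()}
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return compute_gsva(
            X, self.gene_sets, self.tau, self.kernel_bandwidth_factor, self.method
        )
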