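"""Bulk tumor-vs-normal differential expression.

Expression-level QC on FPKM matrices, a two-group linear model with
empirical-Bayes variance moderation on the log2(FPKM + 1) scale,
Benjamini-Hochberg adjustment, and threshold-based DEG classification
(up / down / unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BulkExpressionMatrix",
    "EmptyResultError",
    "ModeratedDE",
    "bh_adjust",
    "classify_degs",
    "filter_expressed_genes",
    "fit_moderated_de",
    "moderated_ttest",
]

PROTEIN_CODING = "protein_coding"

TUMOR = "tumor"
NORMAL = "normal"


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every gene or cell."""


@dataclass
class BulkExpressionMatrix:
    """Genes x samples FPKM matrix with group labels and optional biotypes.

    Parameters
    ----------
    values
        Nonnegative FPKM values, genes as rows, samples as columns.
    sample_groups
        Maps every sample (column) to ``"tumor"`` or ``"normal"``.
    gene_biotype
        Optional per-gene biotype (e.g. ``"protein_coding"``); indexed like
        ``values``.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    gene_biotype: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be nonnegative")
        self.sample_groups = pd.Series(self.sample_groups)
        missing = set(self.values.columns) - set(self.sample_groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.sample_groups = self.sample_groups.loc[self.values.columns]
        bad = set(self.sample_groups.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.gene_biotype is not None:
            self.gene_biotype = pd.Series(self.gene_biotype).reindex(self.values.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self) -> pd.DataFrame:
        """log2(FPKM + 1), the modelling scale used throughout."""
        return np.log2(self.values + 1.0)

    def group_columns(self, group: str) -> pd.Index:
        return self.sample_groups.index[self.sample_groups == group]

    def subset_genes(self, genes) -> "BulkExpressionMatrix":
        biotype = None if self.gene_biotype is None else self.gene_biotype.loc[genes]
        return BulkExpressionMatrix(self.values.loc[genes], self.sample_groups, biotype)


def filter_expressed_genes(
    matrix: BulkExpressionMatrix,
    min_fpkm: float = 1.0,
    min_frac: float = 0.2,
    min_group_size: int = 2,
    coding_only: bool = True,
) -> BulkExpressionMatrix:
    """Expression-based QC.

    A gene is retained iff FPKM >= ``min_fpkm`` in at least ``min_frac`` of
    all samples, or of the samples within either group; a group contributes
    its clause only when it has at least ``min_group_size`` samples. When
    ``coding_only`` the surviving genes are further restricted to
    protein-coding biotypes.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    detected = matrix.values >= min_fpkm
    keep = detected.mean(axis=1) >= min_frac
    for group in (TUMOR, NORMAL):
        cols = matrix.group_columns(group)
        if len(cols) >= min_group_size:
            keep |= detected[cols].mean(axis=1) >= min_frac
    if coding_only:
        if matrix.gene_biotype is None:
            raise ValueError("coding_only=True requires gene_biotype annotation")
        keep &= matrix.gene_biotype == PROTEIN_CODING
    if not keep.any():
        raise EmptyResultError("no genes pass the expression QC filter")
    return matrix.subset_genes(matrix.gene_ids[keep])


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Shrink per-gene sample variances toward a common prior.

    Fits a scaled-F distribution to the observed variances by method of
    moments on log variances (prior df by trigamma inversion), and returns
    ``(prior_df, prior_var, posterior_var)``.  ``prior_df`` may be ``inf``
    when the observed variances are ensemble-consistent with a single value.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("variance pooling needs >= 2 genes with positive variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        var_prior = np.exp(
            emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        )
    else:
        df_prior = np.inf
        var_prior = np.exp(emean)
    if np.isinf(df_prior):
        var_post = np.full_like(s2, var_prior)
    else:
        var_post = (df_prior * var_prior + df * s2) / (df_prior + df)
    return float(df_prior), float(var_prior), var_post


def moderated_ttest(
    y: pd.DataFrame, groups: pd.Series, group_a: str = TUMOR, group_b: str = NORMAL
) -> pd.DataFrame:
    """Two-group moderated t-test on an already-transformed matrix.

    Per row: difference of group means (``group_a`` minus ``group_b``),
    pooled residual variance shrunk by :func:`squeeze_var`, moderated t
    referred to a t distribution with residual + prior df, two-sided p, BH
    adjustment.
    """
    groups = pd.Series(groups).loc[y.columns]
    cols_a = y.columns[groups == group_a]
    cols_b = y.columns[groups == group_b]
    n_a, n_b = len(cols_a), len(cols_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs >= 2 samples")
    ya = y[cols_a].to_numpy(float)
    yb = y[cols_b].to_numpy(float)
    diff = ya.mean(axis=1) - yb.mean(axis=1)
    df_resid = n_a + n_b - 2
    ss = ((ya - ya.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((yb - yb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if not (s2 > 0).any():
        raise ValueError("degenerate matrix: all rows constant within groups")
    df_prior, _, s2_post = squeeze_var(s2, df_resid)
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    df_total = df_resid + df_prior
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "log2fc": diff,
            "t_moderated": t,
            "p_value": p,
            "fdr": bh_adjust(p),
        },
        index=y.index,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up with cumulative minimum)."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def fit_moderated_de(matrix: BulkExpressionMatrix) -> pd.DataFrame:
    """Moderated DE on log2(FPKM + 1), tumor minus normal.

    Returns one row per gene with columns ``log2fc``, ``t_moderated``,
    ``p_value``, ``fdr``.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("need >= 2 genes for variance pooling")
    return moderated_ttest(matrix.log2(), matrix.sample_groups)


def classify_degs(
    records: pd.DataFrame, lfc_threshold: float = 2.0, fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """Label each gene ``up`` / ``down`` / ``unchanged``.

    ``up`` requires log2fc >= ``lfc_threshold`` and FDR < ``fdr_threshold``;
    ``down`` the mirrored thresholds; everything else is ``unchanged``.
    """
    out = records.copy()
    sig = out["fdr"] < fdr_threshold
    cls = np.where(
        sig & (out["log2fc"] >= lfc_threshold),
        "up",
        np.where(sig & (out["log2fc"] <= -lfc_threshold), "down", "unchanged"),
    )
    out["class"] = cls
    return out


class ModeratedDE(BaseEstimator):
    """sklearn-style wrapper around the moderated two-group DE test.

    Parameters
    ----------
    lfc_threshold, fdr_threshold
        Classification cutoffs applied to the fitted table.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-gene log2fc / t_moderated / p_value / fdr / class.
    prior_df_, prior_var_ : float
        Empirical-Bayes hyperparameters of the variance prior.
    """

    def __init__(self, lfc_threshold: float = 2.0, fdr_threshold: float = 0.01):
        self.lfc_threshold = lfc_threshold
        self.fdr_threshold = fdr_threshold

    def fit(self, X: BulkExpressionMatrix, y=None) -> "ModeratedDE":
        table = fit_moderated_de(X)
        log2 = X.log2()
        ya = log2[X.group_columns(TUMOR)].to_numpy(float)
        yb = log2[X.group_columns(NORMAL)].to_numpy(float)
        df = ya.shape[1] + yb.shape[1] - 2
        ss = ((ya - ya.mean(1, keepdims=True)) ** 2).sum(1)
        ss += ((yb - yb.mean(1, keepdims=True)) ** 2).sum(1)
        self.prior_df_, self.prior_var_, _ = squeeze_var(ss / df, df)
        self.results_ = classify_degs(table, self.lfc_threshold, self.fdr_threshold)
        return self

    def summary_counts(self) -> dict[str, int]:
        """Bookkeeping of the fitted classification: up/down/unchanged/total."""
        counts = self.results_["class"].value_counts()
        out = {k: int(counts.get(k, 0)) for k in ("up", "down", "unchanged")}
        out["total_degs"] = out["up"] + out["down"]
        out["total"] = len(self.results_)
        return out
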