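"""Clinical cohort statistics for IHC-scored specimens.

H-score computation from staining intensity fractions, Wilcoxon rank-sum
comparison of positivity between survival groups, an exact Fisher test for
r x c localization-by-survival tables, and Pearson correlation of the two
scoring modalities.
"""

from __future__ import annotations

from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "category_percentages",
    "compare_groups_wilcoxon",
    "compute_h_score",
    "correlate_scores",
    "fisher_exact_test",
]


def compute_h_score(intensity_fractions) -> float:
    """H-score = sum over intensities 1..3 of intensity x percent of cells.

    ``intensity_fractions`` maps intensity bins 0..3 to cell fractions that
    must sum to 1; the result ranges from 0 (all negative) to 300 (all cells
    at intensity 3).
    """
    if isinstance(intensity_fractions, dict):
        fracs = np.array([intensity_fractions.get(i, 0.0) for i in range(4)], float)
    else:
        fracs = np.asarray(intensity_fractions, dtype=float)
        if fracs.shape != (4,):
            raise ValueError("expected fractions for intensities 0..3")
    if (fracs < 0).any():
        raise ValueError("fractions must be nonnegative")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("intensity fractions must sum to 1")
    return float(sum(i * 100.0 * fracs[i] for i in (1, 2, 3)))


def compare_groups_wilcoxon(values, groups) -> tuple[float, float]:
    """Wilcoxon rank-sum test between two groups.

    Returns (W, two-sided p) where W is the midrank rank-sum of the first
    group (first label in sorted order). The p-value is exact (full
    enumeration) when the combined sample size is at most 12 and there are no
    ties, and a normal approximation with tie and continuity corrections
    otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups are required, both non-empty")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(values, method="average")
    w = float(ranks[groups == labels[0]].sum())
    n = len(values)
    no_ties = len(np.unique(values)) == n
    method = "exact" if (n <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def _log_table_prob(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability given fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    out = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
    out -= lgamma(n + 1)
    out -= sum(lgamma(x + 1) for x in table.ravel())
    return out


def _iter_tables(rows, cols):
    """All nonnegative integer tables with the given margins."""
    r, c = len(rows), len(cols)

    def fill(i, remaining_cols, acc):
        if i == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                yield acc + [list(last)]
            return
        target = rows[i]

        def cells(j, left, row):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                yield from cells(j + 1, left - v, row + [v])

        for row in cells(0, target, []):
            yield from fill(
                i + 1,
                [remaining_cols[j] - row[j] for j in range(c)],
                acc + [row],
            )

    yield from fill(0, list(cols), [])


def fisher_exact_test(table) -> float:
    """Two-sided Fisher exact test for an r x c contingency table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed one
    (probability-ordering definition, with 1e-7 relative numeric slack).
    """
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("all margins must be positive")
    log_obs = _log_table_prob(t)
    cutoff = log_obs + 1e-7
    p = 0.0
    for cand in _iter_tables(list(rows), list(cols)):
        lp = _log_table_prob(np.asarray(cand))
        if lp <= cutoff:
            p += np.exp(lp)
    return float(min(p, 1.0))


def correlate_scores(x, y) -> tuple[float, float, float]:
    """Pearson correlation: returns (r, r squared, two-sided p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r ** 2), float(p)


def category_percentages(series: pd.Series, decimals: int = 1) -> pd.DataFrame:
    """Counts and rounded percentages per category (cohort-table style)."""
    counts = series.value_counts()
    pct = (counts / len(series) * 100.0).round(decimals)
    return pd.DataFrame({"n": counts, "pct": pct})
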