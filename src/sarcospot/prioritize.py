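"""Candidate prioritization cascade.

Top-k ranking of genes within the CNV-high target cell subset of each tissue,
cross-tissue intersection, intersection with the quadrant-selected gene set,
and a membrane-evidence gate (membrane association / plasma-membrane
localization / transmembrane topology flags combined into a weighted
evidence score).
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "intersect_candidates",
    "rank_subset_genes",
    "score_membrane_evidence",
]

DEFAULT_WEIGHTS = (1.0, 2.0, 3.0)  # membrane, plasma membrane, transmembrane


def rank_subset_genes(
    log1p_cpm: pd.DataFrame, cell_subset, k: int = 30
) -> list[str]:
    """Top-k genes by mean log1p-CPM over a cell subset.

    Ties in the mean break lexicographically by gene id.
    """
    cells = pd.Index(cell_subset)
    if len(cells) == 0:
        raise ValueError("empty cell subset")
    if k > log1p_cpm.shape[1]:
        raise ValueError("k exceeds the panel size")
    means = log1p_cpm.loc[cells].mean(axis=0)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    return list(order[:k])


def score_membrane_evidence(
    is_membrane: bool,
    is_plasma_membrane: bool,
    is_transmembrane: bool,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Weighted evidence score over the three binary membrane annotations."""
    if any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative")
    w_m, w_pm, w_tm = weights
    return (
        w_m * bool(is_membrane)
        + w_pm * bool(is_plasma_membrane)
        + w_tm * bool(is_transmembrane)
    )


def annotate_membrane(
    membrane: pd.DataFrame, weights: tuple[float, float, float] = DEFAULT_WEIGHTS
) -> pd.DataFrame:
    """Add ``evidence_score`` to a membrane annotation table."""
    out = membrane.copy()
    out["evidence_score"] = [
        score_membrane_evidence(m, pm, tm, weights)
        for m, pm, tm in zip(
            out["is_membrane"], out["is_plasma_membrane"], out["is_transmembrane"]
        )
    ]
    return out


def intersect_candidates(
    topk_per_tissue: dict[str, list[str]],
    quadrant_genes,
    membrane: pd.DataFrame,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    min_evidence: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Stepwise intersection cascade with a membrane-evidence gate.

    shared = intersection over tissues of the top-k lists; cascade = shared
    intersected with the quadrant-selected gene set; retained = cascade
    members whose membrane evidence score exceeds ``min_evidence`` (default:
    any positive evidence). Returns the per-gene candidate table and the
    per-stage counts.
    """
    if not topk_per_tissue:
        raise ValueError("at least one tissue top-k list is required")
    quadrant_genes = set(quadrant_genes)
    tissues = list(topk_per_tissue)
    shared = set(topk_per_tissue[tissues[0]])
    for t in tissues[1:]:
        shared &= set(topk_per_tissue[t])
    cascade = shared & quadrant_genes
    membrane = annotate_membrane(membrane.set_index("gene_id") if "gene_id" in membrane else membrane, weights)
    universe = sorted(set().union(*[set(v) for v in topk_per_tissue.values()]) | quadrant_genes)
    missing = [g for g in cascade if g not in membrane.index]
    if missing:
        warnings.warn(
            f"{len(missing)} cascade genes lack membrane annotation; treated as all-false"
        )
    rows = []
    for gene in universe:
        if gene in membrane.index:
            ev = float(membrane.loc[gene, "evidence_score"])
        else:
            ev = 0.0
        membrane_positive = ev > min_evidence
        rows.append(
            {
                "gene_id": gene,
                **{f"in_top{len(topk_per_tissue[t])}_{t}": gene in set(topk_per_tissue[t]) for t in tissues},
                "in_shared": gene in shared,
                "in_quadrant_set": gene in quadrant_genes,
                "evidence_score": ev,
                "membrane_positive": membrane_positive,
                "retained": gene in cascade and membrane_positive,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    counts = {
        **{f"top_k_{t}": len(topk_per_tissue[t]) for t in tissues},
        "shared": len(shared),
        "cascade": len(cascade),
        "retained": int(table["retained"].sum()),
    }
    return table, counts
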