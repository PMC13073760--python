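"""Synthetic cohorts with planted ground truth.

Generators for every input the pipeline consumes: a tumor/normal bulk FPKM
cohort with planted fold-change effects, a cell-line expression panel with
designated high-expressed genes, a spatial single-cell tissue with planted
CNV clones, immune cells and doublets on a fixed gene panel, and an IHC
clinical cohort. Each generator is deterministic under a fixed seed and
returns its ground truth alongside the data, so downstream stages can be
tested for planted-effect recovery without any external download.

Count models: log-normal FPKM for bulk (matching the log2(FPKM + 1)
modelling scale) and negative binomial for spatial counts (overdispersed,
matching the log1p-CPM transforms). Clones are laid out as Gaussian blobs
inside FOV rectangles so planted clusters are spatially coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .bulk import NORMAL, PROTEIN_CODING, TUMOR, BulkExpressionMatrix

__all__ = [
    "BulkTruth",
    "CloneSpec",
    "SpatialTruth",
    "gen_bulk_cohort",
    "gen_cellline_panel",
    "gen_clinical_cohort",
    "gen_spatial_tissue",
]


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# bulk tumor/normal cohort
# ---------------------------------------------------------------------------


@dataclass
class BulkTruth:
    """Ground truth of a generated bulk cohort."""

    planted_up_genes: set
    planted_down_genes: set
    effect_log2fc: float
    group_labels: pd.Series

    def __post_init__(self) -> None:
        if self.planted_up_genes & self.planted_down_genes:
            raise ValueError("planted up and down sets must be disjoint")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")


def gen_bulk_cohort(
    n_genes: int = 5000,
    n_tumor: int = 6,
    n_normal: int = 7,
    n_up: int = 150,
    n_down: int = 50,
    effect_log2fc: float = 2.5,
    seed: int = 0,
    sigma: float = 0.4,
    low_expr_frac: float = 0.2,
    noncoding_frac: float = 0.2,
) -> tuple[BulkExpressionMatrix, BulkTruth]:
    """Tumor/normal FPKM cohort with planted log2 fold-change effects.

    Expressed genes draw log2(FPKM + 1) values from N(mu_g, sigma) with
    mu_g ~ U(2, 9); planted genes shift the tumor-group mean by
    +/- ``effect_log2fc``. A ``low_expr_frac`` fraction of genes sits below
    the FPKM = 1 QC floor, and ``noncoding_frac`` of genes carry a non-coding
    biotype (planted genes are always expressed and coding so the QC keeps
    them).
    """
    if n_tumor < 2 or n_normal < 2:
        raise ValueError("need >= 2 samples per group")
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down must not exceed n_genes")
    if effect_log2fc < 0:
        raise ValueError("effect_log2fc must be >= 0")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    samples = [f"T{i + 1}" for i in range(n_tumor)] + [
        f"N{i + 1}" for i in range(n_normal)
    ]
    groups = pd.Series(
        [TUMOR] * n_tumor + [NORMAL] * n_normal, index=samples, name="group"
    )

    n_low = int(round(low_expr_frac * n_genes))
    n_noncoding = int(round(noncoding_frac * n_genes))
    perm = rng.permutation(n_genes)
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]
    rest = perm[n_up + n_down :]
    low_idx = rest[:n_low]
    noncoding_idx = rest[n_low : n_low + n_noncoding]

    mu = rng.uniform(2.0, 9.0, size=n_genes)
    mu[low_idx] = rng.uniform(0.0, 0.6, size=len(low_idx))
    # keep planted-down genes well above the floor after the shift
    mu[down_idx] = rng.uniform(4.0 + effect_log2fc, 9.0, size=len(down_idx))

    mu_mat = np.tile(mu[:, None], (1, n_tumor + n_normal))
    mu_mat[np.ix_(up_idx, np.arange(n_tumor))] += effect_log2fc
    mu_mat[np.ix_(down_idx, np.arange(n_tumor))] -= effect_log2fc
    y = np.maximum(rng.normal(mu_mat, sigma), 0.0)
    fpkm = 2.0 ** y - 1.0

    biotype = np.full(n_genes, PROTEIN_CODING, dtype=object)
    biotype[noncoding_idx] = "lincRNA"
    matrix = BulkExpressionMatrix(
        pd.DataFrame(fpkm, index=genes, columns=samples),
        groups,
        pd.Series(biotype, index=genes, name="biotype"),
    )
    gene_arr = np.asarray(genes)
    truth = BulkTruth(
        planted_up_genes=set(gene_arr[up_idx]),
        planted_down_genes=set(gene_arr[down_idx]),
        effect_log2fc=float(effect_log2fc),
        group_labels=groups,
    )
    return matrix, truth


def gen_cellline_panel(
    n_genes: int = 5000,
    n_samples: int = 2,
    high_genes: set | None = None,
    seed: int = 0,
    upshift: float = 5.0,
    gene_ids: list[str] | None = None,
) -> BulkExpressionMatrix:
    """Cell-line FPKM panel; ``high_genes`` draw from an upshifted distribution.

    Baseline log2(FPKM + 1) values are N(4, 1.5); designated genes add
    ``upshift`` log2 units so their within-sample ECDF percentile clears a
    high floor in expectation.
    """
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    if len(genes) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    high_genes = set(high_genes or ())
    unknown = high_genes - set(genes)
    if unknown:
        raise KeyError(f"unknown gene ids in high_genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    samples = [f"CL{i + 1}" for i in range(n_samples)]
    y = rng.normal(4.0, 1.5, size=(n_genes, n_samples))
    if high_genes:
        mask = np.isin(np.asarray(genes), list(high_genes))
        y[mask] += upshift
    fpkm = np.maximum(2.0 ** y - 1.0, 0.0)
    groups = pd.Series([TUMOR] * n_samples, index=samples, name="group")
    biotype = pd.Series(PROTEIN_CODING, index=genes, name="biotype")
    return BulkExpressionMatrix(
        pd.DataFrame(fpkm, index=genes, columns=samples), groups, biotype
    )


# ---------------------------------------------------------------------------
# spatial tissue
# ---------------------------------------------------------------------------


@dataclass
class CloneSpec:
    """A planted tumor clone.

    ``segments`` are (chrom, start gene index, end gene index, copy ratio)
    with indices 0-based half-open in the within-chromosome panel ordering
    and copy ratio 1.0 = neutral.
    """

    name: str
    fraction: float
    segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    label: str = "Mid fibro"


DEFAULT_CLONES = [
    CloneSpec("neutral", 0.75, [], label="Early fibro"),
    CloneSpec(
        "aberrant",
        0.25,
        [("chr1", 100, 250, 1.5), ("chr2", 100, 200, 1.5)],
        label="Mid fibro",
    ),
]


@dataclass
class SpatialTruth:
    """Ground truth of a generated spatial tissue."""

    clone_of_cell: pd.Series
    cnv_segments: dict[str, list[tuple[str, int, int, float]]]
    immune_cells: set
    doublet_cells: set
    cluster_of_cell: pd.Series

    def __post_init__(self) -> None:
        tumor_cells = set(self.clone_of_cell.index[self.clone_of_cell.notna()])
        if tumor_cells & self.immune_cells:
            raise ValueError("immune and tumor-clone assignments must be disjoint")

    def aberrant_cells(self) -> set:
        """Cells belonging to a clone with at least one non-neutral segment."""
        aberrant_clones = {
            name
            for name, segs in self.cnv_segments.items()
            if any(abs(r - 1.0) > 1e-12 for _, _, _, r in segs)
        }
        return set(
            self.clone_of_cell.index[self.clone_of_cell.isin(aberrant_clones)]
        )


def _gene_positions(genes: list[str], n_chroms: int = 2) -> pd.DataFrame:
    """Genes placed uniformly on a synthetic genome, in panel order."""
    n = len(genes)
    per = int(np.ceil(n / n_chroms))
    chrom = [f"chr{i // per + 1}" for i in range(n)]
    start, rows = [], []
    within = {}
    for i, g in enumerate(genes):
        j = within.setdefault(chrom[i], 0)
        within[chrom[i]] = j + 1
        rows.append((g, chrom[i], j * 1000, j * 1000 + 500))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end"]
    ).set_index("gene_id")


def gen_spatial_tissue(
    n_cells: int = 3000,
    n_genes: int = 1000,
    n_fovs: int = 4,
    clones: list[CloneSpec] | None = None,
    immune_frac: float = 0.1,
    doublet_frac: float = 0.05,
    seed: int = 0,
    tissue_id: str = "xeno1",
    low_quality_frac: float = 0.02,
    nb_theta: float = 10.0,
    n_marker_genes: int = 30,
    marker_fold: float = 3.0,
    depth_sigma: float = 0.3,
) -> tuple[ad.AnnData, SpatialTruth]:
    """One xenograft-style tissue on a fixed gene panel.

    Counts are negative binomial around per-gene log-normal base means scaled
    per cell by a log-normal depth factor; cells of a clone multiply the base
    mean of in-segment genes by the segment copy ratio and additionally
    upregulate a scattered clone-marker gene set (``marker_fold``) so planted
    populations are separable by expression clustering. Immune cells carry
    high CD45 intensity; ``doublet_frac`` of cells add a second cell's counts
    and are flagged; ``low_quality_frac`` of cells are generated at ~1% depth
    so they fall under the 20-detected-genes QC floor.
    """
    for frac in (immune_frac, doublet_frac, low_quality_frac):
        if not (0 <= frac < 1):
            raise ValueError("fractions must be in [0, 1)")
    clones = DEFAULT_CLONES if clones is None else clones
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes, prefix="P")
    positions = _gene_positions(genes)
    chrom_sizes = positions["chrom"].value_counts().to_dict()
    for clone in clones:
        for chrom, lo, hi, ratio in clone.segments:
            if ratio <= 0:
                raise ValueError("copy ratio must be > 0")
            if chrom not in chrom_sizes or not (0 <= lo < hi <= chrom_sizes[chrom]):
                raise ValueError(
                    f"segment ({chrom}, {lo}, {hi}) outside the gene ordering"
                )

    cell_ids = [f"{tissue_id}_c{i:05d}" for i in range(n_cells)]
    n_immune = int(round(immune_frac * n_cells))
    order = rng.permutation(n_cells)
    immune_idx = order[:n_immune]
    tumor_idx = order[n_immune:]
    fracs = np.array([c.fraction for c in clones], float)
    fracs = fracs / fracs.sum()
    clone_assign = np.full(n_cells, -1)
    bounds = np.floor(np.cumsum(fracs) * len(tumor_idx)).astype(int)
    start = 0
    for ci, end in enumerate(bounds):
        clone_assign[tumor_idx[start:end]] = ci
        start = end
    clone_assign[tumor_idx[start:]] = len(clones) - 1

    base_mean = rng.lognormal(mean=1.3, sigma=0.5, size=n_genes)
    # per-clone multiplicative factors: CNV segments + scattered markers
    clone_factor = np.ones((len(clones), n_genes))
    chrom_offsets = {}
    off = 0
    for chrom in positions["chrom"].unique():
        chrom_offsets[chrom] = off
        off += chrom_sizes[chrom]
    for ci, clone in enumerate(clones):
        for chrom, lo, hi, ratio in clone.segments:
            sl = slice(chrom_offsets[chrom] + lo, chrom_offsets[chrom] + hi)
            clone_factor[ci, sl] *= ratio
        if n_marker_genes > 0:
            markers = rng.choice(n_genes, size=n_marker_genes, replace=False)
            clone_factor[ci, markers] *= marker_fold
    immune_factor = np.ones(n_genes)
    if n_marker_genes > 0:
        markers = rng.choice(n_genes, size=n_marker_genes, replace=False)
        immune_factor[markers] *= marker_fold

    depth = rng.lognormal(mean=0.0, sigma=depth_sigma, size=n_cells)
    n_low = int(round(low_quality_frac * n_cells))
    low_idx = rng.choice(n_cells, size=n_low, replace=False)
    depth[low_idx] *= 0.002

    mean_mat = np.empty((n_cells, n_genes))
    for i in range(n_cells):
        factor = immune_factor if clone_assign[i] < 0 else clone_factor[clone_assign[i]]
        mean_mat[i] = base_mean * factor * depth[i]
    # negative binomial via gamma-Poisson mixture
    lam = rng.gamma(shape=nb_theta, scale=mean_mat / nb_theta)
    counts = rng.poisson(lam).astype(np.int64)

    n_doublet = int(round(doublet_frac * n_cells))
    doublet_idx = rng.choice(n_cells, size=n_doublet, replace=False)
    partners = rng.integers(0, n_cells, size=n_doublet)
    counts[doublet_idx] += counts[partners]

    # spatial layout: FOV grid, Gaussian blob per (fov, population)
    fov_of_cell = rng.integers(0, n_fovs, size=n_cells)
    fov_grid = int(np.ceil(np.sqrt(n_fovs)))
    fov_origin = np.array(
        [[(f % fov_grid) * 0.5, (f // fov_grid) * 0.5] for f in range(n_fovs)]
    )
    pop_of_cell = np.where(clone_assign < 0, len(clones), clone_assign)
    # well-separated blob centers per (FOV, population): a ring inside the FOV
    n_pops = len(clones) + 1
    angles = 2 * np.pi * (np.arange(n_pops)[None, :] + rng.uniform(0, 1, (n_fovs, 1))) / n_pops
    blob_centers = 0.25 + 0.15 * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
    xy = (
        fov_origin[fov_of_cell]
        + blob_centers[fov_of_cell, pop_of_cell]
        + rng.normal(0.0, 0.04, size=(n_cells, 2))
    )

    cd45 = np.clip(rng.normal(1.0, 0.5, size=n_cells), 0, None)
    cd45[immune_idx] = rng.normal(8.0, 1.0, size=n_immune)
    cd68 = np.clip(rng.normal(0.5, 0.3, size=n_cells), 0, None)
    cd68[immune_idx] += rng.normal(2.0, 0.5, size=n_immune)

    labels = np.empty(n_cells, dtype=object)
    for ci, clone in enumerate(clones):
        labels[clone_assign == ci] = clone.label
    labels[immune_idx] = "Immune"
    doublet_flag = np.zeros(n_cells, dtype=bool)
    doublet_flag[doublet_idx] = True

    obs = pd.DataFrame(
        {
            "tissue_id": tissue_id,
            "fov": fov_of_cell,
            "x_slide_mm": xy[:, 0],
            "y_slide_mm": xy[:, 1],
            "cd45_intensity": cd45,
            "cd68_intensity": cd68,
            "doublet_flag": doublet_flag,
            "cell_label": labels,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = positions.copy()
    adata = ad.AnnData(X=counts, obs=obs, var=var)

    clone_names = np.array([c.name for c in clones] + [None], dtype=object)
    clone_series = pd.Series(
        clone_names[pop_of_cell], index=obs.index, name="clone"
    )
    cluster_series = pd.Series(
        np.where(clone_assign < 0, "immune", clone_series.to_numpy()),
        index=obs.index,
        name="cluster",
    )
    truth = SpatialTruth(
        clone_of_cell=clone_series,
        cnv_segments={c.name: list(c.segments) for c in clones},
        immune_cells=set(obs.index[immune_idx]),
        doublet_cells=set(obs.index[doublet_idx]),
        cluster_of_cell=cluster_series,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

LOCALIZATIONS = ["C", "C/M", "C/M/N"]
SUBTYPES = ["UPS", "USS", "UES", "US"]


def gen_clinical_cohort(
    n: int = 30, effect: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """IHC-scored clinical cohort table.

    ``effect`` controls the association between outcome and the IHC readouts:
    DOD patients shift positivity upward by ``effect`` percent points and
    tilt the localization distribution away from pure cytosolic staining by
    odds factor (1 + effect/25). ``effect=0`` generates the null. Category
    frequencies (subtype, grade, presentation) follow the cohort structure of
    a 30-patient undifferentiated-sarcoma series.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    rng = np.random.default_rng(seed)
    patients = [f"PT{i + 1:03d}" for i in range(n)]
    survival = rng.choice(["Alive", "DOD"], size=n, p=[0.6, 0.4])
    # guarantee both groups occur so group tests are defined
    if len(np.unique(survival)) == 1:
        survival[rng.integers(0, n)] = "DOD" if survival[0] == "Alive" else "Alive"
    positivity = np.clip(
        rng.uniform(20, 95, size=n) + np.where(survival == "DOD", effect, 0.0),
        0.0,
        100.0,
    )
    frac_pos = positivity / 100.0
    pos_split = rng.dirichlet(np.ones(3), size=n)
    fracs = np.column_stack([1.0 - frac_pos, pos_split * frac_pos[:, None]])
    h = np.array([100.0 * (f[1] + 2 * f[2] + 3 * f[3]) for f in fracs])
    pathologist = np.clip(np.ceil(h / 100.0), 1, 3).astype(int)

    base_loc = np.array([0.50, 0.43, 0.07])
    tilt = 1.0 + max(effect, 0.0) / 25.0
    loc = np.empty(n, dtype=object)
    for i in range(n):
        p = base_loc * (np.array([1.0, tilt, tilt]) if survival[i] == "DOD" else 1.0)
        loc[i] = rng.choice(LOCALIZATIONS, p=p / p.sum())

    table = pd.DataFrame(
        {
            "patient_id": patients,
            "subtype": rng.choice(SUBTYPES, size=n, p=[23 / 30, 5 / 30, 1 / 30, 1 / 30]),
            "grade": rng.choice(["I", "II", "III"], size=n, p=[0.0, 4 / 30, 26 / 30]),
            "presentation": rng.choice(
                ["primary", "local recurrence", "metastasis"],
                size=n,
                p=[18 / 30, 7 / 30, 5 / 30],
            ),
            "pathologist_score": pathologist,
            "positivity_pct": positivity,
            "frac_intensity0": fracs[:, 0],
            "frac_intensity1": fracs[:, 1],
            "frac_intensity2": fracs[:, 2],
            "frac_intensity3": fracs[:, 3],
            "h_score": h,
            "localization": loc,
            "survival": survival,
        }
    ).set_index("patient_id")
    return table
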