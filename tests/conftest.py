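import numpy as np
import pandas as pd
import pytest

import sarcospot as ss


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default tumor/normal cohort with planted effects."""
    return ss.gen_bulk_cohort(seed=11)


@pytest.fixture(scope="session")
def small_tissue():
    """One small spatial tissue for unit-level checks."""
    return ss.gen_spatial_tissue(n_cells=900, seed=5)


def run_cnv_pipeline(adata, knn_k=10, **kwargs):
    """QC + normalize + two-pass CNV with the analysis defaults."""
    q = ss.qc_filter_cells(adata)
    ss.normalize_counts(q)
    log1p = pd.DataFrame(
        q.layers["log1p_cpm"], index=q.obs_names, columns=q.var_names
    )
    est = ss.TwoPassCNV(knn_k=knn_k, **kwargs).fit(
        log1p,
        positions=q.var,
        tissue_ids=q.obs["tissue_id"].to_numpy(),
        coords=q.obs[["x_slide_mm", "y_slide_mm"]].to_numpy(),
        total_counts=np.asarray(q.X).sum(axis=1),
    )
    return q, log1p, est


@pytest.fixture(scope="session")
def cnv_band():
    """Two-pass CNV runs on the planted-clone band (3000 cells, ratio 1.5)."""
    out = []
    for seed in (1, 2, 3):
        adata, truth = ss.gen_spatial_tissue(n_cells=3000, seed=seed)
        q, log1p, est = run_cnv_pipeline(adata)
        out.append((q, log1p, est, truth))
    return out


@pytest.fixture(scope="session")
def reference_purity_runs():
    """Reference selection on 80/20 neutral/aberrant tissues over 20 seeds."""
    clones = [
        ss.CloneSpec("neutral", 0.8, [], label="Early fibro"),
        ss.CloneSpec(
            "aberrant", 0.2, [("chr1", 100, 250, 1.5), ("chr2", 100, 200, 1.5)]
        ),
    ]
    results = []
    for seed in range(20):
        adata, truth = ss.gen_spatial_tissue(
            n_cells=1200, clones=clones, seed=100 + seed
        )
        q, log1p, est = run_cnv_pipeline(adata)
        refs = set(log1p.index[est.is_reference_])
        neutral = set(q.obs_names) - truth.aberrant_cells()
        results.append(refs <= neutral)
    return results
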