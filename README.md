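# sarcospot

Integrative biomarker discovery for undifferentiated sarcomas (US), built as
a reusable, tested Python pipeline. Undifferentiated sarcomas are aggressive
mesenchymal cancers with few molecular markers; candidate cell-surface
biomarkers can be triangulated by combining bulk tumor-vs-normal expression,
cell-line transcriptomes, and spatial single-cell profiling of xenograft
tumors. `sarcospot` implements that triangulation end to end:

* **Bulk differential expression** — expression QC (FPKM >= 1 in >= 20% of
  samples, overall or within a group; protein-coding only), per-gene linear
  models on log2(FPKM + 1) with empirical-Bayes variance moderation
  (s~² = (d₀s₀² + d s²)/(d₀ + d), moderated t on d + d₀ df), BH correction,
  and DEG classification at FDR < 0.01 and |log2FC| >= 2.
* **Pathway scoring** — GSVA-style single-sample scores (Gaussian-kernel CDF,
  weighted KS random walk) on gene sets restricted to tumor-upregulated
  genes (sets with < 10 genes dropped), with moderated differential pathway
  testing at FDR < 0.05.
* **Quadrant spotlight** — a scale-free integration of two datasets without
  shared normalization: ΔNT = tumor median − normal median of log2(FPKM + 1)
  per gene vs. the median within-sample ECDF percentile among a DEG subset
  in cell lines; selection at ΔNT > 0 and percentile >= the subset's 80th
  percentile.
* **Spatial preprocessing and two-pass CNV inference** — CosMx-style QC
  (selected FOVs, CD45-negative, >= 20 detected genes, singlets), CPM/log1p
  and TMM normalization, SNN/Leiden clustering on batch-centered PCs, then
  self-referencing copy-number inference: pass 1 scores each cell's
  deviation from the tissue-mean profile, the least-deviant 20–40% become
  internal references, pass 2 yields per-cell CNV_level (median inferred
  copy number) and CNV_score (upper-tail |log2 ratio|), optional
  distance-weighted kNN smoothing, and tissue-wise CNV-high calls at
  mean + 1 sd.
* **Candidate prioritization** — top-30 genes by mean log1p CPM within the
  CNV-high target subset per tissue, intersected across tissues and with the
  quadrant-selected set, then gated on membrane-evidence annotations
  (membrane / plasma membrane / transmembrane, weighted 1/2/3).
* **Clinical statistics** — IHC H-scores (intensity 0–3 × percent positive,
  range 0–300), Wilcoxon rank-sum, exact r×c Fisher tests, Pearson
  correlation, and cohort summary tables.
* **Synthetic data** — deterministic generators for every input (bulk
  cohort, cell-line panel, spatial tissues with planted CNV clones, immune
  cells and doublets, clinical cohort) with ground truth, so every stage is
  testable offline.

See `docs/methods.md` for the models, parameter defaults, and limitations.

## Worked example

```python
import sarcospot as ss

# 6 tumor vs 7 normal bulk cohort with planted 2.5-log2FC effects
matrix, truth = ss.gen_bulk_cohort(seed=7)
filtered = ss.filter_expressed_genes(matrix)          # QC + coding-only
de = ss.ModeratedDE().fit(filtered)                   # moderated t + BH
print(de.summary_counts())

# integrate with a cell-line panel over 101 tumor-up genes
up = sorted(de.results_.index[de.results_["class"] == "up"])[:101]
cells = ss.gen_cellline_panel(n_genes=101, high_genes=set(up[:25]),
                              seed=8, gene_ids=up)
table = ss.build_quadrant_table(matrix, cells, up)
print(len(ss.select_quadrant_genes(table)), "of", len(table), "genes selected")
```

prints

```
{'up': 150, 'down': 48, 'unchanged': 2910, 'total_degs': 198, 'total': 3108}
21 of 101 genes selected
```

3108 coding genes pass QC; the classifier recovers essentially all 150 + 50
planted effects (198 DEGs, a handful lost to the QC floor) and nothing else.
The quadrant rule then keeps exactly the 21 genes at the top-fifth of the
cell-line percentile distribution with positive tumor–normal shift — the
genes planted high in both modalities.

The same objects drive the spatial arm: `ss.gen_spatial_tissue` produces a
CosMx-style tissue with planted clones, `ss.qc_filter_cells` +
`ss.normalize_counts` + `ss.TwoPassCNV` recover CNV-high cells against
truth, and `ss.intersect_candidates` runs the final cascade. A thin CLI
(`sarcospot simulate|de|quadrant|cnv|prioritize|clinstats`) wraps these for
shell use.

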