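# tcalign

Unsupervised alignment of bulk tumor and cancer cell line RNA-seq expression
profiles, with tumor-type classification of cell lines from the aligned
space.

Tumor profiles are confounded by normal-cell contamination (variable tumor
purity) and by systematic tumor-vs-cell-line differences. `tcalign` removes
these in two stages:

1. **Cluster-conditioned contrastive PCA** — each dataset is clustered
   separately (SNN graph in 70-dimensional PCA space, Leiden at resolution
   5), cluster means are subtracted, and the top eigenvectors of
   `Cov_tumor − Cov_cell_line` (tumor-enriched variation, i.e. contamination
   axes) are estimated; the first 4 components are regressed out of both
   datasets.
2. **Asymmetric-k mutual-nearest-neighbor correction** — genes are ranked by
   between-cluster variability (empirical-Bayes moderated F statistics) and
   the union of the top 1000 per dataset defines the neighbor-search space;
   mutual nearest neighbors (k=5 over cell lines, k=50 over tumors, cell
   lines as the fixed reference) yield per-pair difference vectors that are
   Gaussian-kernel-smoothed into a per-tumor correction.

In the aligned space each cell line is classified as the modal tumor type
among its 25 highest-correlated tumors (Pearson over all genes), and a UMAP
(first 70 PCs, `n_neighbors=10`, `min_dist=0.5`) provides the 2D map.

A fully ground-truthed synthetic data generator (`tcalign.simulate`)
emulates the assumed structure — shared disease-type clusters, Beta-drawn
purity, a low-rank nonnegative contamination component scaled by
`1 − purity`, global plus type-specific dataset offsets, dataset-exclusive
types, composition imbalance — so the whole pipeline is testable without
downloads.

## Usage

Python:

```python
from tcalign import PipelineConfig, load_expression_matrix, run_pipeline

tumors = load_expression_matrix("tumor_expression.tsv", "tumor")
cell_lines = load_expression_matrix("cell_line_expression.tsv", "cell_line")
result = run_pipeline(tumors, cell_lines, PipelineConfig(rng_seed=0))
result.report.predicted_type     # per-cell-line tumor type
result.combined_frame()          # aligned combined matrix
```

CLI:

```sh
# generate a synthetic dataset with ground truth
tcalign simulate --seed 1 --out sim/

# align and classify (writes aligned matrix, clusters, F stats, MNN pairs,
# cPC loadings/eigenvalues, predictions, correlations, UMAP coordinates)
tcalign align --tumors sim/tumor_expression.tsv \
              --cell-lines sim/cell_line_expression.tsv \
              --tumor-annot sim/tumor_annotations.tsv \
              --cl-annot sim/cell_line_annotations.tsv \
              --out out/ --rng-seed 1
```

Inputs are samples-by-genes (or genes-by-samples; orientation is
auto-detected) TSV/CSV or HDF5 matrices of log2(TPM+1) values restricted to
a shared gene namespace. Every method parameter has a CLI flag mirroring
`PipelineConfig` (e.g. `--k-tumor`, `--snn-resolution`), or pass
`--config config.yaml`.

## Tests and acceptance report

```sh
python -m pytest tests/            # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` asserts the acceptance criteria (moderated-F
oracle equivalence, closed-form contrastive PCA, exact MNN enumeration,
end-to-end synthetic recovery, determinism, invariants) on fixed-seed
fixtures. `scripts/acceptance.py` recomputes the same quantities for an
arbitrary seed and prints them; it writes an empty target JSON because no
numeric targets are reproducible at desk scale without the full public
tumor and cell-line compendia.
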