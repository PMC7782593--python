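"""End-to-end alignment pipeline.

Stages: per-dataset SNN clustering in PCA space -> cluster-mean
residualization -> contrastive PCA of the two intra-cluster covariances ->
regress out the top tumor-enriched components from both datasets ->
moderated-F union gene selection -> asymmetric-k mutual-nearest-neighbor
correction of tumors toward the cell-line reference -> similarity report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import cpca as _cpca
from . import mnn as _mnn
from . import select as _select
from . import similarity as _similarity
from .config import PipelineConfig
from .io import ExpressionMatrix, SampleAnnotation, harmonize_genes, lineages_for
from .similarity import SimilarityReport

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    gene_ids: list[str]
    tumor_ids: list[str]
    cell_line_ids: list[str]
    tumor_clusters: _cluster.ClusterAssignment
    cell_line_clusters: _cluster.ClusterAssignment
    cpca: _cpca.ContrastiveComponents
    tumor_gene_table: _select.GeneVariabilityTable
    cell_line_gene_table: _select.GeneVariabilityTable
    union_genes: list[str]
    pairing: _mnn.MNNPairing
    correction: _mnn.CorrectionField
    cell_lines_aligned: np.ndarray  # cell lines x genes (cPCA-residualized)
    tumors_aligned: np.ndarray  # tumors x genes (cPCA-residualized + MNN)
    report: SimilarityReport
    tumor_lineages: list[str]
    cell_line_lineages: list[str]
    config: PipelineConfig

    @property
    def combined_values(self) -> np.ndarray:
        """Aligned combined matrix, cell lines first."""
        return np.vstack([self.cell_lines_aligned, self.tumors_aligned])

    @property
    def combined_sample_ids(self) -> list[str]:
        return self.cell_line_ids + self.tumor_ids

    @property
    def combined_datasets(self) -> list[str]:
        return ["cell_line"] * len(self.cell_line_ids) + ["tumor"] * len(self.tumor_ids)

    def combined_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.combined_values, index=self.combined_sample_ids, columns=self.gene_ids
        )
        df.insert(0, "dataset", self.combined_datasets)
        df.index.name = "sample_id"
        return df


def run_pipeline(
    tumors: ExpressionMatrix,
    cell_lines: ExpressionMatrix,
    config: PipelineConfig | None = None,
    tumor_annotations: SampleAnnotation | None = None,
    cell_line_annotations: SampleAnnotation | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    tumors, cell_lines = harmonize_genes(tumors, cell_lines)
    gene_ids = list(tumors.gene_ids)
    tumor_lineages = lineages_for(tumors, tumor_annotations).tolist()
    cl_lineages = lineages_for(cell_lines, cell_line_annotations).tolist()

    # Stage 1: per-dataset clustering and cluster-conditioned contrastive PCA.
    t_clusters = _cluster.cluster_samples(
        tumors.values, tumors.sample_ids, "tumor",
        cfg.n_pcs, cfg.snn_k, cfg.snn_resolution, cfg.rng_seed, cfg.snn_prune,
    )
    c_clusters = _cluster.cluster_samples(
        cell_lines.values, cell_lines.sample_ids, "cell_line",
        cfg.n_pcs, cfg.snn_k, cfg.snn_resolution, cfg.rng_seed, cfg.snn_prune,
    )
    logger.info(
        "clusters: %d tumor, %d cell line",
        t_clusters.n_clusters, c_clusters.n_clusters,
    )
    t_resid = _cluster.subtract_cluster_means(tumors.values, t_clusters.labels)
    c_resid = _cluster.subtract_cluster_means(cell_lines.values, c_clusters.labels)

    n_cpcs = min(
        max(cfg.n_cpcs_removed, 10), len(gene_ids),
        tumors.n_samples - 1, cell_lines.n_samples - 1,
    )
    comps = _cpca.contrastive_components(
        _cpca.intra_cluster_covariance(t_resid),
        _cpca.intra_cluster_covariance(c_resid),
        n_components=n_cpcs,
        alpha=cfg.cpca_alpha,
    )
    n_remove = min(cfg.n_cpcs_removed, n_cpcs)
    tumors_deconf = _cpca.regress_out_components(tumors.values, comps, n_remove)
    cl_deconf = _cpca.regress_out_components(cell_lines.values, comps, n_remove)

    # Stage 2: union gene set and asymmetric-k MNN correction.
    if cfg.f_stats_input == "raw":
        t_fin, c_fin = tumors.values, cell_lines.values
    else:
        t_fin, c_fin = tumors_deconf, cl_deconf
    t_table = _select.moderated_f_stats(t_fin, t_clusters.labels, gene_ids, "tumor")
    c_table = _select.moderated_f_stats(c_fin, c_clusters.labels, gene_ids, "cell_line")
    n_top = min(cfg.n_top_genes_per_dataset, len(gene_ids))
    union_genes = _select.select_union_genes(t_table, c_table, n_top)

    k_cl = min(cfg.k_cell_line, cell_lines.n_samples - 1)
    k_t = min(cfg.k_tumor, tumors.n_samples - 1)
    pairing = _mnn.find_mutual_nn(
        cl_deconf, tumors_deconf,
        cell_lines.sample_ids, tumors.sample_ids,
        gene_ids, union_genes, k_cl, k_t,
    )
    logger.info("%d mutual nearest neighbor pairs", pairing.n_pairs)
    correction = _mnn.compute_correction(
        pairing, cl_deconf, tumors_deconf, gene_ids, cfg.mnn_sigma_multiplier
    )
    tumors_aligned = _mnn.apply_correction(tumors_deconf, correction)

    report = _similarity.build_similarity_report(
        cl_deconf, tumors_aligned,
        cell_lines.sample_ids, tumors.sample_ids,
        tumor_lineages, cl_lineages, min(cfg.k_classify, tumors.n_samples),
    )
    return PipelineResult(
        gene_ids=gene_ids,
        tumor_ids=list(tumors.sample_ids),
        cell_line_ids=list(cell_lines.sample_ids),
        tumor_clusters=t_clusters,
        cell_line_clusters=c_clusters,
        cpca=comps,
        tumor_gene_table=t_table,
        cell_line_gene_table=c_table,
        union_genes=union_genes,
        pairing=pairing,
        correction=correction,
        cell_lines_aligned=cl_deconf,
        tumors_aligned=tumors_aligned,
        report=report,
        tumor_lineages=tumor_lineages,
        cell_line_lineages=cl_lineages,
        config=cfg,
    )


def baseline_report(
    tumors: ExpressionMatrix,
    cell_lines: ExpressionMatrix,
    config: PipelineConfig | None = None,
    tumor_annotations: SampleAnnotation | None = None,
    cell_line_annotations: SampleAnnotation | None = None,
) -> SimilarityReport:
    """Similarity report on the RAW (unaligned) combined data, for contrast."""
    cfg = config or PipelineConfig()
    tumors, cell_lines = harmonize_genes(tumors, cell_lines)
    return _similarity.build_similarity_report(
        cell_lines.values, tumors.values,
        cell_lines.sample_ids, tumors.sample_ids,
        lineages_for(tumors, tumor_annotations).tolist(),
        lineages_for(cell_lines, cell_line_annotations).tolist(),
        min(cfg.k_classify, tumors.n_samples),
    )
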