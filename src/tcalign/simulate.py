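"""Synthetic paired tumor / cell-line expression data with full ground truth.

The generator emulates the structure the alignment method assumes: shared
disease-type cluster structure, per-tumor purity from a Beta distribution, a
low-rank contamination component scaled by (1 - purity), a global plus
type-specific tumor-vs-cell-line offset, dataset-exclusive types, and i.i.d.
Gaussian noise, all on the log2(TPM+1) scale (clipped at 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpca import ContrastiveComponents
from .io import ExpressionMatrix, SampleAnnotation
from .similarity import SimilarityReport, pairwise_correlation

logger = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    tumor_types: list[str]
    cell_line_types: list[str]
    purity: np.ndarray  # per tumor, in (0, 1]
    contamination_loadings: np.ndarray  # genes x r, unit-norm columns
    dataset_offset: np.ndarray
    type_offsets: dict[str, np.ndarray]
    exclusive_types: tuple[set[str], set[str]]  # (tumor_only, cell_line_only)
    seed: int
    clip_fraction: float = 0.0
    type_names: list[str] = field(default_factory=list)

    def tumor_annotation(self) -> SampleAnnotation:
        return _annotation(self._tumor_ids, self.tumor_types, "tumor")

    def cell_line_annotation(self) -> SampleAnnotation:
        return _annotation(self._cl_ids, self.cell_line_types, "cell_line")

    _tumor_ids: list[str] = field(default_factory=list)
    _cl_ids: list[str] = field(default_factory=list)


def _allocate(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n samples to weighted groups."""
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def _annotation(ids: list[str], types: list[str], dataset: str) -> SampleAnnotation:
    return SampleAnnotation(
        pd.DataFrame({"sample_id": ids, "lineage": types, "subtype": "unknown"}),
        dataset,
    )


def generate(
    seed: int,
    n_genes: int = 2000,
    n_types: int = 6,
    n_cell_lines: int = 60,
    n_tumors: int = 600,
    r_contamination: int = 3,
    purity_shape: tuple[float, float] = (4.0, 2.0),
    noise_sd: float = 0.2,
    offset_scale: float = 0.5,
    type_sd: float = 0.4,
    subtype_separation: float = 0.4,
    contamination_scale: float = 200.0,
    program_scale: float = 4.5,
    contamination_overlap: float = 0.25,
    contamination_noise_sd: float = 0.0,
    composition_imbalance: float = 3.0,
    cl_heterogeneity: float = 0.0,
    cl_axis_sd: float = 1.2,
    base_range: tuple[float, float] = (6.5, 7.5),
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Draw a paired synthetic dataset; bit-reproducible from ``seed``."""
    if n_types < 3:
        raise ValueError("need n_types >= 3 (one tumor-only, one cell-line-only)")
    for name, val in (
        ("noise_sd", noise_sd),
        ("offset_scale", offset_scale),
        ("type_sd", type_sd),
        ("contamination_scale", contamination_scale),
    ):
        if val < 0:
            raise ValueError(f"{name} must be >= 0")
    # Independent streams: structural parameters, tumor draws, cell-line
    # draws. Purity/contamination parameters therefore cannot perturb the
    # cell-line dataset.
    ss = np.random.SeedSequence(seed)
    rng, rng_tumor, rng_cl = (np.random.default_rng(s) for s in ss.spawn(3))

    type_names = [f"type_{i:02d}" for i in range(n_types)]
    tumor_only = {type_names[-1]}
    cl_only = {type_names[-2]}
    tumor_eligible = [t for t in type_names if t not in cl_only]
    cl_eligible = [t for t in type_names if t not in tumor_only]
    if n_tumors < len(tumor_eligible) or n_cell_lines < len(cl_eligible):
        raise ValueError("fewer than 1 sample per eligible type")

    base = rng.uniform(base_range[0], base_range[1], n_genes)
    # Disease types come in confusable pairs within well-separated lineage
    # groups (dataset-exclusive types get their own groups): raw-data
    # classification confuses paired subtypes, aligned data resolves them.
    shared = type_names[:-2]
    groups = [shared[i : i + 2] for i in range(0, len(shared), 2)]
    groups += [[t] for t in type_names[-2:]]

    # Contamination signatures are nonnegative expression profiles (stromal /
    # immune cell programs): the first is the global expression-level axis
    # (the purity confound moves samples along it), the rest are random
    # nonnegative signatures. The planted subspace is their span.
    cols = [base / np.linalg.norm(base)]
    for _ in range(r_contamination - 1):
        sig = np.abs(rng.normal(0.0, 1.0, n_genes))
        cols.append(sig / np.linalg.norm(sig))
    L = np.column_stack(cols)
    QL, _ = np.linalg.qr(L)

    def _type_shift(sd: float) -> np.ndarray:
        # Disease-type axes are drawn nearly orthogonal to the contamination
        # subspace: type identity and contamination are mostly independent
        # signals (so removing one cannot erase the other), with a small
        # residual overlap through which contamination confuses raw-data
        # similarity.
        shift = rng.normal(0.0, sd, n_genes)
        return shift - (1.0 - contamination_overlap) * (QL @ (QL.T @ shift))

    centroids: dict[str, np.ndarray] = {}
    for group in groups:
        group_centroid = base + _type_shift(type_sd)
        for t in group:
            centroids[t] = group_centroid + _type_shift(type_sd * subtype_separation)
    # The global tumor-vs-cell-line shift is the dominant systematic offset;
    # type-specific offsets are an order of magnitude smaller (local,
    # correctable wrinkles on top of it).
    dataset_offset = rng.normal(0.0, offset_scale, n_genes)
    type_offsets = {
        t: rng.normal(0.0, 0.1 * offset_scale, n_genes) for t in type_names
    }

    # Tumor type composition is deliberately imbalanced (1:4 within each
    # subtype pair, a large exclusive share), while cell lines are balanced:
    # composition differences between the datasets are one of the confounders
    # the alignment must tolerate.
    imb = composition_imbalance
    pair_weights = {}
    for group in groups:
        if len(group) == 2:
            pair_weights[group[0]], pair_weights[group[1]] = 1.0, imb
        else:
            pair_weights[group[0]] = (1.0 + imb) / 2.0
    pair_weights[next(iter(tumor_only))] = 1.0 + imb
    t_weights = np.array([pair_weights[t] for t in tumor_eligible])
    t_counts = _allocate(n_tumors, t_weights)
    if (t_counts < 1).any():
        raise ValueError("fewer than 1 tumor per eligible type")
    tumor_types = [
        t for t, c in zip(tumor_eligible, t_counts) for _ in range(int(c))
    ]
    cl_types = [cl_eligible[i % len(cl_eligible)] for i in range(n_cell_lines)]

    a, b = purity_shape
    purity = rng_tumor.beta(a, b, n_tumors)
    weights = rng_tumor.dirichlet(np.ones(r_contamination), n_tumors)  # tumors x r

    # A type-neutral tumor-specific expression program (e.g. variable
    # proliferation/stress activity in vivo): tumor-enriched variance that is
    # not type-informative, orthogonal to both the contamination axes and
    # every type axis.
    program_axis = rng.normal(0.0, 1.0, n_genes)
    span = np.column_stack(
        [QL] + [centroids[t] - base for t in type_names]
    )
    Qs, _ = np.linalg.qr(span)
    program_axis -= Qs @ (Qs.T @ program_axis)
    program_axis /= np.linalg.norm(program_axis)
    program_activity = rng_tumor.normal(0.0, 1.0, n_tumors)

    tumor_vals = np.empty((n_tumors, n_genes))
    for i, t in enumerate(tumor_types):
        profile = centroids[t] + rng_tumor.normal(0.0, noise_sd, n_genes)
        contamination = contamination_scale * (L @ weights[i])
        tumor_vals[i] = (
            purity[i] * profile
            + (1.0 - purity[i])
            * (contamination + rng_tumor.normal(0.0, contamination_noise_sd, n_genes))
            + program_scale * program_activity[i] * program_axis
            + dataset_offset
            + type_offsets[t]
            + rng_tumor.normal(0.0, noise_sd, n_genes)
        )

    # Cell lines drift along their own lineage axis (clonal selection /
    # variable differentiation in vitro), so within-type variance along type
    # axes exists in BOTH datasets and is not a tumor-enriched signal.
    differentiation = 1.0 + cl_heterogeneity * rng_cl.normal(0.0, 1.0, n_cell_lines)
    # Cell lines also vary along type-neutral global axes (overall expression
    # level, proliferation/stress programs); this in-vitro variance is real
    # but not tumor-enriched, so the contrast still isolates contamination.
    cl_axes = np.column_stack([QL, program_axis])
    cl_axis_activity = rng_cl.normal(0.0, cl_axis_sd, (n_cell_lines, cl_axes.shape[1]))
    cl_vals = np.empty((n_cell_lines, n_genes))
    for i, t in enumerate(cl_types):
        deviation = centroids[t] - base + rng_cl.normal(0.0, noise_sd, n_genes)
        cl_vals[i] = (
            base
            + differentiation[i] * deviation
            + cl_axes @ cl_axis_activity[i]
            + rng_cl.normal(0.0, noise_sd, n_genes)
        )

    n_clip = int((tumor_vals < 0).sum() + (cl_vals < 0).sum())
    clip_fraction = n_clip / (tumor_vals.size + cl_vals.size)
    if clip_fraction > 0.01:
        logger.warning("clip fraction %.3f exceeds 1%%", clip_fraction)
    np.clip(tumor_vals, 0.0, None, out=tumor_vals)
    np.clip(cl_vals, 0.0, None, out=cl_vals)

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    tumor_ids = [f"tumor_{i:04d}" for i in range(n_tumors)]
    cl_ids = [f"cl_{i:04d}" for i in range(n_cell_lines)]

    tumors = ExpressionMatrix(tumor_vals, tumor_ids, gene_ids, "tumor")
    cell_lines = ExpressionMatrix(cl_vals, cl_ids, gene_ids, "cell_line")
    truth = SyntheticTruth(
        tumor_types=tumor_types,
        cell_line_types=cl_types,
        purity=purity,
        contamination_loadings=L,
        dataset_offset=dataset_offset,
        type_offsets=type_offsets,
        exclusive_types=(tumor_only, cl_only),
        seed=seed,
        clip_fraction=clip_fraction,
        type_names=type_names,
        _tumor_ids=tumor_ids,
        _cl_ids=cl_ids,
    )
    return tumors, cell_lines, truth


def subspace_mean_abs_cosine(planted: np.ndarray, loadings: np.ndarray) -> float:
    """Mean |cos| between each loading column and the planted subspace."""
    Q, _ = np.linalg.qr(np.asarray(planted, dtype=float))
    V = np.asarray(loadings, dtype=float)
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    return float(np.mean(np.linalg.norm(Q.T @ V, axis=0)))


def neighbor_tumor_fraction(
    combined: np.ndarray,
    dataset_tags: list[str],
    member_mask: np.ndarray,
    k: int = 25,
) -> np.ndarray:
    """For each flagged sample, the tumor fraction among its k most
    correlated other samples in the combined matrix."""
    combined = np.asarray(combined, dtype=float)
    is_tumor = np.asarray([t == "tumor" for t in dataset_tags])
    members = np.nonzero(np.asarray(member_mask))[0]
    corr = pairwise_correlation(combined[members], combined)
    fractions = np.empty(len(members))
    for row, i in enumerate(members):
        c = corr[row].copy()
        c[i] = -np.inf  # exclude self
        top = np.argsort(-c, kind="stable")[:k]
        fractions[row] = is_tumor[top].mean()
    return fractions


def evaluate_recovery(
    truth: SyntheticTruth,
    report: SimilarityReport,
    comps: ContrastiveComponents,
    pre_report: SimilarityReport | None = None,
    combined_values: np.ndarray | None = None,
    combined_datasets: list[str] | None = None,
    k_neighbors: int = 25,
) -> dict:
    """Ground-truth recovery metrics for a pipeline run on generated data."""
    universe = set(truth.tumor_types)
    evaluable = [t in universe for t in truth.cell_line_types]
    n_eval = sum(evaluable)
    acc_post = (
        sum(
            p == a
            for p, a, ok in zip(report.predicted_type, truth.cell_line_types, evaluable)
            if ok
        )
        / n_eval
    )
    metrics: dict = {
        "accuracy_post": acc_post,
        "n_evaluated": n_eval,
        "contamination_cosine": subspace_mean_abs_cosine(
            truth.contamination_loadings,
            comps.loadings[:, : truth.contamination_loadings.shape[1]],
        ),
        "clip_fraction": truth.clip_fraction,
    }
    if pre_report is not None:
        metrics["accuracy_pre"] = (
            sum(
                p == a
                for p, a, ok in zip(
                    pre_report.predicted_type, truth.cell_line_types, evaluable
                )
                if ok
            )
            / n_eval
        )
    if combined_values is not None and combined_datasets is not None:
        tumor_only = next(iter(truth.exclusive_types[0]))
        combined_types = truth.cell_line_types + truth.tumor_types
        mask = np.asarray(
            [
                d == "tumor" and t == tumor_only
                for d, t in zip(combined_datasets, combined_types)
            ]
        )
        fracs = neighbor_tumor_fraction(
            combined_values, combined_datasets, mask, k_neighbors
        )
        metrics["exclusive_tumor_neighbor_fraction_min"] = float(fracs.min())
        metrics["exclusive_tumor_neighbor_fraction_mean"] = float(fracs.mean())
    return metrics
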