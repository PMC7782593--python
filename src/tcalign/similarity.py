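"""Tumor/cell-line similarity in the aligned space: pairwise Pearson
correlations, k-NN tumor-type classification and agreement/composition
summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SimilarityReport:
    cell_line_ids: list[str]
    tumor_ids: list[str]
    correlations: np.ndarray  # cell_lines x tumors
    predicted_type: list[str]
    neighbor_ids: list[list[str]]  # per cell line, decreasing correlation
    agreement: float
    n_evaluated: int


def pairwise_correlation(
    cell_lines: np.ndarray,
    tumors: np.ndarray,
    cell_line_ids: list[str] | None = None,
    tumor_ids: list[str] | None = None,
) -> np.ndarray:
    """Pearson correlation between every cell line's and tumor's gene vector."""
    C = np.asarray(cell_lines, dtype=float)
    T = np.asarray(tumors, dtype=float)
    if C.shape[1] != T.shape[1]:
        raise ValueError("matrices must share the gene space")
    for X, ids, what in ((C, cell_line_ids, "cell line"), (T, tumor_ids, "tumor")):
        sd = X.std(axis=1)
        if (sd == 0).any():
            i = int(np.argmax(sd == 0))
            name = ids[i] if ids is not None else str(i)
            raise ValueError(f"zero-variance {what} sample: {name}")
    Cz = (C - C.mean(axis=1, keepdims=True)) / C.std(axis=1, keepdims=True)
    Tz = (T - T.mean(axis=1, keepdims=True)) / T.std(axis=1, keepdims=True)
    corr = Cz @ Tz.T / C.shape[1]
    return np.clip(corr, -1.0, 1.0)


def classify_cell_lines(
    correlations: np.ndarray,
    tumor_types: list[str],
    tumor_ids: list[str],
    k: int,
) -> tuple[list[str], list[list[str]]]:
    """Modal tumor type among each cell line's k highest-correlated tumors.

    Ties are broken by the larger summed correlation over the tied types,
    then lexicographically.
    """
    corr = np.asarray(correlations, dtype=float)
    n_t = corr.shape[1]
    if k > n_t:
        raise ValueError(f"k={k} exceeds number of tumors {n_t}")
    if len(tumor_types) != n_t or len(tumor_ids) != n_t:
        raise ValueError("tumor annotations do not match correlation columns")
    types = np.asarray(tumor_types, dtype=object)
    predicted: list[str] = []
    neighbors: list[list[str]] = []
    for row in corr:
        order = np.lexsort((np.asarray(tumor_ids, dtype=object), -row))[:k]
        neighbors.append([tumor_ids[j] for j in order])
        votes: dict[str, int] = {}
        sums: dict[str, float] = {}
        for j in order:
            t = str(types[j])
            votes[t] = votes.get(t, 0) + 1
            sums[t] = sums.get(t, 0.0) + row[j]
        best = sorted(votes, key=lambda t: (-votes[t], -sums[t], t))[0]
        predicted.append(best)
    return predicted, neighbors


def agreement_score(
    predicted: list[str],
    annotated: list[str],
    tumor_type_universe: set[str],
) -> tuple[float, int]:
    """Fraction of matches among cell lines whose annotated type occurs in
    the tumor dataset."""
    if len(predicted) != len(annotated):
        raise ValueError("predicted and annotated lengths differ")
    pairs = [
        (p, a) for p, a in zip(predicted, annotated) if a in tumor_type_universe
    ]
    if not pairs:
        raise ValueError("no cell line has an annotated type present among tumors")
    matches = sum(p == a for p, a in pairs)
    return matches / len(pairs), len(pairs)


def build_similarity_report(
    cell_lines: np.ndarray,
    tumors: np.ndarray,
    cell_line_ids: list[str],
    tumor_ids: list[str],
    tumor_types: list[str],
    cl_types: list[str],
    k: int,
) -> SimilarityReport:
    corr = pairwise_correlation(cell_lines, tumors, cell_line_ids, tumor_ids)
    predicted, neighbors = classify_cell_lines(corr, tumor_types, tumor_ids, k)
    universe = {t for t in tumor_types if t != "unknown"}
    try:
        agreement, n_eval = agreement_score(predicted, cl_types, universe)
    except ValueError:
        agreement, n_eval = float("nan"), 0
    return SimilarityReport(
        cell_line_ids=list(cell_line_ids),
        tumor_ids=list(tumor_ids),
        correlations=corr,
        predicted_type=predicted,
        neighbor_ids=neighbors,
        agreement=agreement,
        n_evaluated=n_eval,
    )


def cluster_composition(
    labels: np.ndarray,
    dataset_tags: list[str],
    lineages: list[str],
    cl_fraction_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-cluster counts by dataset with lineage breakdown.

    Clusters whose cell-line fraction exceeds ``cl_fraction_threshold`` are
    flagged as candidate dataset-skewed clusters.
    """
    df = pd.DataFrame(
        {
            "cluster": np.asarray(labels),
            "dataset": list(dataset_tags),
            "lineage": [l if l else "unknown" for l in lineages],
        }
    )
    rows = []
    for cluster, grp in df.groupby("cluster", sort=True):
        n_cl = int((grp["dataset"] == "cell_line").sum())
        n_t = int((grp["dataset"] == "tumor").sum())
        frac = n_cl / (n_cl + n_t)
        breakdown = grp["lineage"].value_counts().to_dict()
        rows.append(
            {
                "cluster": cluster,
                "n_cell_lines": n_cl,
                "n_tumors": n_t,
                "cell_line_fraction": frac,
                "flagged": frac > cl_fraction_threshold,
                "lineage_breakdown": breakdown,
            }
        )
    return pd.DataFrame(rows)
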