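"""Mutual-nearest-neighbor pairing between cell lines (reference) and tumors
(query) with asymmetric neighbor counts, and Gaussian-kernel-smoothed
correction of the tumor matrix.

Neighbor search runs in a gene-subset Euclidean space; correction vectors are
differences over ALL genes so the full matrix is aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class MNNPairing:
    """Mutual neighbor pairs: (c, t) is a pair iff c is among t's k_cl nearest
    cell lines and t is among c's k_t nearest tumors."""

    cell_line_idx: np.ndarray
    tumor_idx: np.ndarray
    distances: np.ndarray
    cell_line_ids: list[str]
    tumor_ids: list[str]
    k_cell_line: int
    k_tumor: int
    gene_subset: list[str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.cell_line_idx)

    def as_tuples(self) -> set[tuple[str, str]]:
        return {
            (self.cell_line_ids[c], self.tumor_ids[t])
            for c, t in zip(self.cell_line_idx, self.tumor_idx)
        }


@dataclass
class CorrectionField:
    tumor_ids: list[str]
    vectors: np.ndarray  # tumors x genes
    sigma_sq: float


def _subset_columns(gene_ids: list[str], gene_subset: list[str]) -> np.ndarray:
    if len(gene_subset) == 0:
        raise ValueError("empty gene subset")
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in gene_subset if g not in pos]
    if missing:
        raise KeyError(f"gene subset not within shared genes: {missing[:5]}")
    return np.array([pos[g] for g in gene_subset])


def find_mutual_nn(
    cell_lines: np.ndarray,
    tumors: np.ndarray,
    cell_line_ids: list[str],
    tumor_ids: list[str],
    gene_ids: list[str],
    gene_subset: list[str],
    k_cl: int,
    k_t: int,
) -> MNNPairing:
    """Exact mutual nearest neighbors in the gene-subset Euclidean space."""
    cols = _subset_columns(gene_ids, gene_subset)
    C = np.asarray(cell_lines, dtype=float)[:, cols]
    T = np.asarray(tumors, dtype=float)[:, cols]
    n_cl, n_t = C.shape[0], T.shape[0]
    if not (0 < k_cl < n_cl):
        raise ValueError(f"k_cl={k_cl} must be in (0, n_cell_lines={n_cl})")
    if not (0 < k_t < n_t):
        raise ValueError(f"k_t={k_t} must be in (0, n_tumors={n_t})")

    dist = cdist(C, T, metric="euclidean")  # n_cl x n_t, exact
    # k_cl nearest cell lines of each tumor / k_t nearest tumors of each line
    near_cl = np.argpartition(dist, k_cl - 1, axis=0)[:k_cl, :]  # k_cl x n_t
    near_t = np.argpartition(dist, k_t - 1, axis=1)[:, :k_t]  # n_cl x k_t

    cl_of_tumor = np.zeros((n_cl, n_t), dtype=bool)
    cl_of_tumor[near_cl, np.arange(n_t)[None, :]] = True
    t_of_cl = np.zeros((n_cl, n_t), dtype=bool)
    t_of_cl[np.arange(n_cl)[:, None], near_t] = True

    c_idx, t_idx = np.nonzero(cl_of_tumor & t_of_cl)
    return MNNPairing(
        cell_line_idx=c_idx,
        tumor_idx=t_idx,
        distances=dist[c_idx, t_idx],
        cell_line_ids=list(cell_line_ids),
        tumor_ids=list(tumor_ids),
        k_cell_line=k_cl,
        k_tumor=k_t,
        gene_subset=list(gene_subset),
    )


def compute_correction(
    pairing: MNNPairing,
    cell_lines: np.ndarray,
    tumors: np.ndarray,
    gene_ids: list[str],
    sigma_multiplier: float = 3.0,
) -> CorrectionField:
    """Per-tumor correction vectors.

    Each pair contributes d_p = cellline - tumor over all genes; tumor t's
    correction is the Gaussian-kernel weighted average of the d_p with
    weights exp(-||u_t - u_{tumor(p)}||^2 / sigma^2) in the gene-subset
    space, sigma^2 = sigma_multiplier * median squared tumor-to-pair-tumor
    distance. Every tumor, paired or not, receives a correction.
    """
    if pairing.n_pairs == 0:
        raise ValueError("pairing is empty")
    C = np.asarray(cell_lines, dtype=float)
    T = np.asarray(tumors, dtype=float)
    cols = _subset_columns(gene_ids, pairing.gene_subset)

    d = C[pairing.cell_line_idx] - T[pairing.tumor_idx]  # pairs x genes
    U = T[:, cols]
    Up = U[pairing.tumor_idx]  # pairs x subset
    d2 = cdist(U, Up, metric="sqeuclidean")  # tumors x pairs
    sigma_sq = float(sigma_multiplier * np.median(d2))
    if sigma_sq <= 0:
        # All pair tumors coincide with every tumor (degenerate fixture).
        weights = np.full(d2.shape, 1.0 / d2.shape[1])
    else:
        weights = np.exp(-d2 / sigma_sq)
        totals = weights.sum(axis=1, keepdims=True)
        dead = totals[:, 0] <= 0
        if dead.any():
            logger.warning(
                "%d tumor(s) with zero kernel mass; using unweighted mean",
                int(dead.sum()),
            )
            weights[dead] = 1.0
            totals = weights.sum(axis=1, keepdims=True)
        weights = weights / totals
    vectors = weights @ d
    return CorrectionField(list(pairing.tumor_ids), vectors, sigma_sq)


def apply_correction(tumors: np.ndarray, fieldv: CorrectionField) -> np.ndarray:
    """Move tumors toward the cell-line reference: tumors + vectors."""
    T = np.asarray(tumors, dtype=float)
    if T.shape != fieldv.vectors.shape:
        raise ValueError(
            f"shape mismatch: tumors {T.shape} vs correction {fieldv.vectors.shape}"
        )
    return T + fieldv.vectors
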