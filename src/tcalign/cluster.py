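"""Per-dataset clustering: PCA reduction, SNN graph, community detection and
cluster-mean residualization."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class PCAModel:
    """Gene-mean-centered PCA with a fixed sign convention.

    Each loading column has its largest-magnitude entry positive so results
    are reproducible across solvers.
    """

    loadings: np.ndarray  # genes x n_pcs, orthonormal columns
    scores: np.ndarray  # samples x n_pcs
    gene_means: np.ndarray
    explained_variance: np.ndarray


@dataclass
class ClusterAssignment:
    sample_ids: list[str]
    labels: np.ndarray  # contiguous ints from 0
    dataset: str
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def _fix_signs(loadings: np.ndarray, scores: np.ndarray | None = None):
    """Make the largest-|entry| of each loading column positive."""
    idx = np.abs(loadings).argmax(axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    loadings = loadings * signs
    if scores is not None:
        scores = scores * signs
    return loadings, scores


def pca_reduce(values: np.ndarray, n_pcs: int) -> PCAModel:
    """PCA on gene-mean-centered data (no variance scaling)."""
    X = np.asarray(values, dtype=float)
    n, g = X.shape
    if n_pcs > min(n - 1, g) and n > 1:
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_samples-1, n_genes)={min(n - 1, g)}")
    gene_means = X.mean(axis=0)
    Xc = X - gene_means
    if not np.any(Xc):
        # Zero centered variance (e.g. identical samples): scores are exactly 0.
        warnings.warn("matrix has zero variance after centering; PCA scores are all 0")
        loadings = np.eye(g, n_pcs)
        return PCAModel(
            loadings=loadings,
            scores=np.zeros((n, n_pcs)),
            gene_means=gene_means,
            explained_variance=np.zeros(n_pcs),
        )
    pca = PCA(n_components=n_pcs, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(Xc)
    loadings = pca.components_.T
    loadings, scores = _fix_signs(loadings, scores)
    return PCAModel(
        loadings=loadings,
        scores=scores,
        gene_means=gene_means,
        explained_variance=pca.explained_variance_.copy(),
    )


def build_snn_graph(scores: np.ndarray, k: int, prune: float = 1.0 / 15.0) -> ig.Graph:
    """Shared-nearest-neighbor graph.

    Edge weight between samples i and j is the Jaccard overlap of their
    k-nearest-neighbor sets (Euclidean, self included); weights below
    ``prune`` are dropped. All pairs with nonzero overlap are considered.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be < n_samples={n}")
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)  # self is included (distance 0)
    indptr = np.arange(0, n * k + 1, k)
    adj = sp.csr_matrix(
        (np.ones(n * k), idx.ravel(), indptr), shape=(n, n)
    )
    inter = (adj @ adj.T).tocoo()
    mask = inter.row < inter.col
    rows, cols, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jacc = shared / (2 * k - shared)
    keep = jacc >= prune
    edges = list(zip(rows[keep].tolist(), cols[keep].tolist()))
    graph = ig.Graph(n=n, edges=edges)
    graph.es["weight"] = jacc[keep].tolist()
    return graph


def cluster_graph(graph: ig.Graph, resolution: float, rng_seed: int) -> np.ndarray:
    """Leiden community detection on the SNN graph (RB modularity).

    Returns contiguous integer labels (relabelled by first occurrence so the
    output is a pure function of graph + seed).
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    if graph.ecount() == 0:
        logger.warning("graph has no edges; every node becomes its own cluster")
        return np.arange(graph.vcount())
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=rng_seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    return _contiguous(raw)


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..k-1 in order of first appearance."""
    order: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def cluster_samples(
    values: np.ndarray,
    sample_ids: list[str],
    dataset: str,
    n_pcs: int,
    snn_k: int,
    resolution: float,
    rng_seed: int,
    prune: float = 1.0 / 15.0,
) -> ClusterAssignment:
    """PCA -> SNN graph -> Leiden, with parameters clamped to the data size."""
    n = values.shape[0]
    n_pcs_eff = min(n_pcs, n - 1, values.shape[1])
    if n_pcs_eff < n_pcs:
        logger.info("clamping n_pcs from %d to %d for %s", n_pcs, n_pcs_eff, dataset)
    k_eff = min(snn_k, n - 1)
    model = pca_reduce(values, n_pcs_eff)
    graph = build_snn_graph(model.scores, k_eff, prune=prune)
    # High resolutions shatter small datasets into singletons, which leaves no
    # within-cluster degrees of freedom downstream. Walk a deterministic
    # resolution ladder and keep the finest usable partition (2 <= k <= n/2,
    # residual df >= 2); this only ever triggers far below the sample scale
    # the default resolution is meant for.
    labels = None
    res = resolution
    fallback = None
    for _ in range(16):
        candidate = cluster_graph(graph, res, rng_seed)
        k = int(candidate.max()) + 1
        if 2 <= k <= max(2, n // 2) and n - k >= 2:
            labels = candidate
            break
        if k >= 2 and n - k >= 1:
            fallback = (candidate, res)
        if k < 2:
            break  # coarser resolutions cannot recover multiple clusters
        res /= 2.0
        logger.warning(
            "partition of %s (%d samples) too fine; retrying at resolution %g",
            dataset, n, res,
        )
    if labels is None:
        if fallback is None:
            raise ValueError(
                f"could not find a usable partition for {dataset} ({n} samples)"
            )
        labels, res = fallback
        logger.warning("using fallback partition at resolution %g", res)
    return ClusterAssignment(list(sample_ids), labels, dataset, res)


def subtract_cluster_means(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Subtract each cluster's mean profile from its samples."""
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != X.shape[0]:
        raise ValueError("labels do not cover all samples")
    out = np.empty_like(X)
    for lab in np.unique(labels):
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"cluster {lab} has no samples")
        out[mask] = X[mask] - X[mask].mean(axis=0)
    return out
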