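"""2D visualization of the aligned combined dataset (PCA then UMAP)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import pca_reduce
from .config import PipelineConfig


@dataclass
class Embedding2D:
    sample_ids: list[str]
    coords: np.ndarray  # samples x 2
    n_pcs: int
    n_neighbors: int
    min_dist: float
    seed: int


def umap_embed(
    values: np.ndarray, sample_ids: list[str], config: PipelineConfig
) -> Embedding2D:
    """UMAP on the top principal components (Euclidean, deterministic seed)."""
    import umap  # deferred: numba compilation is slow at import time

    X = np.asarray(values, dtype=float)
    n = X.shape[0]
    if n < config.umap_n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={config.umap_n_neighbors + 1} samples, got {n}"
        )
    n_pcs = min(config.n_pcs, n - 1, X.shape[1])
    scores = pca_reduce(X, n_pcs).scores
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=config.umap_n_neighbors,
        min_dist=config.umap_min_dist,
        metric="euclidean",
        random_state=config.rng_seed,
    )
    coords = np.asarray(reducer.fit_transform(scores), dtype=float)
    if not np.all(np.isfinite(coords)):
        raise FloatingPointError("UMAP produced non-finite coordinates")
    return Embedding2D(
        sample_ids=list(sample_ids),
        coords=coords,
        n_pcs=n_pcs,
        n_neighbors=config.umap_n_neighbors,
        min_dist=config.umap_min_dist,
        seed=config.rng_seed,
    )
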