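"""Pipeline configuration: every numeric method parameter in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the alignment pipeline.

    Defaults are the reference configuration of the method: 70 PCs for per-dataset
    clustering, SNN community detection at resolution 5, removal of the first
    4 contrastive components, union of the top 1000 cluster-variable genes per
    dataset, asymmetric mutual-nearest-neighbor counts (5 cell-line / 50
    tumor), classification over the 25 highest-correlated tumor neighbors and
    a UMAP embedding with n_neighbors=10, min_dist=0.5.
    """

    n_pcs: int = 70
    snn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    snn_resolution: float = 5.0
    n_cpcs_removed: int = 4
    cpca_alpha: float = 1.0
    n_top_genes_per_dataset: int = 1000
    k_cell_line: int = 5
    k_tumor: int = 50
    mnn_sigma_multiplier: float = 3.0
    k_classify: int = 25
    umap_n_neighbors: int = 10
    umap_min_dist: float = 0.5
    rng_seed: int = 0
    # Gene variability can be scored on raw log-TPM (default) or on the
    # contrastive-PCA residualized matrices.
    f_stats_input: str = "raw"

    def __post_init__(self) -> None:
        positive = (
            "n_pcs",
            "snn_k",
            "snn_resolution",
            "n_top_genes_per_dataset",
            "k_cell_line",
            "k_tumor",
            "mnn_sigma_multiplier",
            "k_classify",
            "umap_n_neighbors",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")
        if self.n_cpcs_removed < 0:
            raise ValueError("n_cpcs_removed must be >= 0")
        if self.umap_min_dist < 0:
            raise ValueError("umap_min_dist must be >= 0")
        if self.f_stats_input not in ("raw", "residual"):
            raise ValueError("f_stats_input must be 'raw' or 'residual'")

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})
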