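"""Loading, validation and gene harmonization of expression matrices.

Matrices are samples x genes, values in log2(TPM+1) units. Text files may be
written with samples as rows or as columns; orientation is recovered from the
index label when present and from shape otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DATASET_TAGS = ("tumor", "cell_line")

_SAMPLE_AXIS_NAMES = {"sample", "sample_id", "samples", "sample_ids"}
_GENE_AXIS_NAMES = {"gene", "gene_id", "genes", "gene_ids"}


class ValidationError(ValueError):
    """Raised when an input matrix violates the expression-matrix contract."""


@dataclass
class ExpressionMatrix:
    """A dense samples x genes matrix of log2(TPM+1) values."""

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    dataset: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        validate_expression_matrix(self)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        df.index.name = "sample_id"
        df.columns.name = "gene_id"
        return df

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not present: {missing[:5]}")
        idx = [pos[g] for g in genes]
        return ExpressionMatrix(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            gene_ids=list(genes),
            dataset=self.dataset,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dataset: str) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
            dataset=dataset,
        )


def validate_expression_matrix(em: ExpressionMatrix) -> None:
    if em.dataset not in DATASET_TAGS:
        raise ValidationError(
            f"dataset tag must be one of {DATASET_TAGS}, got {em.dataset!r}"
        )
    if em.values.ndim != 2:
        raise ValidationError("expression values must be a 2D matrix")
    n_s, n_g = em.values.shape
    if n_s == 0 or n_g == 0:
        raise ValidationError("empty expression matrix")
    if len(em.sample_ids) != n_s or len(em.gene_ids) != n_g:
        raise ValidationError("id lengths do not match matrix shape")
    if len(set(em.sample_ids)) != n_s:
        dup = _first_duplicate(em.sample_ids)
        raise ValidationError(f"duplicate sample id: {dup!r}")
    if len(set(em.gene_ids)) != n_g:
        dup = _first_duplicate(em.gene_ids)
        raise ValidationError(f"duplicate gene id: {dup!r}")
    bad = ~np.isfinite(em.values)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [
            f"({em.sample_ids[r]}, {em.gene_ids[c]})"
            for r, c in list(zip(rows, cols))[:5]
        ]
        raise ValidationError(
            f"{bad.sum()} non-finite value(s), first at {', '.join(cells)}"
        )
    if (em.values < 0).any():
        rows, cols = np.nonzero(em.values < 0)
        raise ValidationError(
            "negative value(s) found (log2(TPM+1) must be >= 0), first at "
            f"({em.sample_ids[rows[0]]}, {em.gene_ids[cols[0]]})"
        )


def _first_duplicate(ids: list[str]) -> str:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return ""


def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_expression_matrix(
    path: str | Path, dataset_tag: str, orient: str = "auto"
) -> ExpressionMatrix:
    """Load a delimited-text or HDF5 expression matrix.

    ``orient`` is one of ``"auto"``, ``"samples"`` (rows are samples) or
    ``"genes"`` (rows are genes). In auto mode the index label decides
    (``sample_id`` vs ``gene_id``); failing that, the longer axis is taken to
    be genes.
    """
    path = Path(path)
    if orient not in ("auto", "samples", "genes"):
        raise ValueError(f"invalid orient {orient!r}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _load_hdf5(path, dataset_tag)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty expression matrix in {path}")
    non_numeric = df.columns[df.dtypes == object]
    for col in non_numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric entry {df.loc[row, col]!r} at row {row!r}, "
                f"column {col!r} in {path}"
            )
        df[col] = coerced
    rows_are_genes = _rows_are_genes(df, orient)
    if rows_are_genes:
        df = df.T
    df.index.name = "sample_id"
    df.columns.name = "gene_id"
    return ExpressionMatrix.from_frame(df, dataset_tag)


def _rows_are_genes(df: pd.DataFrame, orient: str) -> bool:
    if orient == "samples":
        return False
    if orient == "genes":
        return True
    idx_name = (df.index.name or "").strip().lower()
    col_name = (df.columns.name or "").strip().lower()
    if idx_name in _GENE_AXIS_NAMES or col_name in _SAMPLE_AXIS_NAMES:
        return True
    if idx_name in _SAMPLE_AXIS_NAMES or col_name in _GENE_AXIS_NAMES:
        return False
    # Heuristic of last resort: gene axes are (much) longer than sample axes.
    return df.shape[0] > df.shape[1]


def write_expression_matrix(
    em: ExpressionMatrix, path: str | Path, orient: str = "samples"
) -> None:
    """Write as TSV/CSV (index label marks the orientation) or HDF5."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_hdf5(em, path)
        return
    df = em.to_frame()
    if orient == "genes":
        df = df.T
    elif orient != "samples":
        raise ValueError(f"invalid orient {orient!r}")
    df.to_csv(path, sep=_sniff_sep(path))


def _load_hdf5(path: Path, dataset_tag: str) -> ExpressionMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        values = np.asarray(f["values"], dtype=float)
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][:]]
        gene_ids = [g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][:]]
    return ExpressionMatrix(values, sample_ids, gene_ids, dataset_tag)


def _write_hdf5(em: ExpressionMatrix, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=em.values)
        f.create_dataset("sample_ids", data=np.array(em.sample_ids, dtype="S"))
        f.create_dataset("gene_ids", data=np.array(em.gene_ids, dtype="S"))
        f.attrs["dataset"] = em.dataset


def harmonize_genes(
    tumor: ExpressionMatrix, cell_lines: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to the shared genes, in the tumor gene order."""
    cl_genes = set(cell_lines.gene_ids)
    shared = [g for g in tumor.gene_ids if g in cl_genes]
    if not shared:
        raise ValidationError("no shared genes between tumor and cell line matrices")
    if len(shared) < 2:
        raise ValidationError("fewer than 2 shared genes")
    return tumor.subset_genes(shared), cell_lines.subset_genes(shared)


@dataclass
class SampleAnnotation:
    """Per-sample lineage/subtype annotations for one dataset."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    dataset: str = "tumor"

    def __post_init__(self) -> None:
        if self.table.empty:
            self.table = pd.DataFrame(columns=["sample_id", "lineage", "subtype"])
        for col in ("lineage", "subtype"):
            if col not in self.table.columns:
                self.table[col] = "unknown"
        self.table = self.table[["sample_id", "lineage", "subtype"]].copy()
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        self.table["lineage"] = self.table["lineage"].fillna("unknown").astype(str)
        self.table["subtype"] = self.table["subtype"].fillna("unknown").astype(str)
        if self.table["sample_id"].duplicated().any():
            dup = self.table["sample_id"][self.table["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate annotation for sample {dup!r}")


def load_annotations(path: str | Path, dataset_tag: str) -> SampleAnnotation:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if "sample_id" not in df.columns:
        raise ValidationError(f"annotation file {path} lacks a sample_id column")
    return SampleAnnotation(df, dataset_tag)


def lineages_for(
    em: ExpressionMatrix, annot: SampleAnnotation | None
) -> pd.Series:
    """Per-sample lineage, aligned to ``em.sample_ids``.

    Expression samples without an annotation get lineage ``"unknown"``;
    annotations without expression are dropped with a warning.
    """
    if annot is None:
        return pd.Series("unknown", index=em.sample_ids, name="lineage")
    mapping = annot.table.set_index("sample_id")["lineage"]
    extra = mapping.index.difference(em.sample_ids)
    if len(extra):
        logger.warning(
            "%d annotation row(s) without expression dropped (e.g. %s)",
            len(extra),
            extra[0],
        )
    out = mapping.reindex(em.sample_ids).fillna("unknown")
    out.name = "lineage"
    return out
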