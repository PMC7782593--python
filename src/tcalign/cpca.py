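"""Contrastive PCA: eigenvectors of the difference between the two datasets'
intra-cluster covariances, and residualization against the top components."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg as spla

_DENSE_GENE_LIMIT = 3000


class CovarianceOperator:
    """Implicit covariance C = R^T R / (n - 1) held in factored form."""

    def __init__(self, residuals: np.ndarray):
        R = np.asarray(residuals, dtype=float)
        if R.ndim != 2:
            raise ValueError("residuals must be 2D")
        if R.shape[0] <= 1:
            raise ValueError("need more than one sample to form a covariance")
        self._R = R
        self.n_samples, self.n_genes = R.shape

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self._R.T @ (self._R @ v) / (self.n_samples - 1)

    def matmat(self, V: np.ndarray) -> np.ndarray:
        return self._R.T @ (self._R @ V) / (self.n_samples - 1)

    def dense(self) -> np.ndarray:
        return self._R.T @ self._R / (self.n_samples - 1)


def intra_cluster_covariance(residuals: np.ndarray) -> CovarianceOperator:
    """Covariance of cluster-mean-subtracted residuals (uncentered, /(n-1))."""
    return CovarianceOperator(residuals)


@dataclass
class ContrastiveComponents:
    """Top eigenvectors of C_tumor - alpha * C_cell_line (tumor-enriched axes)."""

    loadings: np.ndarray  # genes x n_components, orthonormal
    eigenvalues: np.ndarray  # nonincreasing
    contrast_alpha: float = 1.0


def contrastive_components(
    c_tumor: CovarianceOperator,
    c_cell_line: CovarianceOperator,
    n_components: int,
    alpha: float = 1.0,
) -> ContrastiveComponents:
    """Largest-algebraic eigenpairs of the covariance contrast.

    A dense symmetric solve is used for small gene spaces; otherwise a
    Lanczos solve on the implicit operator with a fixed starting vector
    (deterministic output).
    """
    if c_tumor.n_genes != c_cell_line.n_genes:
        raise ValueError("operators act on different gene spaces")
    g = c_tumor.n_genes
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > g:
        raise ValueError("n_components exceeds number of genes")

    if g <= _DENSE_GENE_LIMIT or n_components > g - 2:
        D = c_tumor.dense() - alpha * c_cell_line.dense()
        evals, evecs = scipy.linalg.eigh(D)
        order = np.argsort(evals)[::-1][:n_components]
        vals, vecs = evals[order], evecs[:, order]
    else:
        op = spla.LinearOperator(
            (g, g),
            matvec=lambda v: c_tumor.matvec(v) - alpha * c_cell_line.matvec(v),
            matmat=lambda V: c_tumor.matmat(V) - alpha * c_cell_line.matmat(V),
            dtype=float,
        )
        v0 = np.full(g, 1.0 / np.sqrt(g))  # fixed start: deterministic
        try:
            vals, vecs = spla.eigsh(op, k=n_components, which="LA", v0=v0)
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                f"contrastive eigensolver failed to converge: {exc}"
            ) from exc
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    idx = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return ContrastiveComponents(vecs * signs, vals, alpha)


def regress_out_components(
    X: np.ndarray, comps: ContrastiveComponents, n_remove: int
) -> np.ndarray:
    """Residualize every gene on the sample scores of the first ``n_remove``
    components, keeping gene means.

    Scores are computed on gene-mean-centered data of the given matrix; the
    same loadings are meant to be applied to both datasets.
    """
    X = np.asarray(X, dtype=float)
    if n_remove > comps.loadings.shape[1]:
        raise ValueError("n_remove exceeds available components")
    if n_remove == 0:
        return X.copy()
    V = comps.loadings[:, :n_remove]
    means = X.mean(axis=0)
    Xc = X - means
    S = Xc @ V
    # Scores that are negligible relative to the data carry no signal; a
    # least-squares solve on them would amplify round-off (and break
    # idempotence), so they are dropped.
    keep = np.linalg.norm(S, axis=0) > 1e-9 * max(np.linalg.norm(Xc), 1.0)
    if not keep.any():
        return X.copy()
    S = S[:, keep]
    beta, *_ = np.linalg.lstsq(S, Xc, rcond=None)
    return Xc - S @ beta + means
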