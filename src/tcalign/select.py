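"""Gene ranking by between-cluster variability (empirical-Bayes moderated F)
and selection of the union gene set used for neighbor search.

The moderated F for gene g is MS_between,g / s~_g^2, where the residual
variance s_g^2 of a one-way cluster-means fit is shrunk toward a common value
s0^2 with prior degrees of freedom d0, both estimated by matching the first
two moments of log s_g^2 to a scaled-F distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, polygamma

logger = logging.getLogger(__name__)


@dataclass
class GeneVariabilityTable:
    gene_ids: list[str]
    f_stat: np.ndarray
    residual_df: float
    prior_df: float
    prior_var: float
    dataset: str


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_f_dist_moments(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) from residual variances by the moments of log s^2.

    Returns d0 = inf when the observed spread of log s^2 does not exceed the
    sampling variability implied by ``df`` (fully shrunk limit).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        logger.warning("too few positive residual variances; using d0 = inf")
        return np.inf, float(pos.mean()) if pos.size else 1.0
    z = np.log(pos)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_f_stats(
    values: np.ndarray,
    labels: np.ndarray,
    gene_ids: list[str],
    dataset: str,
) -> GeneVariabilityTable:
    """Moderated one-way F statistic per gene across the given clusters."""
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n, g = X.shape
    if len(labels) != n:
        raise ValueError("labels do not cover all samples")
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    df = n - k
    if df < 1:
        raise ValueError("residual degrees of freedom n - n_clusters must be >= 1")

    counts = np.bincount(inv).astype(float)  # k
    sums = np.zeros((k, g))
    np.add.at(sums, inv, X)
    means = sums / counts[:, None]  # k x g cluster means
    grand = X.mean(axis=0)

    ss_within = ((X - means[inv]) ** 2).sum(axis=0)
    s2 = ss_within / df
    ms_between = (counts[:, None] * (means - grand) ** 2).sum(axis=0) / (k - 1)

    d0, s0_sq = fit_f_dist_moments(s2, df)
    if np.isinf(d0):
        s2_mod = np.full(g, s0_sq)
    else:
        s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(s2_mod > 0, ms_between / s2_mod, 0.0)
    f = np.where(ms_between == 0, 0.0, f)  # constant genes get F = 0
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite moderated F statistic")
    return GeneVariabilityTable(
        gene_ids=list(gene_ids),
        f_stat=f,
        residual_df=float(df),
        prior_df=float(d0),
        prior_var=float(s0_sq),
        dataset=dataset,
    )


def top_genes(table: GeneVariabilityTable, n_top: int) -> list[str]:
    """Top-``n_top`` genes by F, ties broken by gene id (lexicographic)."""
    if n_top > len(table.gene_ids):
        raise ValueError("n_top exceeds number of genes")
    ids = np.asarray(table.gene_ids, dtype=object)
    order = np.lexsort((ids, -table.f_stat))
    return [str(x) for x in ids[order[:n_top]]]


def select_union_genes(
    tumor_table: GeneVariabilityTable,
    cl_table: GeneVariabilityTable,
    n_top: int,
) -> list[str]:
    """Union of each dataset's top-``n_top`` genes, sorted for determinism."""
    if set(tumor_table.gene_ids) != set(cl_table.gene_ids):
        raise ValueError("tables must share the same gene universe")
    union = set(top_genes(tumor_table, n_top)) | set(top_genes(cl_table, n_top))
    return sorted(union)
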