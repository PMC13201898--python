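"""Empirical distance covariance and normalized distance correlation.

For two univariate sample vectors X, Y of length n, form the pairwise
Euclidean distance matrices a_kl = |x_k - x_l| and b_kl = |y_k - y_l|,
double-center each (subtract row means, column means, add the grand mean),
and define

    V_n^2(X, Y) = (1/n^2) * sum_{k,l} A_kl B_kl
    R_n(X, Y)   = V_n^2(X, Y) / sqrt(V_n^2(X, X) * V_n^2(Y, Y))

R_n lies in [0, 1] and vanishes only under full statistical independence, so
it detects nonlinear co-expression that Pearson's r misses.  When either
marginal distance variance is zero (a constant profile) the ratio is
undefined and R_n is reported as 0: a constant vector carries no dependence
evidence.

Gene profiles are univariate here (one expression value per sample), so the
Euclidean norm reduces to the absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ExpressionMatrix


@dataclass(frozen=True)
class CenteredDistanceMatrix:
    """Double-centered pairwise distance matrix of one sample vector."""

    n: int
    values: np.ndarray


@dataclass(frozen=True)
class DcorResult:
    """Squared distance covariance and normalized distance correlation."""

    v2_xy: float
    rn: float


def double_center_distances(v: Sequence[float]) -> CenteredDistanceMatrix:
    """Double-center the pairwise absolute-difference matrix of ``v``.

    Entry (k, l) is a_kl - abar_k. - abar_.l + abar_.. where
    a_kl = |v_k - v_l|.  Row and column sums of the result are zero.
    """
    v = np.asarray(v, dtype=float).ravel()
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    a = np.abs(v[:, None] - v[None, :])
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    grand = a.mean()
    return CenteredDistanceMatrix(n=n, values=a - row - col + grand)


def distance_covariance(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared empirical distance covariance V_n^2(X, Y), clipped at 0.

    The population quantity is provably non-negative; tiny negative values
    from floating-point cancellation are clipped before any square root.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    A = double_center_distances(x).values
    B = double_center_distances(y).values
    v2 = float(np.mean(A * B))
    return max(v2, 0.0)


def distance_correlation(x: Sequence[float], y: Sequence[float]) -> DcorResult:
    """Normalized distance correlation R_n(X, Y) in [0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    A = double_center_distances(x).values
    B = double_center_distances(y).values
    v2_xy = max(float(np.mean(A * B)), 0.0)
    v2_xx = max(float(np.mean(A * A)), 0.0)
    v2_yy = max(float(np.mean(B * B)), 0.0)
    denom = v2_xx * v2_yy
    if denom <= 0.0:
        return DcorResult(v2_xy=v2_xy, rn=0.0)
    rn = v2_xy / np.sqrt(denom)
    return DcorResult(v2_xy=v2_xy, rn=float(min(max(rn, 0.0), 1.0)))


def dcor_matrix(
    expr: ExpressionMatrix,
    samples: Sequence[str] | None = None,
    block_size: int = 64,
) -> np.ndarray:
    """All-pairs gene distance-correlation matrix over a sample subset.

    Each gene's double-centered distance matrix is flattened once; the
    squared distance covariance of a gene pair is then the mean elementwise
    product of the two flattened matrices, so the full matrix reduces to a
    blocked Gram product.  Results are independent of ``block_size``, which
    only bounds the peak size of intermediate products.

    Returns a symmetric matrix with unit diagonal and entries in [0, 1].
    Constant genes must be removed beforehand (see
    :func:`novagene.data_model.filter_zero_variance`).
    """
    if samples is None:
        samples = expr.sample_ids
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    idx = expr.sample_index(samples)
    sub = expr.values[:, idx]
    n_genes, n = sub.shape
    if np.any(np.ptp(sub, axis=1) == 0):
        const = [g for g, c in zip(expr.gene_ids, np.ptp(sub, axis=1) == 0) if c]
        raise ValueError(
            f"constant genes in scope (run filter_zero_variance first): {const}"
        )

    flat = np.empty((n_genes, n * n), dtype=float)
    for i in range(n_genes):
        flat[i] = double_center_distances(sub[i]).values.ravel()

    v2 = np.empty((n_genes, n_genes), dtype=float)
    for start in range(0, n_genes, max(block_size, 1)):
        stop = min(start + max(block_size, 1), n_genes)
        v2[start:stop] = flat[start:stop] @ flat.T / (n * n)
    np.maximum(v2, 0.0, out=v2)

    diag = np.sqrt(np.diag(v2))
    rn = v2 / np.outer(diag, diag)
    rn = np.clip(rn, 0.0, 1.0)
    rn = (rn + rn.T) / 2.0
    np.fill_diagonal(rn, 1.0)
    return rn


def write_correlation_matrix(
    matrix: np.ndarray, gene_ids: Sequence[str], path
) -> None:
    """Export a gene x gene correlation matrix as TSV with gene-id header."""
    import pandas as pd

    pd.DataFrame(matrix, index=list(gene_ids), columns=list(gene_ids)).to_csv(
        path, sep="\t", index_label="gene_id"
    )
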