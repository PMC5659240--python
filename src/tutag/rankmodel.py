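"""Rank-based logistic model of layer membership and leading-fold-change MDS.

Genes are ranked by descending fold enrichment (rank 1 = strongest); a
binomial logistic regression of marker-set membership on rank,

    logit P(member | rank) = beta0 + beta1 * rank,

is fitted by iteratively reweighted least squares with Wald inference from
the inverse Fisher information. A negative slope means layer membership is
more likely among the most-enriched genes.

Sample-level structure is summarized by classical (Torgerson) MDS on
leading-fold-change distances: for each sample pair, the root mean square
of the ``top`` largest absolute log2 ratios of normalized,
pseudocount-stabilized counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DEResult, size_factors
from .io import CountMatrix

__all__ = [
    "LogisticFit",
    "RankedGenes",
    "rank_by_fold_enrichment",
    "fit_logistic",
    "predict_curve",
    "leading_fold_change_distances",
    "mds_leading_foldchange",
]


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit of membership on rank."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    z_intercept: float
    z_slope: float
    p_intercept: float
    p_slope: float
    converged: bool
    n_obs: int
    n_iter: int
    deviance: float


@dataclass
class RankedGenes:
    """Genes of the filtered universe ordered by fold enrichment.

    ``table`` columns: ``rank`` (1 = strongest enrichment),
    ``fold_enrichment``, ``is_member``; indexed by gene id in rank order.
    """

    table: pd.DataFrame
    member_set_size: int


def rank_by_fold_enrichment(
    de: DEResult,
    member_set: Iterable[str],
    enriched_only: bool = False,
) -> RankedGenes:
    """Rank genes by descending fold enrichment against a marker set.

    Ties are broken by ascending padj, then lexicographic gene id (stable).
    Genes with undefined fold enrichment (zero in both sample types) are
    excluded. ``enriched_only`` restricts the ranking to called-enriched
    genes instead of the full filtered universe.
    """
    tab = de.table
    if enriched_only:
        tab = tab[tab["enriched"]]
    tab = tab[tab["fold_enrichment"].notna()]
    if tab.empty:
        raise ValueError("no genes with defined fold enrichment to rank")
    key = tab.reset_index(names="gene_id")
    key = key.sort_values(
        by=["fold_enrichment", "padj", "gene_id"],
        ascending=[False, True, True],
        kind="stable",
    )
    order = key.set_index("gene_id")
    members = set(member_set) & set(de.universe)
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "fold_enrichment": order["fold_enrichment"].to_numpy(),
            "is_member": [g in members for g in order.index],
        },
        index=order.index,
    )
    return RankedGenes(out, member_set_size=len(members))


def _irls(x: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50):
    """IRLS for logit(p) = b0 + b1*x. Returns (beta, cov, converged, iters)."""
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    beta = np.zeros(2)
    converged = False
    it = 0
    cov = np.full((2, 2), np.nan)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        w = np.maximum(w, 1e-12)
        z = eta + (y - p) / w
        XtW = X.T * w
        try:
            fisher = XtW @ X
            new = np.linalg.solve(fisher, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1.0 - p), 1e-12)
    fisher = (X.T * w) @ X
    try:
        cov = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        pass
    with np.errstate(divide="ignore"):
        ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
    deviance = float(-2 * ll)
    return beta, cov, converged, it, deviance


def fit_logistic(ranked: RankedGenes) -> LogisticFit:
    """Fit membership ~ intercept + slope * rank by IRLS.

    Complete separation yields a non-converged fit with a warning (diverging
    coefficients) rather than an exception.
    """
    y = ranked.table["is_member"].to_numpy(dtype=float)
    x = ranked.table["rank"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both member and non-member genes are required for the fit")
    beta, cov, converged, it, deviance = _irls(x, y)
    if not converged:
        warnings.warn(
            "logistic fit did not converge (possible complete separation; "
            "coefficients may be diverging)",
            RuntimeWarning,
            stacklevel=2,
        )
    se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        z_intercept=float(z[0]),
        z_slope=float(z[1]),
        p_intercept=float(p[0]),
        p_slope=float(p[1]),
        converged=bool(converged),
        n_obs=int(len(y)),
        n_iter=int(it),
        deviance=deviance,
    )


def predict_curve(fit: LogisticFit, ranks: np.ndarray | list[float]) -> np.ndarray:
    """Predicted membership probability at the given ranks."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged logistic fit")
    eta = fit.intercept + fit.slope * np.asarray(ranks, dtype=float)
    return 1.0 / (1.0 + np.exp(-eta))


def leading_fold_change_distances(
    matrix: CountMatrix, top: int = 500, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Pairwise leading-fold-change distances between samples.

    Distance = root mean square of the ``top`` largest absolute log2 ratios
    of size-factor-normalized, pseudocount-stabilized counts.
    """
    sf = size_factors(matrix)
    logn = np.log2(matrix.counts.to_numpy(dtype=float) / sf.to_numpy() + pseudocount)
    m = logn.shape[1]
    t = min(top, logn.shape[0])
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            diff = np.abs(logn[:, i] - logn[:, j])
            lead = np.partition(diff, len(diff) - t)[len(diff) - t:]
            D[i, j] = D[j, i] = np.sqrt(np.mean(lead**2))
    return pd.DataFrame(D, index=matrix.sample_ids, columns=matrix.sample_ids)


def classical_mds(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson principal-coordinate embedding of a distance matrix.

    Double-centers the squared distances and takes the top-k eigenpairs;
    negative eigenvalues (non-Euclidean part) are truncated at zero.
    """
    D = np.asarray(D, dtype=float)
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    Bmat = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(Bmat)
    idx = np.argsort(eigval)[::-1][:k]
    return eigvec[:, idx] * np.sqrt(np.clip(eigval[idx], 0, None))


def mds_leading_foldchange(
    matrix: CountMatrix, top: int = 500, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Classical MDS of samples on leading-fold-change distances (2-D)."""
    if matrix.shape[1] < 3:
        raise ValueError("MDS requires at least 3 samples")
    D = leading_fold_change_distances(matrix, top=top, pseudocount=pseudocount).to_numpy()
    coords = classical_mds(D, k=2)
    return pd.DataFrame(coords, index=matrix.sample_ids, columns=["dim1", "dim2"])
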