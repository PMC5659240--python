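"""Negative-binomial differential enrichment between purified sample types.

This is a from-scratch implementation of the classic count-based exact-test
workflow (the first-generation DESeq procedure): a counts-per-million low
expression filter, median-of-ratios size factors, pooled method-of-moments
dispersion estimates shrunk toward a parametric mean trend
phi(mu) = a0 + a1/mu (sharing mode "maximum"), a conditional NB exact test
per gene, Benjamini-Hochberg adjustment, and enrichment calls at
padj < alpha with fold enrichment > 1.

Under the NB model a count K_gj has mean s_j * q_g and variance
s_j * q_g + phi_g * (s_j * q_g)^2, where s_j is the sample's size factor,
q_g the common per-gene concentration and phi_g the dispersion. The exact
test conditions on the total count of a gene across both sample types and
sums the probabilities of all splits at most as probable as the observed
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import CountMatrix, SampleSheet

__all__ = [
    "DEResult",
    "cpm",
    "filter_low_counts",
    "size_factors",
    "estimate_dispersions",
    "nb_exact_test",
    "bh_adjust",
    "run_comparison",
]

_DISP_FLOOR = 1e-8


@dataclass
class DEResult:
    """Per-gene statistics for one pairwise comparison (A enriched over B).

    ``table`` is indexed by gene id with columns ``mean_norm_A``,
    ``mean_norm_B``, ``fold_enrichment`` (A/B on normalized means), ``pval``,
    ``padj`` and ``enriched`` (padj < alpha and fold_enrichment > 1).
    """

    table: pd.DataFrame
    type_a: str
    type_b: str
    alpha: float
    size_factors: dict[str, float]
    dispersion_trend: tuple[float, float]  # (a0, a1) of phi(mu) = a0 + a1/mu
    n_genes_prefilter: int = 0

    @property
    def enriched_genes(self) -> list[str]:
        return list(self.table.index[self.table["enriched"]])

    @property
    def universe(self) -> list[str]:
        """The filtered gene universe this comparison was run on."""
        return list(self.table.index)


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library size * 1e6, per sample."""
    lib = matrix.counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    return matrix.counts / lib * 1e6


def filter_low_counts(
    matrix: CountMatrix,
    samples_in_comparison: list[str] | None = None,
    min_cpm: float = 1.0,
    max_samples_below: int = 2,
) -> CountMatrix:
    """Drop genes with low counts in too many samples of the comparison.

    A gene is removed iff the number of comparison samples with
    CPM < ``min_cpm`` exceeds ``max_samples_below`` (the published rule:
    three or more samples under 1 CPM). CPM uses library sizes of the
    unfiltered matrix; gene order is preserved and all matrix samples are
    retained in the output.
    """
    if samples_in_comparison is None:
        samples_in_comparison = matrix.sample_ids
    if not samples_in_comparison:
        raise ValueError("empty comparison: no samples given")
    sub = matrix.select_samples(samples_in_comparison)
    below = (cpm(sub) < min_cpm).sum(axis=1)
    keep = below <= max_samples_below
    return CountMatrix(matrix.counts.loc[keep])


def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene expressed in every sample, form the ratio of its count to
    its geometric mean across samples; the size factor of a sample is the
    median of these ratios. Columns that are elementwise equal get factor 1.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_geo = np.log(counts).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = counts[usable] / np.exp(log_geo[usable])[:, None]
    return pd.Series(np.median(ratios, axis=0), index=matrix.sample_ids, name="size_factor")


def _gamma_glm_identity(mu: np.ndarray, disp: np.ndarray, start: np.ndarray) -> np.ndarray:
    """One gamma-family GLM fit (identity link) of disp on 1/mu by IRLS."""
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coef = start.copy()
    for _ in range(50):
        fitted = np.maximum(X @ coef, 1e-10)
        w = 1.0 / fitted**2  # gamma working weights, identity link
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X, XtW @ disp)
        except np.linalg.LinAlgError:
            break
        if np.all(np.abs(new - coef) <= 1e-12 * (np.abs(coef) + 1e-12)):
            coef = new
            break
        coef = new
    return coef


def _gamma_trend_fit(mu: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit phi = a0 + a1/mu by iteratively trimmed gamma regression.

    Outer iterations refit on the genes whose ratio disp/fitted lies in
    (1e-4, 15), discarding dispersion outliers far above the trend and
    near-zero estimates, until the coefficients stabilize.
    """
    coef = np.array([0.1, 1.0])
    for _ in range(10):
        fitted = np.maximum(coef[0] + coef[1] / mu, 1e-12)
        resid = disp / fitted
        good = (resid > 1e-4) & (resid < 15)
        if good.sum() < 2:
            break
        old = coef
        coef = _gamma_glm_identity(mu[good], disp[good], coef)
        if np.any(coef <= 0):
            coef = np.maximum(coef, 0.0)
            break
        if np.sum(np.log(np.maximum(coef, 1e-12) / np.maximum(old, 1e-12)) ** 2) < 1e-6:
            break
    a0, a1 = float(coef[0]), float(coef[1])
    return max(a0, 0.0), max(a1, 0.0)


def estimate_dispersions(
    matrix: CountMatrix,
    sf: pd.Series,
    sheet: SampleSheet,
) -> tuple[pd.Series, tuple[float, float]]:
    """Per-gene NB dispersions with a parametric mean trend.

    Method of moments on normalized counts pooled within conditions:
    raw_g = (v_g - z_g) / q_g^2 with q_g the base mean, v_g the pooled
    within-condition sample variance and z_g = q_g * mean(1/s_j) the
    shot-noise contribution. The trend phi(mu) = a0 + a1/mu is fitted on
    genes with positive raw dispersion; the final value is
    max(raw_g, trend(q_g)) floored at 1e-8 (sharing mode "maximum").
    """
    counts = matrix.counts
    s = sf.loc[counts.columns].to_numpy()
    norm = counts.to_numpy(dtype=float) / s

    conditions: dict[str, list[int]] = {}
    for j, sid in enumerate(counts.columns):
        conditions.setdefault(sheet.types[sid], []).append(j)
    if all(len(idx) < 2 for idx in conditions.values()):
        raise ValueError(
            "no condition has replicates; dispersion estimation requires >=2 "
            "replicates in at least one condition (blind mode is out of scope)"
        )

    m = norm.shape[1]
    q = norm.mean(axis=1)
    ss = np.zeros(len(q))
    for idx in conditions.values():
        block = norm[:, idx]
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_resid = m - len(conditions)
    v = ss / max(df_resid, 1)
    z = q * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(q > 0, (v - z) / q**2, 0.0)

    positive = (raw > 0) & (q > 0)
    if positive.sum() >= 2:
        a0, a1 = _gamma_trend_fit(q[positive], raw[positive])
    else:  # essentially dispersion-free data
        a0, a1 = 0.0, 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(q > 0, a0 + a1 / q, a0)
    phi = np.maximum(np.maximum(raw, trend), _DISP_FLOOR)
    return pd.Series(phi, index=counts.index, name="dispersion"), (a0, a1)


def _nb_logpmf(k: np.ndarray, mean: float, size: float | None) -> np.ndarray:
    """Log pmf of NB(mean, size); Poisson when size is None (phi -> 0)."""
    if size is None:
        return stats.poisson.logpmf(k, mean)
    p = size / (size + mean)
    return (
        gammaln(k + size)
        - gammaln(size)
        - gammaln(k + 1)
        + size * math.log(p)
        + k * np.log1p(-p)
    )


def nb_exact_test(
    k_a: np.ndarray,
    k_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    phi: float,
) -> float:
    """Conditional NB exact test for one gene.

    Conditions on the total K over both sample types; each side's total is
    NB with mean q0 * S and variance q0 * S + phi * q0^2 * S2, where
    S = sum of the side's size factors, S2 the sum of their squares and
    q0 = K / (S_A + S_B). The p-value sums, over all splits (a, K - a),
    the probabilities no larger than the observed split's, normalized by the
    total; all-zero genes give p = 1 by convention.
    """
    k_a, k_b = np.asarray(k_a), np.asarray(k_b)
    sf_a, sf_b = np.asarray(sf_a, dtype=float), np.asarray(sf_b, dtype=float)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    ka, kb = int(k_a.sum()), int(k_b.sum())
    K = ka + kb
    if K == 0:
        return 1.0
    SA, SB = sf_a.sum(), sf_b.sum()
    # common concentration = base mean of normalized counts over both sides
    q0 = (np.sum(k_a / sf_a) + np.sum(k_b / sf_b)) / (len(k_a) + len(k_b))
    if q0 <= 0:
        q0 = K / (SA + SB)

    def side_params(S: float, S2: float) -> tuple[float, float | None]:
        mean = q0 * S
        var = mean + phi * q0**2 * S2
        if var <= mean * (1 + 1e-12):
            return mean, None  # Poisson limit
        return mean, mean**2 / (var - mean)

    mean_a, size_a = side_params(SA, (sf_a**2).sum())
    mean_b, size_b = side_params(SB, (sf_b**2).sum())

    ks = np.arange(K + 1)
    logp = _nb_logpmf(ks, mean_a, size_a) + _nb_logpmf(ks[::-1], mean_b, size_b)
    logp_obs = logp[ka]
    # 1e-12 relative guard so exactly-mirrored splits tie despite rounding
    incl = logp <= logp_obs + 1e-12 * abs(logp_obs) + 1e-300
    with np.errstate(over="ignore"):
        num = np.exp(logp[incl] - logp_obs).sum()
        den = np.exp(logp - logp_obs).sum()
    return float(min(1.0, num / den))


def bh_adjust(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_comparison(
    matrix: CountMatrix,
    sheet: SampleSheet,
    type_a: str,
    type_b: str,
    alpha: float = 0.1,
    min_cpm: float = 1.0,
    max_samples_below: int = 2,
) -> DEResult:
    """Full filter -> normalize -> dispersion -> exact test -> BH pipeline.

    ``type_a`` is the sample type of interest: ``enriched`` means
    significantly higher normalized mean in A than in B.
    """
    samples_a = sheet.samples_of_type(type_a)
    samples_b = sheet.samples_of_type(type_b)
    for label, ss in ((type_a, samples_a), (type_b, samples_b)):
        if len(ss) < 2:
            raise ValueError(f"sample type {label!r} needs >=2 samples, found {len(ss)}")
    comparison_samples = samples_a + samples_b

    filtered = filter_low_counts(
        matrix.select_samples(comparison_samples),
        comparison_samples,
        min_cpm=min_cpm,
        max_samples_below=max_samples_below,
    )
    sf = size_factors(filtered)
    sub_sheet = SampleSheet({s: sheet.types[s] for s in comparison_samples})
    phi, trend = estimate_dispersions(filtered, sf, sub_sheet)

    counts = filtered.counts
    norm = counts / sf
    mean_a = norm[samples_a].mean(axis=1)
    mean_b = norm[samples_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean_a / mean_b  # 0/0 -> NaN, x/0 -> +inf sentinel

    sfa = sf.loc[samples_a].to_numpy()
    sfb = sf.loc[samples_b].to_numpy()
    ka = counts[samples_a].to_numpy()
    kb = counts[samples_b].to_numpy()
    pvals = np.array(
        [
            nb_exact_test(ka[i], kb[i], sfa, sfb, float(phi.iloc[i]))
            for i in range(counts.shape[0])
        ]
    )
    padj = bh_adjust(pvals)
    table = pd.DataFrame(
        {
            "mean_norm_A": mean_a,
            "mean_norm_B": mean_b,
            "fold_enrichment": fold,
            "pval": pvals,
            "padj": padj,
            "dispersion": phi,
        },
        index=counts.index,
    )
    table["enriched"] = (table["padj"] < alpha) & (table["fold_enrichment"] > 1)
    return DEResult(
        table=table,
        type_a=type_a,
        type_b=type_b,
        alpha=alpha,
        size_factors={s: float(v) for s, v in sf.items()},
        dispersion_trend=trend,
        n_genes_prefilter=matrix.shape[0],
    )
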