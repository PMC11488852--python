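"""Differential expression between Y^M and III^M samples.

The stage mirrors a standard bulk RNA-seq chain: a counts-per-million
abundance filter, a variance-stabilizing normalization (median-of-ratios
size factors followed by log2), surrogate-variable estimation for latent
batch structure, per-gene linear models with empirical-Bayes moderated
t-statistics, and Benjamini-Hochberg FDR control.

The fold-change orientation is fixed as III^M minus Y^M and recorded on
the result object, since "upregulated in Y^M" and "upregulated in III^M"
are both meaningful directions downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "filter_low_expression",
    "normalize_vst",
    "estimate_surrogate_variables",
    "fit_de_model",
    "adjust_fdr",
]


@dataclass
class DEResult:
    """Per-gene moderated contrast results.

    ``table`` has columns ``log2fc`` (orientation: ``contrast`` label),
    ``t``, ``p`` and ``p_adj`` indexed by gene ID.
    """

    table: pd.DataFrame
    contrast: str = "IIIM-YM"
    prior_df: float = np.inf
    prior_var: float = np.nan

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


def filter_low_expression(
    counts: pd.DataFrame, cpm_threshold: float = 0.5, min_samples: int = 4
) -> pd.DataFrame:
    """Keep genes with CPM >= ``cpm_threshold`` in >= ``min_samples`` samples.

    Library size is the per-sample column sum; gene order is preserved.
    """
    libs = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(libs <= 0):
        raise ValueError("all library sizes must be positive")
    cpm = counts.to_numpy(dtype=float) / libs[None, :] * 1e6
    keep = (cpm >= cpm_threshold).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return counts.loc[keep]


def normalize_vst(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios size factors followed by ``log2(count/sf + 1)``.

    The size factor of a sample is the median across genes of the ratio of
    its counts to the per-gene geometric-mean reference, computed over
    genes with all-positive counts.  If no such gene exists, library-size
    factors (scaled to geometric mean 1) are used with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if allpos.any():
        logx = np.log(x[allpos])
        ref = logx.mean(axis=1)  # log geometric mean
        sf = np.exp(np.median(logx - ref[:, None], axis=0))
    else:
        warnings.warn(
            "no gene with all-positive counts; falling back to library-size factors",
            stacklevel=2,
        )
        libs = x.sum(axis=0)
        sf = libs / np.exp(np.mean(np.log(libs)))
    out = np.log2(x / sf[None, :] + 1.0)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def _design_matrix(genotype: pd.Series | np.ndarray) -> np.ndarray:
    g = np.asarray(genotype)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("genotype must have exactly two levels")
    # second level (sorted) is coded 1 so that IIIM - YM is positive for IIIM
    hi = sorted(map(str, levels))[0]
    x = (g.astype(str) == hi).astype(float)
    return np.column_stack([np.ones_like(x), x])


def estimate_surrogate_variables(
    expr: pd.DataFrame,
    genotype: pd.Series | np.ndarray,
    n_sv: int | None = None,
    n_permutations: int = 20,
    alpha: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Estimate surrogate variables for latent (e.g. batch) variation.

    Residualizes the expression matrix against the genotype design and
    takes leading left singular vectors of the sample-space residuals.
    When ``n_sv`` is None, the number of components is chosen by
    permutation-based parallel analysis: a singular value is kept while it
    exceeds the ``1 - alpha`` quantile of singular values obtained after
    independently permuting each gene's residuals across samples.

    Returns a ``samples x k`` orthonormal matrix (possibly ``k = 0``); the
    columns are orthogonal to the design by construction.
    """
    X = _design_matrix(genotype)
    n = expr.shape[1]
    if n <= X.shape[1]:
        raise ValueError("need more samples than design columns")
    max_k = n - X.shape[1] - 1
    if n_sv is not None and n_sv > max_k:
        raise ValueError(f"n_sv={n_sv} >= residual degrees of freedom")
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    H = X @ np.linalg.pinv(X)
    R = Y - H @ Y
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    if n_sv is None:
        # parallel analysis on variance shares: permuting each gene's
        # residuals breaks latent sample structure, and re-residualizing
        # plus share-normalization keeps the null comparable to the
        # observed rank-deficient residual spectrum
        share = s**2 / np.sum(s**2)
        rng = np.random.Generator(np.random.Philox(seed))
        null_share = np.empty((n_permutations, len(s)))
        for b in range(n_permutations):
            perm = rng.permuted(R, axis=0)  # permute each gene independently
            perm = perm - H @ perm
            s_null = np.linalg.svd(perm, compute_uv=False)
            null_share[b] = s_null**2 / np.sum(s_null**2)
        thresh = np.quantile(null_share, 1.0 - alpha, axis=0)
        k = 0
        while k < max_k and share[k] > thresh[k]:
            k += 1
    else:
        k = n_sv
    return U[:, :k]


def _moment_match_prior(log_s2: np.ndarray, df: float) -> tuple[float, float]:
    """limma-style moment matching on log residual variances.

    ``e_g = log(s_g^2) - digamma(df/2) + log(df/2)`` is an unbiased
    estimate of ``log(sigma_g^2)`` up to prior spread; the excess of
    ``var(e)`` over ``trigamma(df/2)`` identifies the prior df via the
    inverse trigamma, and the prior variance follows from the mean.
    """
    e = log_s2 - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 1e-8:
        return np.inf, float(np.exp(np.mean(e)))
    # invert trigamma(x) = excess by Newton (standard limma trick)
    x = 0.5 + 1.0 / excess
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / excess) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10:
            break
    d0 = 2.0 * x
    s0_sq = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    return d0, s0_sq


def fit_de_model(
    expr: pd.DataFrame,
    genotype: pd.Series | np.ndarray,
    surrogate_vars: np.ndarray | None = None,
    shrink: bool = True,
) -> DEResult:
    """Per-gene linear model for the genotype contrast with moderated t.

    Ordinary least squares gene by gene on a design of intercept +
    genotype + surrogate variables; residual variances are shrunk toward
    an empirical-Bayes prior (method-of-moments on log variances) and the
    genotype coefficient is tested with a t distribution on the combined
    degrees of freedom.  ``shrink=False`` gives the classical per-gene t.
    """
    X = _design_matrix(genotype)
    if surrogate_vars is not None and surrogate_vars.size:
        X = np.column_stack([X, surrogate_vars])
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design (collinear genotype/surrogate columns)")
    if n <= p:
        raise ValueError("no residual degrees of freedom")
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # p x genes
    resid = Y - X @ beta
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    c = XtX_inv[1, 1]  # genotype coefficient variance multiplier
    fc = beta[1]

    if shrink:
        pos = s2 > 0
        if pos.sum() >= 2:
            d0, s0_sq = _moment_match_prior(np.log(s2[pos]), df)
        else:
            d0, s0_sq = np.inf, float(s2.mean())
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = d0 + df
    else:
        d0, s0_sq = 0.0, np.nan
        s2_post = s2
        df_total = df

    se = np.sqrt(np.maximum(s2_post, 0.0) * c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / np.where(se > 0, se, 1.0), 0.0)
    t = np.where(fc == 0, 0.0, t)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {"log2fc": fc, "t": t, "p": pvals, "p_adj": adjust_fdr(pvals)},
        index=expr.index,
    )
    return DEResult(table=table, contrast="IIIM-YM", prior_df=d0, prior_var=s0_sq)


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
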