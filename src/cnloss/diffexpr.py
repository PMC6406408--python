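"""Precision-weighted two-group differential expression with empirical-Bayes
variance moderation.

The procedure reimplements the published voom/limma formulas for the
two-group case:

1.  log2-CPM values are fitted per gene by ordinary least squares on the
    (intercept, group) design; the square-root residual standard deviations
    are smoothed against average log2 count by LOWESS, and each observation
    receives weight (trend at its fitted log2 count)^-4 — the inverse of the
    predicted variance of its log2-CPM value.
2.  Weighted least squares per gene yields the group coefficient beta (the
    log2 fold change), its unscaled standard deviation u, and the residual
    variance s^2 on d = n - 2 degrees of freedom.
3.  The gene-wise variances are shrunk toward a common prior: the marginal
    distribution of s^2 under the hierarchical model is s0^2 * F(d, d0), and
    (d0, s0^2) are estimated by matching moments of log s^2 (solving the
    trigamma equation for d0).  The posterior variance is the
    degrees-of-freedom-weighted average (d0*s0^2 + d*s^2) / (d0 + d).
4.  Moderated t = beta / (u * s_post) on d0 + d degrees of freedom; q-values
    are Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, cpm, log_cpm
from .io import CountMatrix, DE_COLUMNS

logger = logging.getLogger(__name__)

LOWESS_SPAN = 0.5


@dataclass
class GeneFits:
    """Per-gene weighted least-squares summaries (arrays over genes)."""

    beta: np.ndarray        # group coefficient, log2 units
    stdev_unscaled: np.ndarray  # sqrt of (group, group) entry of (X'WX)^-1
    sigma: np.ndarray       # residual standard deviation
    df_residual: int
    ave_expr: np.ndarray    # mean log2-CPM per gene


@dataclass
class ModerationPrior:
    """Empirical-Bayes prior for the gene-wise residual variances."""

    df_prior: float         # d0, may be inf
    s2_prior: float         # s0^2

    def posterior_variance(self, s2: np.ndarray, df: float) -> np.ndarray:
        if np.isinf(self.df_prior):
            return np.full_like(np.asarray(s2, dtype=float), self.s2_prior)
        return (self.df_prior * self.s2_prior + df * s2) / (self.df_prior + df)


def build_design(n_inactivated: int, n_control: int) -> np.ndarray:
    """(intercept, group) design; rows are inactivated samples then controls.

    The group indicator is 1 for inactivated, so a negative coefficient means
    lower expression in the inactivated set.
    """
    if n_inactivated < 1 or n_control < 1:
        raise ValueError("both groups must be non-empty")
    n = n_inactivated + n_control
    design = np.ones((n, 2))
    design[n_inactivated:, 1] = 0.0
    return design


def mean_variance_weights(logcpm: ExpressionMatrix, design: np.ndarray,
                          span: float = LOWESS_SPAN) -> np.ndarray:
    """Observation-level precision weights from the mean-variance trend.

    Fits each gene by OLS, smooths sqrt(residual sd) against average log2
    count with LOWESS (span ``span``, 3 robustness iterations, the reference
    defaults), and evaluates the trend at every observation's fitted log2
    count; the weight is trend^-4.  With no residual variation anywhere the
    trend is undefined and unit weights are returned with a warning.
    """
    y = logcpm.values
    n_genes, n = y.shape
    if n_genes < 10:
        raise ValueError(
            f"only {n_genes} genes after filtering; the mean-variance trend "
            "needs >= 10 — relax the expression filters")
    # gene-wise OLS with a shared design
    pinv = np.linalg.pinv(design)          # p x n
    coef = y @ pinv.T                      # G x p
    fitted = coef @ design.T               # G x n
    resid = y - fitted
    df_resid = n - design.shape[1]
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    if not np.any(sigma > 1e-10):  # exact fits everywhere: trend undefined
        warnings.warn("no residual variation in any gene; "
                      "falling back to unit precision weights")
        return np.ones_like(y)
    # mean log2 count per gene; log2 library-size offset puts CPM back on
    # the count scale
    offset = np.mean(np.log2(logcpm.lib_sizes + 1.0)) - np.log2(1e6)
    sx = y.mean(axis=1) + offset
    sy = np.sqrt(sigma)
    delta = 0.01 * (sx.max() - sx.min())
    trend = sm_lowess(sy, sx, frac=span, it=3, delta=delta, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # collapse duplicate x for interpolation
    tx, idx = np.unique(tx, return_index=True)
    ty = ty[idx]
    # fitted log2 count for every observation
    fitted_logcount = fitted + np.log2(logcpm.lib_sizes + 1.0)[np.newaxis, :] \
        - np.log2(1e6)
    pred = np.interp(fitted_logcount, tx, ty)   # constant extrapolation
    pred = np.maximum(pred, 1e-10)
    return pred ** -4


def weighted_lm_fit(logcpm: ExpressionMatrix, weights: np.ndarray,
                    design: np.ndarray) -> GeneFits:
    """Gene-wise weighted least squares on a shared design.

    Returns the group coefficient, its unscaled standard deviation
    u = sqrt[(X'WX)^-1_(group,group)], and the residual sd on n - 2 df.
    """
    y = logcpm.values
    if weights.shape != y.shape:
        raise ValueError("weights shape must match the expression matrix")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    n, p = design.shape
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("singular design matrix")
    xtwx = np.einsum("gn,ni,nj->gij", weights, design, design)
    xtwy = np.einsum("gn,ni,gn->gi", weights, design, y)
    cov_unscaled = np.linalg.inv(xtwx)
    coef = np.einsum("gij,gj->gi", cov_unscaled, xtwy)
    resid = y - coef @ design.T
    df_resid = n - p
    s2 = (weights * resid ** 2).sum(axis=1) / df_resid
    return GeneFits(
        beta=coef[:, 1],
        stdev_unscaled=np.sqrt(cov_unscaled[:, 1, 1]),
        sigma=np.sqrt(s2),
        df_residual=df_resid,
        ave_expr=y.mean(axis=1),
    )


def trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x for y > 0 (Newton iteration on the trigamma)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationPrior:
    """Fit the scaled-F prior to the observed residual variances.

    Moment-matching on e = log s^2 - psi(d/2) + log(d/2): the excess of
    var(e) over trigamma(d/2) identifies d0 through the inverse trigamma;
    s0^2 follows from the mean.  Zero variances (exact fits) are left out of
    the moment estimation but are still shrunk by the resulting prior.  When
    the observed log-variances underdisperse the pure sampling noise, d0 is
    infinite and the prior variance is the geometric mean of the positive
    s^2 — in particular, all-equal variances are returned unchanged.
    """
    s2 = np.asarray(s2, dtype=float)
    if df <= 0 or s2.size < 2:
        raise ValueError("need >= 2 genes with positive residual df")
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all residual variances are zero; no variation to model")
    e = np.log(pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df_prior = 2.0 * trigamma_inverse(evar)
        s2_prior = float(np.exp(np.mean(e) + special.digamma(df_prior / 2.0)
                                - np.log(df_prior / 2.0)))
    else:
        df_prior = np.inf
        s2_prior = float(np.exp(np.mean(np.log(pos))))
    return ModerationPrior(df_prior=df_prior, s2_prior=s2_prior)


def moderated_stats(fits: GeneFits, prior: ModerationPrior
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided p-values.

    t = beta / (u * s_post) on d0 + d degrees of freedom; the total df is
    capped at the pooled residual df (G * d) so an infinite prior yields the
    pooled-variance (asymptotically normal) reference distribution.
    """
    s2_post = prior.posterior_variance(fits.sigma ** 2, fits.df_residual)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.beta / (fits.stdev_unscaled * np.sqrt(s2_post))
    t = np.where(np.isnan(t), 0.0, t)
    df_total = prior.df_prior + fits.df_residual
    df_pooled = fits.df_residual * len(fits.beta)
    df_total = min(df_total, df_pooled)
    if np.isinf(df_total):  # pragma: no cover - only without the pooled cap
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, s2_post


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(counts: CountMatrix, n_inactivated: int, n_control: int,
             span: float = LOWESS_SPAN
             ) -> tuple[pd.DataFrame, ModerationPrior]:
    """Full differential-expression table for a filtered count matrix.

    The matrix columns must be ordered inactivated samples first, controls
    after, matching :func:`build_design`.  Returns the per-gene table
    (sorted by q ascending, ties by \\|logFC\\| descending) and the fitted
    moderation prior.
    """
    design = build_design(n_inactivated, n_control)
    ylog = log_cpm(counts)
    weights = mean_variance_weights(ylog, design, span=span)
    fits = weighted_lm_fit(ylog, weights, design)
    prior = estimate_prior(fits.sigma ** 2, fits.df_residual)
    t, p, _ = moderated_stats(fits, prior)
    q = adjust_bh(p)
    expr = cpm(counts)
    med_inact = np.median(expr.values[:, :n_inactivated], axis=1)
    med_ctrl = np.median(expr.values[:, n_inactivated:], axis=1)
    table = pd.DataFrame({
        "gene": counts.gene_ids,
        "logFC": fits.beta,
        "AveExpr": fits.ave_expr,
        "t": t,
        "p": p,
        "q": q,
        "median_cpm_inactivated": med_inact,
        "median_cpm_control": med_ctrl,
    }, columns=DE_COLUMNS)
    table["_abs_lfc"] = table["logFC"].abs()
    table = (table.sort_values(["q", "_abs_lfc", "gene"],
                               ascending=[True, False, True], kind="mergesort")
             .drop(columns="_abs_lfc").reset_index(drop=True))
    return table, prior
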