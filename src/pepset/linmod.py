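"""Per-peptide linear models and empirical-Bayes moderated t-statistics.

Each peptide is fit by ordinary least squares on its observed samples
(intercept + two-group indicator + optional covariates). Residual
variances are then shrunk toward a pooled prior by moment matching of
log variances against a scaled-F model, giving moderated t-statistics
with ``d0 + df_resid`` degrees of freedom. An optional covariate trend
lets the prior variance vary smoothly (lowess) with, e.g., log peptide
count in protein-level comparator workflows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import DesignSpec, PeptideQuantTable

__all__ = [
    "PeptideFitResult",
    "fit_peptides",
    "empirical_bayes",
    "moderated_t",
    "moderate",
    "trigamma_inverse",
]


@dataclass
class PeptideFitResult:
    """OLS estimates per peptide, later augmented with moderated statistics.

    ``ok`` flags peptides with an estimable contrast (>=2 observations in
    each group and positive residual df); the rest carry NaN but are kept
    so row order matches the source table.
    """

    effect: np.ndarray
    sigma2: np.ndarray
    df_resid: np.ndarray
    stdev_unscaled: np.ndarray
    ok: np.ndarray
    d0: float | np.ndarray | None = None
    s0_2: float | np.ndarray | None = None
    s2_post: np.ndarray | None = None
    t_mod: np.ndarray | None = None
    df_total: np.ndarray | None = None
    p: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.effect)


def fit_peptides(table: PeptideQuantTable, design: DesignSpec) -> PeptideFitResult:
    """Fit per-peptide OLS models for the group contrast.

    The effect is the test-minus-reference coefficient. Peptides with
    fewer than 2 observations in either group (or with no residual df)
    are flagged, not dropped.
    """
    design = design.aligned(table.sample_ids)
    y = table.abundance
    n_pep = table.n_peptides

    if design.covariates is None:
        g = design.group_indicator().astype(bool)
        return _fit_two_group(y, g)

    X_full, eff_col = design.design_matrix()
    effect = np.full(n_pep, np.nan)
    sigma2 = np.full(n_pep, np.nan)
    df_resid = np.zeros(n_pep)
    unscaled = np.full(n_pep, np.nan)
    ok = np.zeros(n_pep, dtype=bool)
    g = design.group_indicator().astype(bool)
    for i in range(n_pep):
        obs = ~np.isnan(y[i])
        if np.sum(obs & g) < 2 or np.sum(obs & ~g) < 2:
            continue
        X = X_full[obs]
        yi = y[i, obs]
        beta, _, rank, _ = np.linalg.lstsq(X, yi, rcond=None)
        df = int(obs.sum()) - rank
        if df < 1 or rank < X.shape[1]:
            continue
        resid = yi - X @ beta
        xtx_inv = np.linalg.inv(X.T @ X)
        effect[i] = beta[eff_col]
        sigma2[i] = resid @ resid / df
        df_resid[i] = df
        unscaled[i] = math.sqrt(xtx_inv[eff_col, eff_col])
        ok[i] = True
    return PeptideFitResult(effect, sigma2, df_resid, unscaled, ok)


def _fit_two_group(y: np.ndarray, test_mask: np.ndarray) -> PeptideFitResult:
    """Vectorized group-only OLS (equivalent to lstsq per peptide)."""
    obs = ~np.isnan(y)
    n1 = (obs & ~test_mask).sum(axis=1)   # reference group
    n2 = (obs & test_mask).sum(axis=1)    # test group
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(np.where(~test_mask, y, np.nan), axis=1)
        m2 = np.nanmean(np.where(test_mask, y, np.nan), axis=1)
        ss1 = np.nansum(np.where(~test_mask, (y - m1[:, None]) ** 2, np.nan), axis=1)
        ss2 = np.nansum(np.where(test_mask, (y - m2[:, None]) ** 2, np.nan), axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    df = np.where(ok, n1 + n2 - 2, 0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.where(ok, m2 - m1, np.nan)
        sigma2 = np.where(ok, (ss1 + ss2) / np.where(df > 0, df, 1), np.nan)
        unscaled = np.where(ok, np.sqrt(1.0 / np.maximum(n1, 1)
                                        + 1.0 / np.maximum(n2, 1)), np.nan)
    return PeptideFitResult(effect, sigma2, df, unscaled, ok)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration (tol 1e-8)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return x


def empirical_bayes(sigma2: np.ndarray, df_resid: np.ndarray,
                    trend_covariate: np.ndarray | None = None,
                    span: float = 0.5):
    """Estimate prior df ``d0`` and prior variance ``s0_2``.

    Moment matching on log variances: ``e = log(s2) - digamma(df/2) +
    log(df/2)`` is an unbiased estimate of ``log(sigma2_true)``; its excess
    variance over ``trigamma(df/2)`` identifies ``trigamma(d0/2)``. With a
    trend covariate the location of ``e`` is a lowess fit on the covariate
    and ``s0_2`` becomes per-peptide.

    Returns ``(d0, s0_2)``; ``d0`` is ``inf`` when the log variances show no
    excess spread (all-equal variances give back the common value).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df_resid = np.asarray(df_resid, dtype=float)
    use = np.isfinite(sigma2) & (sigma2 > 0) & (df_resid > 0)
    if use.sum() < 2:
        raise ValueError("need >=2 peptides with positive residual variance")
    s2 = sigma2[use]
    df = df_resid[use]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)

    if trend_covariate is not None:
        cov = np.asarray(trend_covariate, dtype=float)[use]
        if not np.isfinite(cov).all():
            raise ValueError("trend covariate contains non-finite values")
        if np.ptp(cov) == 0:
            emean_local = np.full_like(e, e.mean())
        else:
            order = np.argsort(cov, kind="stable")
            with warnings.catch_warnings():
                # heavily tied covariates trip a harmless 0/0 inside lowess
                warnings.simplefilter("ignore", RuntimeWarning)
                fitted = lowess(e[order], cov[order], frac=span, return_sorted=False)
            emean_local = np.empty_like(e)
            emean_local[order] = fitted
    else:
        emean_local = np.full_like(e, e.mean())

    n = len(e)
    evar = np.mean((e - emean_local) ** 2) * n / (n - 1) \
        - np.mean(special.polygamma(1, df / 2.0))

    if np.allclose(s2, s2[0], rtol=1e-12, atol=0.0):
        d0 = np.inf
        s0_full = np.full(len(sigma2), np.nan)
        s0_full[use] = s2[0]
    elif evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0 = np.exp(emean_local + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        s0_full = np.full(len(sigma2), np.nan)
        s0_full[use] = s0
    else:
        d0 = np.inf
        s0_full = np.full(len(sigma2), np.nan)
        s0_full[use] = np.exp(emean_local)

    if trend_covariate is None:
        s0_scalar = float(s0_full[use][0]) if np.allclose(
            s0_full[use], s0_full[use][0]) else float(np.nanmean(s0_full))
        return d0, s0_scalar
    return d0, s0_full


def moderated_t(fit: PeptideFitResult) -> PeptideFitResult:
    """Compute moderated t and two-sided p from a fit with d0/s0_2 set.

    Posterior variance ``s2_post = (d0*s0_2 + df*sigma2) / (d0 + df)``;
    the reference distribution is Student t with ``d0 + df`` df (normal in
    the ``d0 = inf`` limit).
    """
    if fit.d0 is None or fit.s0_2 is None:
        raise ValueError("empirical_bayes must be applied before moderated_t")
    d0 = fit.d0
    s0 = np.broadcast_to(np.asarray(fit.s0_2, dtype=float), fit.effect.shape)
    df = fit.df_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.where(fit.ok, s0, np.nan)
            df_total = np.full_like(fit.effect, np.inf)
        else:
            s2_post = (d0 * s0 + df * fit.sigma2) / (d0 + df)
            df_total = d0 + df
        t = fit.effect / (np.sqrt(s2_post) * fit.stdev_unscaled)
    t = np.where(fit.ok, t, np.nan)
    p = np.full_like(t, np.nan)
    fin = np.isfinite(t)
    inf_df = np.isinf(df_total)
    p[fin & inf_df] = 2.0 * stats.norm.sf(np.abs(t[fin & inf_df]))
    reg = fin & ~inf_df
    p[reg] = 2.0 * stats.t.sf(np.abs(t[reg]), df_total[reg])
    fit.s2_post = np.where(fit.ok, s2_post, np.nan)
    fit.t_mod = t
    fit.df_total = np.where(fit.ok, df_total, np.nan)
    fit.p = p
    return fit


def moderate(fit: PeptideFitResult,
             trend_covariate: np.ndarray | None = None) -> PeptideFitResult:
    """Convenience: empirical Bayes shrinkage followed by moderated t."""
    d0, s0_2 = empirical_bayes(fit.sigma2, fit.df_resid, trend_covariate)
    fit.d0, fit.s0_2 = d0, s0_2
    return moderated_t(fit)
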