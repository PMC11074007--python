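"""Within-protein inter-peptide correlation estimation.

The default estimator fits, per protein, the linear mixed model

    y_ij = x_j' beta_i + r_j + eps_ij,

with peptide-specific fixed effects (each peptide gets its own
coefficients for the sample design), a random intercept per sample
``r_j ~ N(0, sigma_r2)`` and residual ``eps_ij ~ N(0, sigma_e2)``, by
REML. The common pairwise correlation is ``rho = sigma_r2 / (sigma_r2 +
sigma_e2)``, non-negative by construction.

For complete (no-missing) data the REML optimum has a closed form
obtained from the balanced ANOVA decomposition; otherwise the REML
criterion is profiled down to a single variance ratio and optimized on
the log scale.

The alternative (``wu``) estimator recovers the mean pairwise
correlation from the variance of the standardized residual row-mean and
requires complete data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io import DesignSpec, PeptideQuantTable

__all__ = ["CorrelationEstimate", "estimate_rho_mixed", "estimate_rho_wu"]

_LOG_RATIO_BOUNDS = (-18.0, 18.0)


@dataclass
class CorrelationEstimate:
    """Variance components and the implied inter-peptide correlation."""

    protein_id: str
    rho: float
    sigma_r2: float
    sigma_e2: float
    n_peptides: int
    method: str
    converged: bool = True
    flag: str = ""


def _coerce_matrix(y) -> np.ndarray:
    if isinstance(y, PeptideQuantTable):
        y = y.abundance
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected a peptide x sample matrix")
    return y


def _design_columns(design: DesignSpec, n_samples: int) -> np.ndarray:
    X, _ = design.design_matrix()
    if X.shape[0] != n_samples:
        raise ValueError("design rows do not match sample count")
    return X


def _balanced_reml(y: np.ndarray, D: np.ndarray) -> tuple:
    """Closed-form REML for complete data.

    With every peptide observed in every sample and the same per-sample
    design D, GLS equals per-peptide OLS for any variance ratio, and the
    profiled REML criterion is maximized at the ANOVA estimators
    (truncated at the boundary). Returns (sigma_r2, sigma_e2).
    """
    m, N = y.shape
    B, _, rank, _ = np.linalg.lstsq(D, y.T, rcond=None)
    R = y - (D @ B).T
    k = rank
    s1 = float(np.sum(R * R))
    rbar = R.mean(axis=0)
    s2 = float(m * np.sum(rbar * rbar))
    df_s = N - k
    if df_s <= 0 or m < 2:
        raise ValueError("insufficient residual df for variance components")
    ms_e = (s1 - s2) / ((m - 1) * df_s)
    ms_s = s2 / df_s
    sigma_r2 = (ms_s - ms_e) / m
    if sigma_r2 <= 0:
        # boundary: random effect at zero, residual picks up all variance
        sigma_e2 = s1 / (m * df_s)
        return 0.0, sigma_e2
    return sigma_r2, ms_e


class _ProfiledREML:
    """Profiled REML criterion for one protein with missing cells.

    Observations are the observed (peptide, sample) cells. The fixed-effect
    matrix stacks, per peptide, that peptide's own copy of the sample design
    columns. With H = I + lambda * Z Z' (Z the sample indicator), all H
    solves reduce to per-sample rank-one corrections.
    """

    def __init__(self, y: np.ndarray, D: np.ndarray):
        m, N = y.shape
        obs_i, obs_j = np.nonzero(~np.isnan(y))
        self.n = len(obs_i)
        k = D.shape[1]
        p = m * k
        X = np.zeros((self.n, p))
        for r, (i, j) in enumerate(zip(obs_i, obs_j)):
            X[r, i * k:(i + 1) * k] = D[j]
        yy = y[obs_i, obs_j]
        self.rank = np.linalg.matrix_rank(X)
        self.xtx = X.T @ X
        self.xty = X.T @ yy
        self.yty = float(yy @ yy)
        # per-sample sums of design rows and of y
        self.nj = np.bincount(obs_j, minlength=N).astype(float)
        self.uj = np.zeros((N, p))
        np.add.at(self.uj, obs_j, X)
        self.sj = np.bincount(obs_j, weights=yy, minlength=N)
        keep = self.nj > 0
        self.nj, self.uj, self.sj = self.nj[keep], self.uj[keep], self.sj[keep]

    def _pieces(self, lam: float):
        c = lam / (1.0 + lam * self.nj)
        A = self.xtx - (self.uj.T * c) @ self.uj
        b = self.xty - self.uj.T @ (c * self.sj)
        yhy = self.yty - float(np.sum(c * self.sj * self.sj))
        logdet_h = float(np.sum(np.log1p(lam * self.nj)))
        return A, b, yhy, logdet_h

    def criterion(self, lam: float) -> float:
        A, b, yhy, logdet_h = self._pieces(lam)
        evals, evecs = np.linalg.eigh(A)
        tol = max(evals.max(), 0) * A.shape[0] * np.finfo(float).eps
        pos = evals > tol
        logdet_a = float(np.sum(np.log(evals[pos])))
        beta = evecs[:, pos] @ ((evecs[:, pos].T @ b) / evals[pos])
        rss = max(yhy - float(b @ beta), 1e-300)
        df = self.n - self.rank
        return logdet_h + logdet_a + df * np.log(rss)

    def components(self, lam: float) -> tuple:
        A, b, yhy, _ = self._pieces(lam)
        beta = np.linalg.lstsq(A, b, rcond=None)[0]
        rss = max(yhy - float(b @ beta), 0.0)
        sigma_e2 = rss / (self.n - self.rank)
        return lam * sigma_e2, sigma_e2


def estimate_rho_mixed(y, design: DesignSpec, protein_id: str = "") -> CorrelationEstimate:
    """REML estimate of the common inter-peptide correlation for one protein.

    ``y`` is the protein's peptide x sample log2 matrix (NaN allowed,
    missing-at-random) in the design's sample order, or a
    :class:`PeptideQuantTable` restricted to that protein.
    """
    mat = _coerce_matrix(y)
    if isinstance(y, PeptideQuantTable):
        design = design.aligned(y.sample_ids)
    m, N = mat.shape
    if m < 2:
        return CorrelationEstimate(protein_id, 0.0, 0.0, np.nan, m, "mixed",
                                   converged=False, flag="m<2: estimation refused")
    D = _design_columns(design, N)
    obs_per_sample = np.sum(~np.isnan(mat), axis=0)
    if (obs_per_sample == 0).any():
        mat = mat[:, obs_per_sample > 0]
        D = D[obs_per_sample > 0]

    if not np.isnan(mat).any():
        sigma_r2, sigma_e2 = _balanced_reml(mat, D)
        rho = sigma_r2 / (sigma_r2 + sigma_e2)
        return CorrelationEstimate(protein_id, float(rho), float(sigma_r2),
                                   float(sigma_e2), m, "mixed")

    prof = _ProfiledREML(mat, D)
    res = minimize_scalar(lambda th: prof.criterion(np.exp(th)),
                          bounds=_LOG_RATIO_BOUNDS, method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    converged = bool(res.success)
    at_zero = prof.criterion(0.0) <= res.fun
    if at_zero or res.x <= _LOG_RATIO_BOUNDS[0] + 1e-6:
        lam, flag = 0.0, "boundary: sigma_r2 at zero"
    elif res.x >= _LOG_RATIO_BOUNDS[1] - 1e-6:
        flag = "boundary: variance ratio at upper bound"
        warnings.warn(f"REML hit the upper ratio bound for {protein_id!r}",
                      UserWarning)
    else:
        flag = ""
    sigma_r2, sigma_e2 = prof.components(lam)
    rho = lam / (1.0 + lam)
    return CorrelationEstimate(protein_id, float(rho), float(sigma_r2),
                               float(sigma_e2), m, "mixed",
                               converged=converged, flag=flag)


def estimate_rho_wu(y, design: DesignSpec | np.ndarray | None = None,
                    protein_id: str = "") -> CorrelationEstimate:
    """Wu–Smyth mean pairwise correlation from standardized residual means.

    Projects the sample design out of each peptide's profile (orthonormal
    residual coordinates), scales each peptide to unit mean square, and
    reads the mean correlation off the variance of the across-peptide mean:
    ``vif = m * mean(colmean^2)``, ``rho = (vif - 1) / (m - 1)``, clamped
    to [0, 1]. Complete data required.
    """
    mat = _coerce_matrix(y)
    if isinstance(y, PeptideQuantTable) and isinstance(design, DesignSpec):
        design = design.aligned(y.sample_ids)
    m, N = mat.shape
    if np.isnan(mat).any():
        raise ValueError("wu estimator does not allow missing values; "
                         "use the mixed-model estimator instead")
    if m < 2:
        return CorrelationEstimate(protein_id, 0.0, np.nan, np.nan, m, "wu",
                                   converged=False, flag="m<2: estimation refused")
    if design is None:
        X = np.ones((N, 1))
    elif isinstance(design, DesignSpec):
        X = _design_columns(design, N)
    else:
        X = np.asarray(design, dtype=float)
    Q, _ = np.linalg.qr(X, mode="complete")
    rank = np.linalg.matrix_rank(X)
    Q2 = Q[:, rank:]
    U = mat @ Q2                       # m x (N - rank) residual coordinates
    msq = np.mean(U * U, axis=1)
    if (msq == 0).any():
        raise ValueError("peptide with zero residual variance; wu estimator "
                         "undefined")
    U = U / np.sqrt(msq)[:, None]
    colmean = U.mean(axis=0)
    vif = m * float(np.mean(colmean * colmean))
    raw = (vif - 1.0) / (m - 1.0)
    rho = min(max(raw, 0.0), 1.0)
    return CorrelationEstimate(protein_id, rho, np.nan, np.nan, m, "wu",
                               flag="clamped to 0" if raw < 0 else "")
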