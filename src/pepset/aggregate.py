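"""Aggregation-based comparator workflows.

Peptides are rolled up into protein abundances either by summing raw
intensities or by robust two-way regression (Huber M-estimation on the
log2 scale), and the protein matrix is then tested with the same OLS +
empirical-Bayes machinery used at the peptide level, optionally with a
log-peptide-count trend on the prior variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import DesignSpec, PeptideQuantTable
from .linmod import fit_peptides, moderate
from .settest import adjust_pvalues

__all__ = [
    "AggregatedProteinTable",
    "aggregate_sum",
    "aggregate_robust",
    "protein_level_test",
]

HUBER_T = 1.345
IRLS_MAXITER = 50
IRLS_TOL = 1e-6


@dataclass
class AggregatedProteinTable:
    """Protein x sample log2 abundance from a peptide rollup."""

    abundance: np.ndarray
    protein_ids: list
    sample_ids: list
    n_peptides: np.ndarray
    method: str
    flags: dict = field(default_factory=dict)

    def as_table(self) -> PeptideQuantTable:
        """View the protein matrix as a quant table (rows map to themselves)."""
        return PeptideQuantTable(
            abundance=self.abundance, peptide_ids=list(self.protein_ids),
            protein_map=[(p,) for p in self.protein_ids],
            sample_ids=self.sample_ids, meta={"aggregation": self.method})


def aggregate_sum(table: PeptideQuantTable) -> AggregatedProteinTable:
    """Summed raw peptide intensity per protein, re-logged.

    Missing cells are skipped; a protein/sample cell with no observed
    peptide stays missing.
    """
    raw = np.power(2.0, table.abundance)
    pidx = table.protein_index()
    proteins = sorted(pidx)
    out = np.full((len(proteins), table.n_samples), np.nan)
    n_pep = np.zeros(len(proteins), dtype=int)
    for r, prot in enumerate(proteins):
        rows = pidx[prot]
        n_pep[r] = len(rows)
        block = raw[rows]
        any_obs = ~np.all(np.isnan(block), axis=0)
        sums = np.nansum(block, axis=0)
        out[r, any_obs] = np.log2(sums[any_obs])
    return AggregatedProteinTable(out, proteins, list(table.sample_ids),
                                  n_pep, "sum")


def _robust_two_way(block: np.ndarray) -> np.ndarray:
    """Huber IRLS fit of log2 abundance ~ peptide + sample for one protein.

    Returns the per-sample protein profile: estimated sample effects
    recentered to the protein's grand mean. Samples with no observed
    peptide stay NaN; on rank deficiency the observed-cell sample means
    are returned instead.
    """
    m, n_s = block.shape
    obs_i, obs_j = np.nonzero(~np.isnan(block))
    y = block[obs_i, obs_j]
    samples_seen = np.unique(obs_j)
    profile = np.full(n_s, np.nan)
    if m == 1:
        profile[samples_seen] = y
        return profile
    # sum-to-zero coding over the peptides/samples actually observed
    pep_codes = {p: k for k, p in enumerate(np.unique(obs_i))}
    smp_codes = {s: k for k, s in enumerate(samples_seen)}
    n_p_eff, n_s_eff = len(pep_codes), len(smp_codes)
    X = np.zeros((len(y), 1 + (n_p_eff - 1) + (n_s_eff - 1)))
    X[:, 0] = 1.0
    for r, (i, j) in enumerate(zip(obs_i, obs_j)):
        pi, sj = pep_codes[i], smp_codes[j]
        if pi < n_p_eff - 1:
            X[r, 1 + pi] = 1.0
        else:
            X[r, 1:n_p_eff] = -1.0
        if sj < n_s_eff - 1:
            X[r, n_p_eff + sj] = 1.0
        else:
            X[r, n_p_eff:] = -1.0
    if np.linalg.matrix_rank(X) < X.shape[1]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(block, axis=0)
        profile[samples_seen] = means[samples_seen]
        return profile
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T))
    fit = rlm.fit(maxiter=IRLS_MAXITER, tol=IRLS_TOL, conv="coefs")
    beta = fit.params
    samp_eff = np.zeros(n_s_eff)
    samp_eff[:n_s_eff - 1] = beta[1 + (n_p_eff - 1):]
    samp_eff[n_s_eff - 1] = -samp_eff[:n_s_eff - 1].sum()
    profile[samples_seen] = beta[0] + samp_eff
    return profile


def aggregate_robust(table: PeptideQuantTable) -> AggregatedProteinTable:
    """Robust-regression rollup (two-way model with Huber weights)."""
    pidx = table.protein_index()
    proteins = sorted(pidx)
    out = np.full((len(proteins), table.n_samples), np.nan)
    n_pep = np.zeros(len(proteins), dtype=int)
    flags = {}
    for r, prot in enumerate(proteins):
        rows = pidx[prot]
        n_pep[r] = len(rows)
        block = table.abundance[rows]
        if np.all(np.isnan(block)):
            flags[prot] = "all missing"
            continue
        profile = _robust_two_way(block)
        out[r] = profile
    return AggregatedProteinTable(out, proteins, list(table.sample_ids),
                                  n_pep, "robust", flags=flags)


def protein_level_test(agg: AggregatedProteinTable, design: DesignSpec,
                       trend: bool = False, adjust: str = "BH") -> pd.DataFrame:
    """Moderated t-test on the aggregated protein matrix.

    ``trend=True`` feeds log(peptide count) to the empirical-Bayes prior
    so peptide-rich proteins get their own prior variance level.
    """
    table = agg.as_table()
    design = design.aligned(table.sample_ids)
    fit = fit_peptides(table, design)
    cov = np.log(agg.n_peptides.astype(float)) if trend else None
    fit = moderate(fit, trend_covariate=cov)
    df = pd.DataFrame({
        "protein": agg.protein_ids,
        "n_peptides": agg.n_peptides,
        "logFC": fit.effect,
        "t": fit.t_mod,
        "p": fit.p,
    })
    df["p_adj"] = adjust_pvalues(df["p"].to_numpy(), method=adjust)
    return df.sort_values(["p", "protein"], kind="stable").reset_index(drop=True)
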