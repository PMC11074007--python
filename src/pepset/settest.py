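"""Competitive peptide set test with a variance inflation factor.

For a protein of interest (POI) the moderated t-statistics of its
peptides (set P) are compared against those of all other peptides
(background Pc) with a two-sided two-sample t-test. Correlation among the
m set peptides inflates the variance of the set mean by
``VIF = 1 + (m - 1) * rho``; the background center and scale may be
robustified (median and 1.4826-scaled MAD). With ``rho = 0`` and the SD
scale the statistic reduces exactly to the ordinary pooled two-sample
t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .correlation import estimate_rho_mixed, estimate_rho_wu
from .io import DesignSpec, PeptideQuantTable
from .linmod import fit_peptides, moderate

__all__ = [
    "ProteinSetResult",
    "MAD_SCALE",
    "scaled_mad",
    "competitive_set_test",
    "adjust_pvalues",
    "run_pepsettest",
    "results_to_frame",
]

#: consistency constant aligning the MAD with the SD under normality,
#: 1 / qnorm(0.75) to four decimals
MAD_SCALE = 1.4826


@dataclass
class ProteinSetResult:
    """Outcome of the competitive set test for one protein."""

    protein_id: str
    m: int
    rho: float
    T_set: float
    df: float
    p: float
    p_adj: float = np.nan
    mean_logFC: float = np.nan
    direction: int = 0
    flag: str = ""


def scaled_mad(values) -> float:
    """Normal-consistent robust scale: ``1.4826 * median(|x - median(x)|)``."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("scaled_mad needs >=2 finite values")
    mad = float(np.median(np.abs(x - np.median(x))))
    if mad == 0.0:
        warnings.warn("MAD is zero (over half the values coincide)", UserWarning)
    return MAD_SCALE * mad


def competitive_set_test(t_stats, set_index, rho: float = 0.0,
                         scale_method: str = "sd") -> ProteinSetResult:
    """Two-sample test of set-mean vs background-mean peptide t-statistics.

    Non-finite t-statistics are excluded from both set and background. The
    background center/scale come from Pc (mean+SD or median+scaled MAD);
    the pooled variance combines the set's sample variance with the
    squared background scale under two-sample pooling, and the set-mean
    variance carries the inflation factor ``VIF/m``.
    """
    if scale_method not in ("sd", "mad"):
        raise ValueError(f"unknown scale_method: {scale_method!r}")
    t = np.asarray(t_stats, dtype=float)
    set_index = np.asarray(set_index, dtype=int)
    if len(set_index) == 0:
        raise ValueError("empty peptide set")
    in_set = np.zeros(len(t), dtype=bool)
    in_set[set_index] = True
    fin = np.isfinite(t)
    tset = t[in_set & fin]
    tbg = t[~in_set & fin]
    m, m2 = len(tset), len(tbg)
    if m == 0:
        raise ValueError("no finite t-statistics in the set")
    if m2 < 2:
        raise ValueError("background needs >=2 finite t-statistics")

    if scale_method == "sd":
        center = float(np.mean(tbg))
        scale2 = float(np.var(tbg, ddof=1))
    else:
        center = float(np.median(tbg))
        scale2 = scaled_mad(tbg) ** 2

    set_mean = float(np.mean(tset))
    s_set2 = float(np.var(tset, ddof=1)) if m >= 2 else 0.0
    pooled = ((m - 1) * s_set2 + (m2 - 1) * scale2) / (m + m2 - 2)
    if pooled <= 0:
        raise ValueError("degenerate inputs: pooled scale of t-statistics is zero")

    rho_eff = max(float(rho), 0.0)
    vif = 1.0 + (m - 1) * rho_eff
    se = math.sqrt(pooled * (vif / m + 1.0 / m2))
    T = (set_mean - center) / se
    df = float(m + m2 - 2)
    p = float(2.0 * stats.t.sf(abs(T), df))
    direction = int(np.sign(set_mean - center))
    return ProteinSetResult(protein_id="", m=m, rho=rho_eff, T_set=float(T),
                            df=df, p=p, direction=direction)


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini–Hochberg / Benjamini–Yekutieli step-up adjustment.

    NaN entries are ignored (and returned as NaN); BY multiplies the BH
    factor by the harmonic number of the number of tests.
    """
    if method not in ("BH", "BY"):
        raise ValueError(f"unknown adjustment method: {method!r}")
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    q = p[mask]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(q)
    if n == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * n / np.arange(1, n + 1)
    if method == "BY":
        ranked *= np.sum(1.0 / np.arange(1, n + 1))
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[mask] = res
    return out


def run_pepsettest(table: PeptideQuantTable, design: DesignSpec,
                   cor_method: str = "mixed", scale_method: str = "mad",
                   adjust: str = "BH") -> list:
    """Full competitive set-test pipeline over every mappable protein.

    Fits per-peptide models, moderates them, estimates per-protein
    correlation (``mixed``, ``wu`` or ``none``), runs the competitive test
    per protein against the rest of the fitted peptidome, adjusts p-values
    across proteins and returns results sorted by (p, accession).
    """
    if cor_method not in ("mixed", "wu", "none"):
        raise ValueError(f"unknown cor_method: {cor_method!r}")
    design = design.aligned(table.sample_ids)
    fit = moderate(fit_peptides(table, design))
    t = fit.t_mod
    finite = np.isfinite(t)
    results = []
    for protein, rows in table.protein_index().items():
        rows_ok = rows[finite[rows]]
        m = len(rows_ok)
        if m == 0:
            continue
        if len(t[finite]) - m < 2:
            continue
        flag = ""
        if m == 1:
            rho, flag = 0.0, "single-peptide set: VIF fixed at 1"
        elif cor_method == "none":
            rho = 0.0
        elif cor_method == "mixed":
            est = estimate_rho_mixed(table.abundance[rows_ok], design,
                                     protein_id=protein)
            rho = est.rho
            flag = est.flag
        else:
            est = estimate_rho_wu(table.abundance[rows_ok], design,
                                  protein_id=protein)
            rho = est.rho
            flag = est.flag
        res = competitive_set_test(t, rows_ok, rho=rho, scale_method=scale_method)
        res.protein_id = protein
        res.mean_logFC = float(np.mean(fit.effect[rows_ok]))
        res.flag = flag
        results.append(res)
    if not results:
        warnings.warn("no testable proteins", UserWarning)
        return results
    p_adj = adjust_pvalues([r.p for r in results], method=adjust)
    for r, a in zip(results, p_adj):
        r.p_adj = float(a)
    results.sort(key=lambda r: (r.p, r.protein_id))
    return results


def results_to_frame(results) -> "pd.DataFrame":
    """Tabulate set-test results (one row per protein, sorted as given)."""
    import pandas as pd

    return pd.DataFrame(
        [{"protein": r.protein_id, "n_peptides": r.m, "rho": r.rho,
          "T": r.T_set, "df": r.df, "p": r.p, "p_adj": r.p_adj,
          "mean_logFC": r.mean_logFC, "direction": r.direction,
          "flag": r.flag} for r in results])
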