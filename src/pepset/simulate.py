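"""Synthetic peptidome generation and the factorial benchmark harness.

Peptidomes are drawn from a block-equicorrelated multivariate normal:
peptide means are standard normal, peptide variances 1, and peptides of
one protein share pairwise correlation ``rho`` (exactly sampled through a
one-factor construction: shared factor sqrt(rho) + independent noise
sqrt(1-rho)). A configurable fraction of proteins is differentially
expressed, half shifted up and half down in the test group.

The harness runs every requested method on identical replicates and
tallies Type I error and power from raw p-values, FDR and TPR from
BH-adjusted ones, with Monte-Carlo standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .aggregate import aggregate_robust, aggregate_sum, protein_level_test
from .io import DesignSpec, PeptideQuantTable
from .settest import results_to_frame, run_pepsettest

__all__ = ["SimConfig", "SimMetrics", "simulate_peptidome", "run_simulation",
           "confusion_metrics", "METHODS"]

METHODS = ("pepsettest_sd", "pepsettest_mad", "sum_limma", "robust_limma")

MIXTURE_PROTEOME = [(1400, 3), (360, 10), (40, 30)]


@dataclass
class SimConfig:
    """One simulation scenario.

    ``proteome`` is a list of ``(n_proteins, peptides_per_protein)``
    blocks; ``n_samples`` is the TOTAL sample count with half per group.
    """

    proteome: list
    rho: float = 0.0
    n_samples: int = 6
    de_fraction: float = 0.0
    effect: float = 0.5
    n_reps: int = 200
    seed: int = 0
    methods: tuple = ("pepsettest_sd",)
    alpha: float = 0.05

    def __post_init__(self):
        self.proteome = [(int(a), int(b)) for a, b in self.proteome]
        if any(a < 1 or b < 1 for a, b in self.proteome):
            raise ValueError("proteome blocks need positive counts")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1) for a positive-definite "
                             "equicorrelation block")
        if self.n_samples < 4 or self.n_samples % 2:
            raise ValueError("n_samples must be an even integer >= 4")
        if not (0.0 <= self.de_fraction <= 0.5):
            raise ValueError("de_fraction must lie in [0, 0.5]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        self.methods = tuple(self.methods)

    @property
    def n_proteins(self) -> int:
        return sum(a for a, _ in self.proteome)

    @property
    def n_peptides(self) -> int:
        return sum(a * b for a, b in self.proteome)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid simulation config: {exc}") from exc

    def to_yaml(self, path) -> None:
        data = {"proteome": [list(b) for b in self.proteome], "rho": self.rho,
                "n_samples": self.n_samples, "de_fraction": self.de_fraction,
                "effect": self.effect, "n_reps": self.n_reps, "seed": self.seed,
                "methods": list(self.methods), "alpha": self.alpha}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SimMetrics:
    """Per-method Type I error / power / FDR / TPR with Monte-Carlo SEs."""

    metrics: dict
    n_reps_used: int
    n_reps_failed: int
    config: SimConfig
    per_replicate: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, vals in self.metrics.items():
            for metric, (value, se) in vals.items():
                rows.append({"method": method, "metric": metric,
                             "value": value, "mc_se": se})
        return pd.DataFrame(rows)


def _protein_layout(config: SimConfig):
    sizes = np.concatenate([np.full(a, b, dtype=int) for a, b in config.proteome])
    protein_of_pep = np.repeat(np.arange(len(sizes)), sizes)
    return sizes, protein_of_pep


def _select_de(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-protein shift direction: 0 null, +1 up, -1 down.

    Selection is stratified across proteome blocks (proportional count per
    block) and split as evenly as possible between up and down shifts.
    """
    J = config.n_proteins
    signs = np.zeros(J, dtype=int)
    if config.de_fraction == 0:
        return signs
    start = 0
    chosen = []
    for n_b, _ in config.proteome:
        k_b = int(round(config.de_fraction * n_b))
        if k_b > 0:
            chosen.append(start + rng.choice(n_b, size=k_b, replace=False))
        start += n_b
    chosen = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    rng.shuffle(chosen)
    half = len(chosen) // 2
    signs[chosen[:half]] = 1
    signs[chosen[half:]] = -1
    return signs


def simulate_peptidome(config: SimConfig, rep_seed) -> tuple:
    """Draw one synthetic peptidome.

    Returns ``(table, design, labels)`` where ``labels`` is a DataFrame
    with per-protein ``de`` flag and shift ``sign``. The test group's mean
    is shifted by ``sign * effect`` for every peptide of a DE protein.
    """
    rng = np.random.default_rng(rep_seed)
    sizes, protein_of_pep = _protein_layout(config)
    J, P, N = len(sizes), int(sizes.sum()), config.n_samples
    half = N // 2

    mu = rng.standard_normal(P)
    factor = rng.standard_normal((J, N))
    noise = rng.standard_normal((P, N))
    rho = config.rho
    y = mu[:, None] + np.sqrt(rho) * factor[protein_of_pep] \
        + np.sqrt(1.0 - rho) * noise

    signs = _select_de(config, rng)
    if signs.any():
        shift = signs[protein_of_pep].astype(float) * config.effect
        y[:, half:] += shift[:, None]

    protein_ids = [f"prot{j:05d}" for j in range(J)]
    table = PeptideQuantTable(
        abundance=y,
        peptide_ids=[f"pep{i:06d}" for i in range(P)],
        protein_map=[(protein_ids[g],) for g in protein_of_pep],
        sample_ids=[f"s{j + 1}" for j in range(N)],
        meta={"simulated": True, "rho": rho})
    design = DesignSpec(sample_ids=list(table.sample_ids),
                        group=np.array(["A"] * half + ["B"] * half, dtype=object),
                        contrast=("B", "A"))
    labels = pd.DataFrame({"protein": protein_ids, "de": signs != 0,
                           "sign": signs})
    return table, design, labels


def _method_pvalues(method: str, table: PeptideQuantTable,
                    design: DesignSpec, trend: bool) -> pd.DataFrame:
    if method == "pepsettest_sd":
        res = results_to_frame(run_pepsettest(table, design, cor_method="mixed",
                                              scale_method="sd"))
    elif method == "pepsettest_mad":
        res = results_to_frame(run_pepsettest(table, design, cor_method="mixed",
                                              scale_method="mad"))
    elif method == "sum_limma":
        res = protein_level_test(aggregate_sum(table), design, trend=trend)
    elif method == "robust_limma":
        res = protein_level_test(aggregate_robust(table), design, trend=trend)
    else:
        raise ValueError(method)
    return res[["protein", "p", "p_adj"]]


def confusion_metrics(calls: np.ndarray, truth: np.ndarray) -> tuple:
    """(fdr, tpr) from boolean call and truth vectors; FDR is 0 with no calls."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    disc = int(calls.sum())
    fp = int((calls & ~truth).sum())
    tp = int((calls & truth).sum())
    fdr = fp / disc if disc > 0 else 0.0
    tpr = tp / int(truth.sum()) if truth.any() else np.nan
    return fdr, tpr


def run_simulation(config: SimConfig, progress: bool = False,
                   keep_reps: bool = False) -> SimMetrics:
    """Run the scenario: every method on identical replicates.

    Replicate seeds are spawned from the master seed with
    ``np.random.SeedSequence(seed).spawn(n_reps)`` so results are
    reproducible and methods see the same data.
    """
    rep_seeds = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    per_rep = {m: [] for m in config.methods}
    trend = len({b for _, b in config.proteome}) > 1
    n_failed = 0
    for r, seq in enumerate(rep_seeds):
        table, design, labels = simulate_peptidome(config, seq)
        truth = labels.set_index("protein")["de"]
        try:
            rep_rows = {}
            for method in config.methods:
                res = _method_pvalues(method, table, design, trend)
                res = res.set_index("protein").reindex(truth.index)
                de = truth.to_numpy()
                raw_call = (res["p"] < config.alpha).to_numpy()
                adj_call = (res["p_adj"] < config.alpha).to_numpy()
                row = {}
                if (~de).any():
                    row["type1"] = float(raw_call[~de].mean())
                if de.any():
                    row["power"] = float(raw_call[de].mean())
                fdr, tpr = confusion_metrics(adj_call, de)
                row["fdr"] = fdr
                if de.any():
                    row["tpr"] = tpr
                rep_rows[method] = row
        except Exception as exc:  # failed replicate: excluded and counted
            n_failed += 1
            warnings.warn(f"replicate {r} failed: {exc}", UserWarning)
            continue
        for method, row in rep_rows.items():
            per_rep[method].append(row)
        if progress and (r + 1) % 10 == 0:
            print(f"  replicate {r + 1}/{config.n_reps}", flush=True)

    metrics = {}
    for method in config.methods:
        rows = pd.DataFrame(per_rep[method])
        vals = {}
        for metric in rows.columns:
            x = rows[metric].to_numpy(float)
            se = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
            vals[metric] = (float(np.mean(x)), se)
        metrics[method] = vals
    per_replicate = ({m: pd.DataFrame(per_rep[m]) for m in config.methods}
                     if keep_reps else {})
    return SimMetrics(metrics=metrics, n_reps_used=config.n_reps - n_failed,
                      n_reps_failed=n_failed, config=config,
                      per_replicate=per_replicate)
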