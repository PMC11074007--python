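import numpy as np
import pytest

from pepset.io import DesignSpec, PeptideQuantTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


def make_design(n_samples, groups=None, contrast=("B", "A"), covariates=None):
    if groups is None:
        half = n_samples // 2
        groups = ["A"] * half + ["B"] * (n_samples - half)
    return DesignSpec(sample_ids=[f"s{i+1}" for i in range(n_samples)],
                      group=np.asarray(groups, dtype=object),
                      contrast=contrast, covariates=covariates)


def make_table(abundance, protein_map=None, peptide_ids=None):
    abundance = np.asarray(abundance, dtype=float)
    n, s = abundance.shape
    if peptide_ids is None:
        peptide_ids = [f"pep{i}" for i in range(n)]
    if protein_map is None:
        protein_map = [("P1",)] * n
    return PeptideQuantTable(abundance=abundance, peptide_ids=peptide_ids,
                             protein_map=protein_map,
                             sample_ids=[f"s{i+1}" for i in range(s)])


@pytest.fixture
def toy_table():
    """6-sample, 8-peptide, 3-protein toy with a strong effect on PB."""
    rng = np.random.default_rng(11)
    y = rng.normal(size=(8, 6)) * 0.3
    y[3:6, 3:] += 2.0  # PB peptides respond in group B
    prots = [("PA",)] * 3 + [("PB",)] * 3 + [("PC",)] * 2
    return make_table(y, protein_map=prots)


@pytest.fixture
def toy_design():
    return make_design(6)


def equicorrelated(rng, m, n, rho, mu=None):
    """Direct one-factor draw of an m-peptide equicorrelated block."""
    u = rng.standard_normal(n)
    y = np.sqrt(rho) * u + np.sqrt(1 - rho) * rng.standard_normal((m, n))
    if mu is not None:
        y = y + np.asarray(mu)[:, None]
    return y
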