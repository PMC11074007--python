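"""Reading, filtering and normalizing peptide quantitation tables.

Tables are wide TSV files (peptides in rows, samples in columns). Two
dialects are supported: ``maxquant`` (MaxQuant ``peptides.txt`` column
conventions) and ``generic`` (user-named id/protein columns plus a common
intensity-column prefix). Intensities are log2-transformed on ingestion;
zero or empty cells become missing values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PeptideQuantTable",
    "DesignSpec",
    "FormatError",
    "IngestionError",
    "read_peptide_table",
    "read_design",
    "filter_missing",
    "normalize_columns",
    "write_table",
    "read_table",
    "CONTAMINANT_PREFIX",
    "REVERSE_PREFIX",
]

CONTAMINANT_PREFIX = "CON__"
REVERSE_PREFIX = "REV__"

_MAXQUANT_DEFAULTS = {"id_col": "Sequence", "protein_col": "Proteins",
                      "intensity_prefix": "Intensity "}
_GENERIC_DEFAULTS = {"id_col": "peptide", "protein_col": "protein",
                     "intensity_prefix": "intensity_"}


class FormatError(ValueError):
    """A required column or structural element is absent from the input."""


class IngestionError(ValueError):
    """The input parses but violates a table invariant (e.g. duplicate ids)."""


@dataclass
class PeptideQuantTable:
    """Log2 peptide abundance matrix with peptide→protein mapping.

    Parameters
    ----------
    abundance
        ``(n_peptides, n_samples)`` float array of log2 intensities;
        ``NaN`` marks missing values.
    peptide_ids
        Unique peptide identifiers, one per row.
    protein_map
        One tuple of protein accessions per peptide (shared peptides map
        to several proteins).
    sample_ids
        Unique sample identifiers, one per column.
    meta
        Free-form provenance recorded by processing steps and written to
        output headers.
    """

    abundance: np.ndarray
    peptide_ids: list
    protein_map: list
    sample_ids: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance, dtype=float)
        self.peptide_ids = list(self.peptide_ids)
        self.protein_map = [tuple(p) if not isinstance(p, str) else (p,)
                            for p in self.protein_map]
        self.sample_ids = list(self.sample_ids)
        n, s = self.abundance.shape
        if len(self.peptide_ids) != n:
            raise IngestionError("peptide_ids length does not match row count")
        if len(self.sample_ids) != s:
            raise IngestionError("sample_ids length does not match column count")
        if len(set(self.peptide_ids)) != n:
            raise IngestionError("duplicate peptide ids")
        if len(set(self.sample_ids)) != s:
            raise IngestionError("duplicate sample ids")
        if len(self.protein_map) != n:
            raise IngestionError("protein_map length does not match row count")
        if any(len(p) == 0 for p in self.protein_map):
            raise IngestionError("every peptide must map to >=1 protein")
        bad = ~(np.isfinite(self.abundance) | np.isnan(self.abundance))
        if bad.any():
            raise IngestionError("abundance contains non-finite sentinel values")

    @property
    def n_peptides(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def protein_index(self) -> dict:
        """Map each protein accession to the row indices of its peptides.

        Shared peptides appear under every protein they map to; within a
        protein, row order of the table is preserved.
        """
        idx: dict = {}
        for i, prots in enumerate(self.protein_map):
            for p in prots:
                idx.setdefault(p, []).append(i)
        return {p: np.asarray(rows, dtype=int) for p, rows in idx.items()}

    def subset_rows(self, rows) -> "PeptideQuantTable":
        rows = np.asarray(rows)
        return PeptideQuantTable(
            abundance=self.abundance[rows],
            peptide_ids=[self.peptide_ids[i] for i in rows],
            protein_map=[self.protein_map[i] for i in rows],
            sample_ids=self.sample_ids,
            meta=dict(self.meta),
        )


@dataclass
class DesignSpec:
    """Two-group sample design with an ordered contrast (test − reference)."""

    sample_ids: list
    group: np.ndarray
    contrast: tuple
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        self.group = np.asarray(self.group, dtype=object)
        if len(self.sample_ids) != len(self.group):
            raise IngestionError("group length does not match sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IngestionError("duplicate sample ids in design")
        levels = set(self.group.tolist())
        if self.contrast is not None:
            test, ref = self.contrast
            if levels != {test, ref}:
                raise IngestionError(
                    f"contrast ({test}, {ref}) requires exactly those two "
                    f"group levels; design has {sorted(map(str, levels))}")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            if len(self.covariates) != len(self.sample_ids):
                raise IngestionError("covariates row count does not match samples")

    def aligned(self, sample_ids: Sequence) -> "DesignSpec":
        """Return a copy whose rows follow ``sample_ids`` order exactly."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise IngestionError(f"samples absent from design: {missing}")
        order = [pos[s] for s in sample_ids]
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[order].reset_index(drop=True)
        return DesignSpec(sample_ids=list(sample_ids),
                          group=self.group[order],
                          contrast=self.contrast,
                          covariates=cov)

    def group_indicator(self) -> np.ndarray:
        """0/1 vector: 1 for the test level of the contrast."""
        test, _ = self.contrast
        return (self.group == test).astype(float)

    def design_matrix(self) -> tuple:
        """Intercept + test-group indicator (+ numeric covariate columns).

        Returns ``(X, effect_col)`` where ``effect_col`` is the index of the
        group-indicator column whose coefficient is the contrast estimate.
        """
        cols = [np.ones(len(self.sample_ids)), self.group_indicator()]
        if self.covariates is not None:
            for c in self.covariates.columns:
                col = self.covariates[c]
                if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                    dummies = pd.get_dummies(col, drop_first=True)
                    for d in dummies.columns:
                        cols.append(dummies[d].to_numpy(dtype=float))
                else:
                    cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols), 1


def _log2_or_nan(values: np.ndarray) -> np.ndarray:
    v = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy(float)
    v = v.reshape(values.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(v > 0, np.log2(np.where(v > 0, v, 1.0)), np.nan)
    return out


def read_peptide_table(path, dialect: str = "generic", id_col: str | None = None,
                       protein_col: str | None = None,
                       intensity_prefix: str | None = None) -> PeptideQuantTable:
    """Read a wide TSV peptide table and return log2 abundances.

    ``maxquant`` dialect defaults to MaxQuant ``peptides.txt`` columns
    (``Sequence``, ``Proteins``, ``Intensity <sample>``) and removes rows
    whose accessions carry the contaminant (``CON__``) or reverse
    (``REV__``) prefixes, or that are flagged in the ``Reverse`` /
    ``Potential contaminant`` columns when present.
    """
    if dialect not in ("maxquant", "generic"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    defaults = _MAXQUANT_DEFAULTS if dialect == "maxquant" else _GENERIC_DEFAULTS
    id_col = id_col or defaults["id_col"]
    protein_col = protein_col or defaults["protein_col"]
    intensity_prefix = intensity_prefix or defaults["intensity_prefix"]

    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "maxquant" and protein_col not in df.columns \
            and "Leading razor protein" in df.columns:
        protein_col = "Leading razor protein"
    for col in (id_col, protein_col):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} not found in {path}")
    int_cols = [c for c in df.columns
                if c.startswith(intensity_prefix) and len(c) > len(intensity_prefix)]
    if not int_cols:
        raise FormatError(
            f"no intensity columns with prefix {intensity_prefix!r} in {path}")

    if dialect == "maxquant":
        keep = np.ones(len(df), dtype=bool)
        prots = df[protein_col].fillna("")
        bad = prots.str.split(";").apply(
            lambda ps: any(p.startswith((CONTAMINANT_PREFIX, REVERSE_PREFIX))
                           for p in ps))
        keep &= ~bad.to_numpy()
        for flag_col in ("Reverse", "Potential contaminant"):
            if flag_col in df.columns:
                keep &= df[flag_col].fillna("") != "+"
        df = df.loc[keep].reset_index(drop=True)

    pep_ids = df[id_col].tolist()
    if len(set(pep_ids)) != len(pep_ids):
        dups = df[id_col][df[id_col].duplicated()].unique()[:5]
        raise IngestionError(f"duplicate peptide ids: {list(dups)}")
    prot_map = [tuple(p for p in str(s).split(";") if p)
                for s in df[protein_col].fillna("")]
    if any(len(p) == 0 for p in prot_map):
        raise IngestionError("peptides with no protein accession present")

    abundance = _log2_or_nan(df[int_cols].to_numpy())
    sample_ids = [c[len(intensity_prefix):] for c in int_cols]
    return PeptideQuantTable(
        abundance=abundance, peptide_ids=pep_ids, protein_map=prot_map,
        sample_ids=sample_ids,
        meta={"source": str(path), "dialect": dialect, "transform": "log2"})


def read_design(path, sample_col: str = "sample", group_col: str = "group",
                contrast: tuple | None = None) -> DesignSpec:
    """Read a design TSV (columns: sample, group, optional covariates)."""
    df = pd.read_csv(path, sep="\t")
    for col in (sample_col, group_col):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} not found in {path}")
    if contrast is None:
        levels = sorted(df[group_col].astype(str).unique())
        if len(levels) != 2:
            raise IngestionError(
                f"design has {len(levels)} group levels; a two-level contrast "
                "must be given explicitly")
        contrast = (levels[1], levels[0])
    extra = [c for c in df.columns if c not in (sample_col, group_col)]
    cov = df[extra] if extra else None
    return DesignSpec(sample_ids=df[sample_col].astype(str).tolist(),
                      group=df[group_col].astype(str).to_numpy(),
                      contrast=contrast, covariates=cov)


def filter_missing(table: PeptideQuantTable, min_frac: float = 0.7) -> PeptideQuantTable:
    """Keep peptides observed in at least ``ceil(min_frac * n_samples)`` samples."""
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must lie in (0, 1]")
    need = math.ceil(min_frac * table.n_samples)
    counts = np.sum(~np.isnan(table.abundance), axis=1)
    rows = np.nonzero(counts >= need)[0]
    if len(rows) == 0:
        warnings.warn("missingness filter removed every peptide", UserWarning)
    out = table.subset_rows(rows)
    out.meta["filter_missing"] = {"min_frac": min_frac, "min_samples": need}
    return out


def normalize_columns(table: PeptideQuantTable,
                      method: str = "median_center") -> PeptideQuantTable:
    """Per-sample normalization of the log2 matrix.

    ``median_center`` subtracts each column's observed median and adds back
    the grand median of all observed values, so column medians coincide.
    ``none`` returns the table unchanged.
    """
    if method == "none":
        return table
    if method != "median_center":
        raise ValueError(f"unknown normalization method: {method!r}")
    a = table.abundance
    n_obs = np.sum(~np.isnan(a), axis=0)
    if (n_obs == 0).any():
        bad = [table.sample_ids[i] for i in np.nonzero(n_obs == 0)[0]]
        raise ValueError(f"samples with no observed values: {bad}")
    col_med = np.nanmedian(a, axis=0)
    grand = np.nanmedian(a)
    out = table.subset_rows(np.arange(table.n_peptides))
    out.abundance = a - col_med[None, :] + grand
    out.meta["normalize"] = {"method": method}
    return out


def write_table(table: PeptideQuantTable, path) -> None:
    """Write a table as TSV with a ``#``-prefixed YAML metadata header."""
    header = yaml.safe_dump(
        {"format": "pepset.PeptideQuantTable", **table.meta},
        sort_keys=False).rstrip("\n")
    df = pd.DataFrame(table.abundance, columns=table.sample_ids)
    df.insert(0, "proteins", [";".join(p) for p in table.protein_map])
    df.insert(0, "peptide", table.peptide_ids)
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> PeptideQuantTable:
    """Read a table written by :func:`write_table`."""
    header_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line[1:].strip("\n").removeprefix(" "))
            else:
                break
    meta = yaml.safe_load("\n".join(header_lines)) or {}
    meta.pop("format", None)
    df = pd.read_csv(path, sep="\t", comment="#")
    sample_ids = [c for c in df.columns if c not in ("peptide", "proteins")]
    return PeptideQuantTable(
        abundance=df[sample_ids].to_numpy(float),
        peptide_ids=df["peptide"].tolist(),
        protein_map=[tuple(s.split(";")) for s in df["proteins"].astype(str)],
        sample_ids=sample_ids, meta=meta)
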