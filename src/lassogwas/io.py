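"""Genotype/phenotype readers and writers and significance-level utilities.

Supported on-disk formats:

* delimited text (CSV): subjects x SNPs, header row of SNP ids, entries in
  {0, 1, 2}; lines starting with '#' are treated as comments;
* PLINK ``.raw`` dialect: whitespace-delimited, six leading metadata columns
  (FID IID PAT MAT SEX PHENOTYPE), then one column per SNP with a
  ``NAME_ALLELE`` header (counted-allele suffix);
* phenotype: a single column of numbers, optional '#' comments.

Missing genotypes are rejected outright — the downstream penalized fits
require complete data, mirroring the contract of existing penalized
regression software — and non-{0,1,2} entries raise a parse error naming
the line and column.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from . import __version__
from .simdata import GenotypeMatrix


class GenotypeParseError(ValueError):
    pass


class MissingGenotypeError(ValueError):
    pass


def provenance_header(config: dict | None = None, seed: int | None = None) -> str:
    """Comment line recording version, config hash, and master seed."""
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return f"# lassogwas v{__version__} config={digest} seed={seed}"


def _validate_genotypes(values: np.ndarray, path, offset_rows: int,
                        offset_cols: int, col_names):
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise MissingGenotypeError(
            f"{path}: missing genotype (NA) at line {i + offset_rows}, column "
            f"{col_names[j]!r}; penalized fits require complete data — impute "
            f"or drop before loading")
    bad = ~np.isin(values, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeParseError(
            f"{path}: genotype value {values[i, j]!r} at line "
            f"{i + offset_rows}, column {col_names[j]!r} is not in {{0,1,2}}")


def _mafs_from_counts(values: np.ndarray) -> np.ndarray:
    freq = values.mean(axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def read_genotypes(path, format: str = "csv") -> GenotypeMatrix:
    """Load an additive-coded genotype matrix from csv or PLINK .raw text."""
    if format == "csv":
        df = pd.read_csv(path, comment="#")
        snp_ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=np.float64)
        _validate_genotypes(values, path, offset_rows=2, offset_cols=1,
                            col_names=snp_ids)
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing_meta = [c for c in meta if c not in df.columns]
        if missing_meta:
            raise GenotypeParseError(
                f"{path}: not a PLINK .raw file (missing columns {missing_meta})")
        snp_cols = [c for c in df.columns if c not in meta]
        # NAME_ALLELE headers: strip the counted-allele suffix
        snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
        values = df[snp_cols].to_numpy(dtype=np.float64)
        _validate_genotypes(values, path, offset_rows=2, offset_cols=7,
                            col_names=snp_cols)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return GenotypeMatrix(values=values, mafs=_mafs_from_counts(values),
                          standardized=False, snp_ids=snp_ids)


def read_phenotype(path) -> np.ndarray:
    """Load a single-column quantitative phenotype."""
    vals = pd.read_csv(path, comment="#", header=None).iloc[:, 0]
    return vals.to_numpy(dtype=np.float64)


def _raw_values(G: GenotypeMatrix) -> np.ndarray:
    if not G.standardized:
        return G.values
    if G.raw_values is None:
        raise ValueError("standardized matrix without retained raw counts "
                         "cannot be written in genotype formats")
    return G.raw_values


def write_genotypes_csv(G: GenotypeMatrix, path, config: dict | None = None,
                        seed: int | None = None):
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        fh.write(",".join(G.snp_ids) + "\n")
        np.savetxt(fh, _raw_values(G), fmt="%.10g", delimiter=",")


def write_genotypes_raw(G: GenotypeMatrix, path,
                        phenotype: np.ndarray | None = None,
                        counted_allele: str = "A"):
    """PLINK .raw dialect (no comment header — the format has none)."""
    n = G.n_subjects
    values = _raw_values(G)
    cols = " ".join(f"{s}_{counted_allele}" for s in G.snp_ids)
    pheno = phenotype if phenotype is not None else np.full(n, -9.0)
    with open(path, "w") as fh:
        fh.write("FID IID PAT MAT SEX PHENOTYPE " + cols + "\n")
        for i in range(n):
            row = " ".join(f"{v:.10g}" for v in values[i])
            fh.write(f"F{i} I{i} 0 0 0 {pheno[i]:.10g} {row}\n")


def write_phenotype(y: np.ndarray, path, config: dict | None = None,
                    seed: int | None = None):
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        np.savetxt(fh, np.asarray(y, dtype=np.float64), fmt="%.10g")


def write_decisions_tsv(frame: pd.DataFrame, path, config: dict | None = None,
                        seed: int | None = None):
    """Result table with a provenance comment line (byte-stable for fixed input)."""
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed) + "\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def adjust_alpha_fwer(alpha: float, p: int) -> float:
    """Bonferroni family-wise level: alpha* = alpha / p."""
    if p < 1:
        raise ValueError(f"need p >= 1 tests, got {p}")
    return alpha / p
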