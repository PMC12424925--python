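"""Tab-separated interchange tables with registered schemas.

Every stage communicates through typed TSV tables; reading checks the header
against the registered schema, names missing columns, and preserves extra
columns with a warning.  Genotypes round-trip as a plain-text dosage table
(individuals x SNPs) with a companion SNP-frequency table.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix
from .errors import ConfigurationError

__all__ = ["SCHEMAS", "write_table", "read_table", "write_genotypes", "read_genotypes"]

SCHEMAS: dict[str, dict] = {
    "estimates": {
        "trait": str, "bin": int, "median_age": float, "n": int,
        "estimate": float, "se": float, "metric": str,
    },
    "scores": {"id": str, "score_name": str, "value": float},
    "case_control": {"disease": str, "bin": int, "id": str, "role": str},
    "visits": {"id": str, "visit": int, "age": float, "trait": str, "value": float},
    "individuals": {"id": str, "sex": int, "baseline_age": float, "censor_age": float},
    "diagnoses": {"id": str, "disease": str, "age_at_diagnosis": float},
    "trends": {
        "label": str, "metric": str, "slope": float, "slope_se": float,
        "rel_change_10yr": float, "rel_change_se": float, "lrt_p": float,
    },
    "attribution": {
        "disease": str, "delta_qrs": float, "delta_prs": float, "delta_h2": float,
        "expected_combined": float, "z": float, "p": float,
    },
    "correlations": {
        "trait": str, "kind": str, "rho_raw": float, "age_gap": float,
        "rho_10yr": float, "se": float, "z": float, "p": float,
    },
}


def _schema(name: str) -> dict:
    if name not in SCHEMAS:
        raise ConfigurationError(f"unknown schema {name!r}; known: {sorted(SCHEMAS)}")
    return SCHEMAS[name]


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    cols = _schema(schema)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{schema} table missing columns: {missing}")
    ordered = list(cols) + [c for c in df.columns if c not in cols]
    df[ordered].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    cols = _schema(schema)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{schema} table at {path} missing columns: {missing}")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        warnings.warn(f"{schema} table has extra columns {extra}; preserved")
    for c, typ in cols.items():
        df[c] = df[c].astype(typ)
    return df


def write_genotypes(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Dosages to <prefix>.dosages.tsv (rows = individuals) and SNP metadata
    to <prefix>.snps.tsv."""
    prefix = Path(prefix)
    dos = pd.DataFrame(
        genotypes.dosages, index=genotypes.individual_ids, columns=genotypes.snp_ids
    )
    dos.index.name = "id"
    dos.to_csv(prefix.with_suffix(".dosages.tsv"), sep="\t")
    pd.DataFrame(
        {"snp_id": genotypes.snp_ids, "allele_freq": genotypes.allele_freqs}
    ).to_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index=False)


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    dos = pd.read_csv(prefix.with_suffix(".dosages.tsv"), sep="\t", index_col="id")
    snps = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    return GenotypeMatrix(
        dosages=dos.to_numpy(dtype=np.int8),
        allele_freqs=snps["allele_freq"].to_numpy(),
        snp_ids=list(dos.columns),
        individual_ids=[str(i) for i in dos.index],
    )
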