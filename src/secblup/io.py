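"""Delimited-text readers and writers for genotypes, phenotypes, kinships,
plot-level records and result tables.

All files are plain CSV/TSV with a header row and a leading id column.
Genotypes are matched by label across files, never by position.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .kinship import MarkerMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
    "read_plot_data",
    "write_plot_data",
    "read_results",
    "write_results",
    "read_config",
]

SYMMETRY_TOL = 1e-8


def _read_table(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    else:
        df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_genotypes(path, sep: str | None = None) -> MarkerMatrix:
    """Read a genotype dosage table (rows = genotypes, columns = SNPs)."""
    df = _read_table(path, sep)
    try:
        dos = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric dosage cell in {path}: {exc}") from exc
    return MarkerMatrix(
        dosages=dos,
        genotype_ids=df.index.to_numpy(dtype=object),
        snp_ids=df.columns.to_numpy(dtype=object),
    )


def write_genotypes(markers: MarkerMatrix, path, sep: str = ",") -> None:
    markers.to_frame().to_csv(path, sep=sep, index_label="genotype")


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    """Read a phenotype table (rows = genotypes, columns = trait names)."""
    df = _read_table(path, sep)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric phenotype column {col!r} in {path}")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path, sep: str = ",") -> None:
    phenotypes.to_csv(path, sep=sep, index_label="genotype")


def read_kinship(path, sep: str | None = None, tol: float = SYMMETRY_TOL) -> pd.DataFrame:
    """Read a square labeled kinship matrix; enforce symmetry up to ``tol``."""
    df = _read_table(path, sep)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1] or not (df.index == df.columns).all():
        raise ValueError(f"kinship in {path} is not square with matching labels")
    k = df.to_numpy(dtype=float)
    asym = np.max(np.abs(k - k.T)) if len(k) else 0.0
    if asym > tol:
        raise ValueError(
            f"kinship in {path} is asymmetric beyond tolerance ({asym:.3g} > {tol:g})"
        )
    return df


def write_kinship(K: pd.DataFrame, path, sep: str = ",") -> None:
    K.to_csv(path, sep=sep, index_label="genotype")


def read_plot_data(path, sep: str | None = None) -> pd.DataFrame:
    """Read plot-level replicated records: genotype, rep, then trait columns."""
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=sep)
    required = {"genotype", "rep"}
    if not required.issubset(df.columns):
        raise ValueError(f"plot-level file {path} must have columns {sorted(required)}")
    df["genotype"] = df["genotype"].astype(str)
    return df


def write_plot_data(plots: pd.DataFrame, path, sep: str = ",") -> None:
    plots.to_csv(path, sep=sep, index=False)


RESULT_COLUMNS = [
    "method",
    "scenario",
    "lambda_causal",
    "rho_G",
    "rho_E",
    "replicate",
    "accuracy",
]


def read_results(path, sep: str | None = None) -> pd.DataFrame:
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=sep)


def write_results(results: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a long-format results table with a stable column order."""
    lead = [c for c in RESULT_COLUMNS if c in results.columns]
    rest = [c for c in results.columns if c not in lead]
    results[lead + rest].to_csv(path, sep=sep, index=False)


def read_config(path) -> dict:
    """Run configuration in YAML (or JSON, a YAML subset)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def check_ids_covered(phenotypes: pd.DataFrame, kinship: pd.DataFrame) -> None:
    """Raise if a phenotyped genotype is absent from the kinship, naming it."""
    missing = [g for g in phenotypes.index if g not in kinship.index]
    if missing:
        raise ValueError(
            f"genotypes present in phenotypes but absent from kinship: {missing}"
        )


def fit_to_json(fit, path=None) -> str:
    """Serialize a fitted variance-component object to JSON for audit logs."""
    payload = {}
    for key, val in vars(fit).items():
        if isinstance(val, np.ndarray):
            payload[key] = val.tolist()
        elif isinstance(val, (np.floating, np.integer)):
            payload[key] = val.item()
        elif isinstance(val, (str, int, float, bool, list, type(None))):
            payload[key] = val
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
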