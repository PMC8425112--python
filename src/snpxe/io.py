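"""Readers and writers for subject tables and result files.

Subject tables are plain pandas DataFrames read from CSV/TSV (header
required) or PLINK .raw dosage exports; results are written as TSV
with p-values in 3-significant-digit scientific notation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("snpxe")

__all__ = ["read_table", "write_batch_tsv", "write_allfits_tsv", "format_pvalue"]

_NA_TOKENS = ["", "NA", ".", "NaN", "nan"]

_PLINK_FIXED = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".raw":
        return "plink_raw"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format= explicitly")


def _check_header(path: Path, sep: str) -> None:
    import csv as _csv

    with open(path, newline="") as fh:
        reader = _csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path.name}: empty file (header required)") from None
    dupes = [c for c in header if header.count(c) > 1]
    if dupes:
        raise ValueError(f"{path.name}: duplicate header columns at line 1: {sorted(set(dupes))}")


def read_table(path, format: str | None = None) -> pd.DataFrame:
    """Load a subject table from CSV, TSV, or PLINK .raw.

    Missing-value tokens ("", "NA", ".") are normalized to NaN.  PLINK
    .raw files are whitespace-delimited with the six fixed columns
    FID/IID/PAT/MAT/SEX/PHENOTYPE followed by 0/1/2 dosage columns;
    the dosage column names keep their ``SNP_allele`` form.  Logs a
    load report (rows, missing counts).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        _check_header(path, sep)
        df = pd.read_csv(path, sep=sep, na_values=_NA_TOKENS, keep_default_na=True)
    elif fmt == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", na_values=_NA_TOKENS, keep_default_na=True)
        missing_fixed = [c for c in _PLINK_FIXED if c not in df.columns]
        if missing_fixed:
            raise ValueError(
                f"{path.name}: not a PLINK .raw file (missing header columns {missing_fixed})"
            )
    else:
        raise ValueError(f"unknown format {fmt!r}; use csv, tsv or plink_raw")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path.name}: duplicate header columns {dupes}")
    n_missing = int(df.isna().sum().sum())
    logger.info("loaded %s: %d rows, %d columns, %d missing values",
                path.name, len(df), df.shape[1], n_missing)
    return df


def format_pvalue(p) -> str:
    """Scientific notation with 3 significant digits, e.g. 3.60e-04."""
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "NA"
    return f"{p:.2e}"


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_batch_tsv(batch, path) -> None:
    """Write the per-pair summary table with selection metadata."""
    df = batch.table.copy()
    for col in ("p_SNPiv", "p_int"):
        df[col] = df[col].map(format_pvalue)
    df["MAF"] = df["MAF"].map(lambda v: _fmt(round(v, 6)) if v is not None else "NA")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    meta = {
        "alpha": batch.alpha,
        "alpha_corrected": batch.alpha_corrected,
        "m_tests": batch.m_tests,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def write_allfits_tsv(pair, path) -> None:
    """Write the long per-pattern table (one row per fitted pattern)."""
    df = pair.to_frame()
    df["p_int"] = df["p_int"].map(format_pvalue)
    df["bic"] = df["bic"].map(_fmt)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
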