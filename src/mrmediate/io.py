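"""Reading and writing GWAS summary statistics and LD matrices.

Files are delimited text with a header; both tab- and general
whitespace-delimited layouts are accepted. Consortium headers vary, so
columns are resolved through a caller-supplied ``column_map`` falling back
to a catalogue of common aliases (SNP/rsid, chr, pos, effect_allele/EA,
other_allele/OA, eaf, beta, se, pval/p, n).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    SUMSTATS_COLUMNS,
    VALID_ALLELES,
    LDMatrix,
    SummaryStatsTable,
)
from .errors import ConfigurationError, InputError

#: Column aliases recognised without an explicit ``column_map`` (lower-cased).
DEFAULT_COLUMN_ALIASES: dict[str, list[str]] = {
    "snp_id": ["snp_id", "snp", "rsid", "rs_id", "variant_id", "markername", "id"],
    "chrom": ["chrom", "chr", "chromosome"],
    "pos": ["pos", "position", "bp", "base_pair_location"],
    "effect_allele": ["effect_allele", "ea", "a1", "allele1", "alt"],
    "other_allele": ["other_allele", "oa", "a2", "allele2", "non_effect_allele", "ref"],
    "eaf": ["eaf", "effect_allele_frequency", "freq", "af", "frq"],
    "beta": ["beta", "effect", "b", "beta_hat"],
    "se": ["se", "standard_error", "stderr", "sebeta"],
    "pval": ["pval", "p", "p_value", "pvalue", "p_val"],
    "n": ["n", "sample_size", "samplesize", "n_total"],
}

MANDATORY_FIELDS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]


def _resolve_columns(header: list[str], column_map: dict[str, str] | None) -> dict[str, str]:
    """Map canonical field names to file column names."""
    resolved: dict[str, str] = {}
    lower = {c.lower(): c for c in header}
    column_map = column_map or {}
    for fld in SUMSTATS_COLUMNS:
        if fld in column_map:
            col = column_map[fld]
            if col not in header:
                raise ConfigurationError(
                    f"column_map maps {fld!r} to {col!r}, which is not in the header {header}"
                )
            resolved[fld] = col
            continue
        for alias in DEFAULT_COLUMN_ALIASES[fld]:
            if alias in lower:
                resolved[fld] = lower[alias]
                break
    missing = [f for f in MANDATORY_FIELDS if f not in resolved]
    if missing:
        raise ConfigurationError(
            f"cannot resolve mandatory columns {missing}; supply a column_map"
        )
    return resolved


def read_summary_stats(
    path,
    column_map: dict[str, str] | None = None,
    trait_id: str = "trait",
    trait_role: str = "exposure",
) -> SummaryStatsTable:
    """Read one trait's GWAS summary statistics from delimited text.

    Rows that fail field parsing or violate per-SNP invariants (non-positive
    SE, p-value outside (0, 1], allele not a single A/C/G/T base, eaf outside
    (0, 1)) are dropped and counted in ``provenance["read_log"]``. Alleles
    are upper-cased. ``eaf`` and ``n`` are optional columns.

    Raises
    ------
    ConfigurationError
        If a mandatory column cannot be resolved.
    InputError
        If no row survives parsing.
    """
    try:
        raw = pd.read_csv(path, sep=None, engine="python", comment="#")
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read summary statistics from {path}: {exc}") from exc
    resolved = _resolve_columns(list(raw.columns), column_map)

    df = pd.DataFrame(index=raw.index)
    df["snp_id"] = raw[resolved["snp_id"]].astype(str)
    df["chrom"] = raw[resolved["chrom"]].astype(str) if "chrom" in resolved else "0"
    df["pos"] = (
        pd.to_numeric(raw[resolved["pos"]], errors="coerce") if "pos" in resolved else 0
    )
    df["effect_allele"] = raw[resolved["effect_allele"]].astype(str).str.upper()
    df["other_allele"] = raw[resolved["other_allele"]].astype(str).str.upper()
    df["eaf"] = (
        pd.to_numeric(raw[resolved["eaf"]], errors="coerce") if "eaf" in resolved else np.nan
    )
    for fld in ("beta", "se", "pval"):
        df[fld] = pd.to_numeric(raw[resolved[fld]], errors="coerce")
    df["n"] = pd.to_numeric(raw[resolved["n"]], errors="coerce") if "n" in resolved else np.nan

    n_input = len(df)
    drop_reasons: dict[str, int] = {}

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        k = int(mask.sum())
        if k:
            drop_reasons[reason] = drop_reasons.get(reason, 0) + k
            df = df[~mask]

    _drop(df["beta"].isna() | df["se"].isna() | df["pval"].isna(), "unparseable numeric field")
    _drop(~df["effect_allele"].isin(VALID_ALLELES), "effect allele not a single A/C/G/T base")
    _drop(~df["other_allele"].isin(VALID_ALLELES), "other allele not a single A/C/G/T base")
    _drop(df["effect_allele"] == df["other_allele"], "identical alleles")
    _drop(~(df["se"] > 0), "se not > 0")
    _drop(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval outside (0, 1]")
    _drop(df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1)), "eaf outside (0, 1)")
    _drop(df["n"].notna() & ~(df["n"] > 0), "n not positive")
    _drop(df["snp_id"].duplicated(), "duplicated snp_id")

    if len(df) == 0:
        raise InputError(f"zero parseable rows in {path}")

    df["pos"] = df["pos"].fillna(0).astype("int64")
    df["n"] = df["n"].round().astype("Int64")
    df = df.reset_index(drop=True)
    log = {
        "n_input_rows": n_input,
        "n_kept": len(df),
        "n_dropped": n_input - len(df),
        "drop_reasons": drop_reasons,
    }
    return SummaryStatsTable(trait_id, trait_role, df, {"read_log": log})


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table as tab-delimited text with canonical column names.

    Missing ``eaf``/``n`` values are emitted as ``NA``. Reading the file back
    with :func:`read_summary_stats` reproduces the table field-for-field.
    """
    if table.n_snps == 0:
        raise InputError("refusing to write a table with no records")
    out = table.data.copy()
    try:
        out.to_csv(path, sep="\t", index=False, na_rep="NA")
    except OSError as exc:
        raise InputError(f"cannot write summary statistics to {path}: {exc}") from exc


def read_ld_matrix(path) -> LDMatrix:
    """Read a labelled square LD r-squared matrix from delimited text.

    Row and column labels must agree. Asymmetries up to 1e-8 are averaged
    away; larger ones are an error, as are entries outside [0, 1] or a
    diagonal departing from 1 by more than 1e-8.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read LD matrix from {path}: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise InputError(f"LD matrix must be square, got shape {df.shape}")
    rows = [str(s) for s in df.index]
    cols = [str(s) for s in df.columns]
    if rows != cols:
        raise InputError("LD matrix row and column labels disagree")
    mat = df.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise InputError("LD matrix contains unparseable entries")
    if mat.min() < 0 or mat.max() > 1:
        raise InputError("LD matrix entries must lie in [0, 1]")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise InputError("LD matrix asymmetric beyond 1e-8")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise InputError("LD matrix diagonal departs from 1 beyond 1e-8")
    return LDMatrix(snp_ids=rows, r2=mat)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    """Write an LD matrix as tab-delimited text with SNP-ID labels."""
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")
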