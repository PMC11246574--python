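"""Core data containers for two-sample Mendelian randomization.

The universal input currency is a :class:`SummaryStatsTable`: one trait's GWAS
summary statistics (per-SNP effect estimates, standard errors, p-values,
allele metadata). Instrument selection and harmonization turn one or more
exposure tables plus an outcome table into a :class:`HarmonizedDataset`,
the direct input of every MR estimator: SNP-exposure effects gamma (J x K),
SNP-outcome effects Gamma (length J), and their standard errors, all expressed
on a common effect-allele orientation.

Tables are pandas-backed; the canonical column order is
``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se, pval, n``.
``eaf`` and ``n`` may be missing (NA).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
VALID_ROLES = frozenset({"exposure", "mediator", "outcome"})

#: Canonical column order of a summary-statistics table.
SUMSTATS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of the ``effect_allele`` on the trait
    (trait units, or SD for a standardized trait); ``eaf`` is the
    effect-allele frequency and may be missing (``None``); coordinates are
    1-based.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None


@dataclass
class ValidationIssue:
    """A single invariant violation found in a table."""

    snp_id: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.snp_id}: {self.field}: {self.message}"


@dataclass
class SummaryStatsTable:
    """GWAS summary statistics for one trait.

    Parameters
    ----------
    trait_id : str
        Identifier of the trait (e.g. a GWAS accession or a short name).
    trait_role : {"exposure", "mediator", "outcome"}
        Role the trait plays in the analysis.
    data : pandas.DataFrame
        One row per SNP, columns :data:`SUMSTATS_COLUMNS`.
    provenance : dict
        Free-form log of how the table was produced (rows dropped at read
        time, filters applied, removals with reasons).
    """

    trait_id: str
    trait_role: str
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_role not in VALID_ROLES:
            raise ValueError(
                f"trait_role must be one of {sorted(VALID_ROLES)}, got {self.trait_role!r}"
            )
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"summary statistics table missing columns: {missing}")
        self.data = self.data[SUMSTATS_COLUMNS].reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    @property
    def snp_ids(self) -> list[str]:
        return self.data["snp_id"].tolist()

    def subset(self, snp_ids, provenance_note: str | None = None) -> "SummaryStatsTable":
        """Return a new table restricted to ``snp_ids`` (original row order)."""
        keep = self.data["snp_id"].isin(set(snp_ids))
        prov = dict(self.provenance)
        if provenance_note is not None:
            prov[provenance_note] = int((~keep).sum())
        return SummaryStatsTable(self.trait_id, self.trait_role, self.data[keep].copy(), prov)

    def iter_records(self) -> Iterator[SnpAssociation]:
        for row in self.data.itertuples(index=False):
            yield SnpAssociation(
                snp_id=row.snp_id,
                chrom=str(row.chrom),
                pos=int(row.pos) if pd.notna(row.pos) else 0,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=None if pd.isna(row.n) else int(row.n),
            )


def validate_summary_stats(table: SummaryStatsTable) -> list[ValidationIssue]:
    """Check every table invariant; return one issue per violation.

    The report is empty iff the table is valid. Purely a reporting
    operation: the table is never modified (and repeated calls return the
    same report).
    """
    issues: list[ValidationIssue] = []
    df = table.data

    dup = df["snp_id"][df["snp_id"].duplicated()]
    for snp in dup.unique():
        issues.append(ValidationIssue(str(snp), "snp_id", "duplicated snp_id"))

    for row in df.itertuples(index=False):
        snp = str(row.snp_id)
        if row.effect_allele not in VALID_ALLELES:
            issues.append(ValidationIssue(snp, "effect_allele", f"invalid allele {row.effect_allele!r}"))
        if row.other_allele not in VALID_ALLELES:
            issues.append(ValidationIssue(snp, "other_allele", f"invalid allele {row.other_allele!r}"))
        if row.effect_allele == row.other_allele:
            issues.append(ValidationIssue(snp, "other_allele", "effect and other allele identical"))
        if not pd.isna(row.eaf) and not (0.0 < row.eaf < 1.0):
            issues.append(ValidationIssue(snp, "eaf", f"eaf {row.eaf} outside (0, 1)"))
        if not (row.se > 0):
            issues.append(ValidationIssue(snp, "se", f"se {row.se} not > 0"))
        if not (0.0 < row.pval <= 1.0):
            issues.append(ValidationIssue(snp, "pval", f"pval {row.pval} outside (0, 1]"))
        if not pd.isna(row.n) and not (row.n > 0):
            issues.append(ValidationIssue(snp, "n", f"n {row.n} not positive"))
    return issues


@dataclass
class LDMatrix:
    """Pairwise linkage-disequilibrium r-squared between a set of SNPs.

    ``r2`` is square and symmetric with unit diagonal, entries in [0, 1].
    ``positions`` optionally carries per-SNP (chrom, pos) pairs; physical
    window checks during clumping use the summary-statistics table's own
    coordinates, so positions here are informational.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        J = len(self.snp_ids)
        if self.r2.shape != (J, J):
            raise ValueError(f"r2 must be {J}x{J}, got {self.r2.shape}")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValueError("r2 entries must lie in [0, 1]")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 must be symmetric (within 1e-8)")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        # normalize: exact symmetry and exact unit diagonal
        self.r2 = (self.r2 + self.r2.T) / 2.0
        np.fill_diagonal(self.r2, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        if len(self._index) != J:
            raise ValueError("snp_ids must be unique")

    def lookup(self, snp_a: str, snp_b: str) -> float | None:
        """r2 between two SNPs, or None if either is absent."""
        ia = self._index.get(snp_a)
        ib = self._index.get(snp_b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


@dataclass
class HarmonizedDataset:
    """SNP-aligned effect matrices on a common effect-allele orientation.

    gamma (``exposure_betas``, J x K) and Gamma (``outcome_betas``, length J)
    with their standard errors; no missing values are allowed. Column k of
    the exposure matrix corresponds to ``exposure_ids[k]``; the first
    exposure defines the allele orientation. ``orientation_log`` records the
    per-SNP harmonization actions (kept/flipped/dropped, with reasons).
    """

    snp_ids: list[str]
    exposure_betas: np.ndarray
    exposure_ses: np.ndarray
    outcome_betas: np.ndarray
    outcome_ses: np.ndarray
    exposure_ids: list[str] = field(default_factory=lambda: ["exposure"])
    outcome_id: str = "outcome"
    orientation_log: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, dtype=float))
        if self.exposure_betas.shape[0] == 1 and len(self.snp_ids) > 1:
            self.exposure_betas = self.exposure_betas.T
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, dtype=float))
        if self.exposure_ses.shape[0] == 1 and len(self.snp_ids) > 1:
            self.exposure_ses = self.exposure_ses.T
        self.outcome_betas = np.asarray(self.outcome_betas, dtype=float).ravel()
        self.outcome_ses = np.asarray(self.outcome_ses, dtype=float).ravel()

        J = len(self.snp_ids)
        if J < 1:
            raise ValueError("HarmonizedDataset needs at least one SNP")
        if len(set(self.snp_ids)) != J:
            raise ValueError("snp_ids must be unique")
        if self.exposure_betas.shape[0] != J or self.outcome_betas.shape[0] != J:
            raise ValueError("effect arrays must have one row per SNP")
        if self.exposure_ses.shape != self.exposure_betas.shape:
            raise ValueError("exposure_ses must match exposure_betas in shape")
        if self.outcome_ses.shape != self.outcome_betas.shape:
            raise ValueError("outcome_ses must match outcome_betas in shape")
        if len(self.exposure_ids) != self.exposure_betas.shape[1]:
            raise ValueError("exposure_ids must name each exposure column")
        arrays = [self.exposure_betas, self.exposure_ses, self.outcome_betas, self.outcome_ses]
        if any(np.isnan(a).any() for a in arrays):
            raise ValueError("harmonized data may not contain missing values")
        if np.any(self.exposure_ses <= 0) or np.any(self.outcome_ses <= 0):
            raise ValueError("all standard errors must be > 0")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.exposure_betas.shape[1]

    def single_exposure(self) -> tuple[np.ndarray, np.ndarray]:
        """(gamma, se_gamma) for a K=1 dataset; error otherwise."""
        if self.n_exposures != 1:
            raise ValueError(
                f"operation requires a single-exposure dataset, got K={self.n_exposures}"
            )
        return self.exposure_betas[:, 0], self.exposure_ses[:, 0]
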