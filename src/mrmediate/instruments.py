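"""Genetic-instrument selection, pruning, harmonization and strength.

The selection pipeline mirrors standard two-sample MR practice: keep SNPs
below a genome-wide significance threshold (5e-8, with 5e-6 as the
documented relaxed fallback), greedily clump to mutual LD independence
(r2 < 0.001 within a 10,000 kb window, lowest p-value wins), remove SNPs on
a confounder blocklist (a local stand-in for PhenoScanner look-ups), then
quantify strength with per-SNP and overall R^2/F statistics where F > 10 is
the conventional weak-instrument screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import HarmonizedDataset, LDMatrix, SummaryStatsTable
from .errors import ConfigurationError, InputError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


@dataclass
class InstrumentStrength:
    """Variance explained and F statistics for a set of instruments.

    ``method_note`` records, per SNP, whether R^2 came from the
    allele-frequency formula (``eaf``) or from the z-score fallback
    (``zscore_fallback``) used when eaf is missing.
    """

    per_snp_r2: np.ndarray
    per_snp_f: np.ndarray
    overall_r2: float
    overall_f: float
    n_used: int
    method_note: list[str]


def select_by_pvalue(table: SummaryStatsTable, threshold: float) -> SummaryStatsTable:
    """Keep SNPs with p-value strictly below ``threshold`` (order preserved)."""
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"p-value threshold must lie in (0, 1), got {threshold}")
    keep = table.data["pval"] < threshold
    if not keep.any():
        raise InputError(
            f"no SNP passes p < {threshold:g} for trait {table.trait_id!r}; "
            "consider the relaxed threshold 5e-6 used when few SNPs reach "
            "genome-wide significance"
        )
    out = table.data[keep].reset_index(drop=True)
    prov = dict(table.provenance)
    prov["pvalue_selection"] = {
        "threshold": threshold,
        "kept": int(keep.sum()),
        "total": len(keep),
    }
    return SummaryStatsTable(table.trait_id, table.trait_role, out, prov)


def ld_clump(
    table: SummaryStatsTable,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> SummaryStatsTable:
    """Greedy LD clumping: retain mutually independent SNPs, best p first.

    SNPs are visited in order of ascending p-value (ties broken by snp_id for
    determinism); each accepted SNP discards every not-yet-accepted SNP that
    is correlated above ``r2_threshold`` AND lies within ``window_kb`` on the
    same chromosome. SNPs absent from the LD matrix are treated as unlinked,
    with a warning. The returned table preserves the original row order.
    """
    if not (0.0 <= r2_threshold <= 1.0):
        raise ConfigurationError(f"r2_threshold must lie in [0, 1], got {r2_threshold}")
    df = table.data
    missing = [s for s in df["snp_id"] if s not in ld._index]
    if missing:
        warnings.warn(
            f"{len(missing)} SNPs absent from the LD matrix are treated as unlinked",
            stacklevel=2,
        )

    order = df[["snp_id", "pval", "chrom", "pos"]].sort_values(
        ["pval", "snp_id"], kind="mergesort"
    )
    window_bp = window_kb * 1000
    accepted: list[str] = []
    discarded: set[str] = set()
    info = {r.snp_id: (str(r.chrom), int(r.pos)) for r in order.itertuples(index=False)}

    for row in order.itertuples(index=False):
        if row.snp_id in discarded:
            continue
        accepted.append(row.snp_id)
        chrom_a, pos_a = info[row.snp_id]
        for other in order["snp_id"]:
            if other == row.snp_id or other in discarded or other in accepted:
                continue
            chrom_b, pos_b = info[other]
            if chrom_b != chrom_a or abs(pos_b - pos_a) > window_bp:
                continue
            r2 = ld.lookup(row.snp_id, other)
            if r2 is not None and r2 > r2_threshold:
                discarded.add(other)

    # post-hoc independence assertion on every call
    for i, a in enumerate(accepted):
        for b in accepted[i + 1 :]:
            r2 = ld.lookup(a, b)
            if r2 is not None and r2 > r2_threshold:
                ca, pa = info[a]
                cb, pb = info[b]
                assert not (ca == cb and abs(pa - pb) <= window_bp), (
                    f"clumping invariant violated for {a}, {b}"
                )

    prov = dict(table.provenance)
    prov["ld_clump"] = {
        "r2_threshold": r2_threshold,
        "window_kb": window_kb,
        "kept": len(accepted),
        "total": table.n_snps,
    }
    keep = df["snp_id"].isin(set(accepted))
    return SummaryStatsTable(table.trait_id, table.trait_role, df[keep].copy(), prov)


def apply_blocklist(table: SummaryStatsTable, blocklist_path) -> SummaryStatsTable:
    """Remove confounder-associated SNPs listed in a local blocklist file.

    The file holds one ``snp_id [reason...]`` entry per line (delimiter:
    whitespace or tab; ``#`` comments and an optional ``snp_id`` header are
    ignored). Each removal is logged with its reason; listed SNPs absent
    from the table are counted as not found. An empty blocklist is a no-op.
    """
    entries: list[tuple[str, str]] = []
    try:
        with open(blocklist_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                if parts[0].lower() in {"snp_id", "snp", "rsid"}:
                    continue
                entries.append((parts[0], parts[1].strip() if len(parts) > 1 else "unspecified"))
    except OSError as exc:
        raise InputError(f"cannot read blocklist {blocklist_path}: {exc}") from exc

    present = set(table.snp_ids)
    removals = [(snp, reason) for snp, reason in entries if snp in present]
    not_found = [snp for snp, _ in entries if snp not in present]
    remove_ids = {snp for snp, _ in removals}
    keep = ~table.data["snp_id"].isin(remove_ids)
    prov = dict(table.provenance)
    prov["blocklist"] = {
        "removed": [{"snp_id": s, "reason": r} for s, r in removals],
        "not_found": len(not_found),
    }
    return SummaryStatsTable(table.trait_id, table.trait_role, table.data[keep].copy(), prov)


def compute_instrument_strength(table: SummaryStatsTable) -> InstrumentStrength:
    """Per-SNP and overall R^2 / F statistics for a set of instruments.

    With the effect-allele frequency available, the variance explained by
    SNP j on a standardized trait is ``R2_j = 2 * eaf * (1 - eaf) * beta^2``
    and ``F_j = (n - 2) * R2_j / (1 - R2_j)``. Without eaf the z-score
    fallback is used: ``F_j = (beta / se)^2`` and
    ``R2_j = F_j / (F_j + n - 2)`` (flagged in ``method_note``). Overall,
    with k instruments, ``R2 = sum R2_j`` and
    ``F = ((n - k - 1) / k) * R2 / (1 - R2)``. ``n_used`` is the median
    per-SNP sample size.
    """
    df = table.data
    if df["n"].isna().any():
        raise InputError("instrument strength requires a sample size n for every SNP")
    k = len(df)
    n_used = int(np.median(df["n"].astype(float)))
    if n_used <= k + 1:
        raise InputError(
            f"insufficient sample size for overall F (n={n_used} <= k+1={k + 1})"
        )

    r2 = np.empty(k)
    f = np.empty(k)
    notes: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        n_i = float(row.n)
        if pd.notna(row.eaf):
            r2_i = 2.0 * row.eaf * (1.0 - row.eaf) * row.beta**2
            r2_i = min(r2_i, 1.0 - 1e-12)
            f_i = (n_i - 2.0) * r2_i / (1.0 - r2_i)
            notes.append("eaf")
        else:
            f_i = (row.beta / row.se) ** 2
            r2_i = f_i / (f_i + n_i - 2.0)
            notes.append("zscore_fallback")
        r2[i] = r2_i
        f[i] = f_i

    overall_r2 = float(min(r2.sum(), 1.0 - 1e-12))
    overall_f = float((n_used - k - 1) / k * overall_r2 / (1.0 - overall_r2))
    return InstrumentStrength(
        per_snp_r2=r2,
        per_snp_f=f,
        overall_r2=overall_r2,
        overall_f=overall_f,
        n_used=n_used,
        method_note=notes,
    )


def _align_to_reference(
    ref_ea: str,
    ref_oa: str,
    ref_eaf: float | None,
    ea: str,
    oa: str,
    eaf: float | None,
    palindrome_policy: str,
    eaf_ambiguity: float,
) -> tuple[float, str] | tuple[None, str]:
    """Orientation factor (+1/-1) of one record against the reference alleles,
    or (None, reason) when the SNP must be dropped."""
    if _is_palindromic(ref_ea, ref_oa):
        if palindrome_policy == "drop_all":
            return None, "palindromic SNP (drop_all policy)"
        if ref_eaf is None or eaf is None or pd.isna(ref_eaf) or pd.isna(eaf):
            return None, "ambiguous palindrome (missing eaf)"
        half = 0.5
        if abs(ref_eaf - half) <= eaf_ambiguity or abs(eaf - half) <= eaf_ambiguity:
            return None, "ambiguous palindrome"
        if {ea, oa} != {ref_ea, ref_oa}:
            return None, "allele mismatch"
        # allele labels cannot resolve strand for palindromes; frequency can
        if (ref_eaf < half) == (eaf < half):
            return 1.0, "palindrome aligned by eaf"
        return -1.0, "palindrome flipped by eaf"

    if (ea, oa) == (ref_ea, ref_oa):
        return 1.0, "aligned"
    if (ea, oa) == (ref_oa, ref_ea):
        return -1.0, "alleles swapped: beta sign flipped"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return 1.0, "strand complemented"
    if (cea, coa) == (ref_oa, ref_ea):
        return -1.0, "strand complemented and flipped"
    return None, "allele mismatch"


def harmonize(
    exposures: SummaryStatsTable | list[SummaryStatsTable],
    outcome: SummaryStatsTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity: float = 0.08,
) -> HarmonizedDataset:
    """Align exposure and outcome effect alleles onto a common orientation.

    The first exposure defines the reference orientation. For every SNP
    shared by all tables: swapped alleles flip the beta sign (and eaf);
    strand-complemented alleles are complemented then aligned; palindromic
    (A/T or C/G) SNPs are dropped under ``drop_all``, or aligned by allele
    frequency under ``infer_by_eaf`` unless either frequency lies within
    ``eaf_ambiguity`` of 0.5; irreconcilable alleles drop the SNP. Every
    action is recorded in ``orientation_log``.

    Raises
    ------
    InputError
        If the SNP intersection across tables is empty.
    """
    if isinstance(exposures, SummaryStatsTable):
        exposures = [exposures]
    if not exposures:
        raise InputError("at least one exposure table is required")
    if palindrome_policy not in {"drop_all", "infer_by_eaf"}:
        raise ConfigurationError(
            f"palindrome_policy must be 'drop_all' or 'infer_by_eaf', got {palindrome_policy!r}"
        )

    tables = exposures + [outcome]
    shared = set(tables[0].snp_ids)
    for t in tables[1:]:
        shared &= set(t.snp_ids)
    if not shared:
        raise InputError("empty SNP intersection between exposure and outcome tables")
    # deterministic order: follow the reference exposure's row order
    ref = exposures[0]
    snp_order = [s for s in ref.snp_ids if s in shared]

    indexed = [t.data.set_index("snp_id") for t in tables]
    log_rows: list[dict] = []
    kept_ids: list[str] = []
    exp_betas, exp_ses, out_betas, out_ses = [], [], [], []

    for snp in snp_order:
        ref_row = indexed[0].loc[snp]
        ref_ea, ref_oa = ref_row["effect_allele"], ref_row["other_allele"]
        ref_eaf = ref_row["eaf"]
        factors: list[float] = []
        drop_reason = None
        for t, df in zip(tables, indexed):
            row = df.loc[snp]
            factor, action = _align_to_reference(
                ref_ea,
                ref_oa,
                None if pd.isna(ref_eaf) else float(ref_eaf),
                row["effect_allele"],
                row["other_allele"],
                None if pd.isna(row["eaf"]) else float(row["eaf"]),
                palindrome_policy,
                eaf_ambiguity,
            )
            log_rows.append(
                {
                    "snp_id": snp,
                    "table": t.trait_id,
                    "action": action,
                    "kept": factor is not None,
                }
            )
            if factor is None:
                drop_reason = action
                break
            factors.append(factor)
        if drop_reason is not None:
            continue
        kept_ids.append(snp)
        exp_betas.append(
            [factors[k] * float(indexed[k].loc[snp, "beta"]) for k in range(len(exposures))]
        )
        exp_ses.append(
            [float(indexed[k].loc[snp, "se"]) for k in range(len(exposures))]
        )
        out_betas.append(factors[-1] * float(indexed[-1].loc[snp, "beta"]))
        out_ses.append(float(indexed[-1].loc[snp, "se"]))

    if not kept_ids:
        raise InputError("no SNP survived harmonization")

    return HarmonizedDataset(
        snp_ids=kept_ids,
        exposure_betas=np.asarray(exp_betas, dtype=float),
        exposure_ses=np.asarray(exp_ses, dtype=float),
        outcome_betas=np.asarray(out_betas, dtype=float),
        outcome_ses=np.asarray(out_ses, dtype=float),
        exposure_ids=[t.trait_id for t in exposures],
        outcome_id=outcome.trait_id,
        orientation_log=pd.DataFrame(log_rows),
    )
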