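"""Instrument selection, clumping, blocklist, strength and harmonization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.datatypes import LDMatrix
from mrmediate.errors import ConfigurationError, InputError
from mrmediate.instruments import (
    apply_blocklist,
    compute_instrument_strength,
    harmonize,
    ld_clump,
    select_by_pvalue,
)

from conftest import make_table


class TestSelectByPvalue:
    def test_strict_threshold_filter(self):
        table = make_table([{"pval": 1e-9}, {"pval": 1e-7}, {"pval": 0.2}])
        assert select_by_pvalue(table, 5e-8).n_snps == 1
        assert select_by_pvalue(table, 5e-6).n_snps == 2

    def test_zero_survivors_advises_relaxed_threshold(self):
        table = make_table([{"pval": 0.05}, {"pval": 0.5}])
        with pytest.raises(InputError, match="relaxed threshold 5e-6"):
            select_by_pvalue(table, 5e-8)

    def test_threshold_validated(self):
        table = make_table([{"pval": 0.5}])
        with pytest.raises(ConfigurationError):
            select_by_pvalue(table, 2.0)


def _block_ld(snp_ids, r2=0.8):
    J = len(snp_ids)
    mat = np.full((J, J), r2)
    np.fill_diagonal(mat, 1.0)
    return LDMatrix(snp_ids, mat)


class TestLdClump:
    def test_same_block_keeps_lowest_p_only(self):
        # exhaustive check of the greedy rule: all pairs linked and within
        # the window, so only the smallest p-value survives
        table = make_table(
            [
                {"pval": 1e-10, "pos": 1000},
                {"pval": 1e-9, "pos": 2000},
                {"pval": 1e-8, "pos": 3000},
            ]
        )
        ld = _block_ld(table.snp_ids, 0.8)
        out = ld_clump(table, ld, 0.001, 10_000)
        assert out.snp_ids == ["rs1"]

    def test_different_chromosomes_escape_the_window(self):
        table = make_table(
            [{"chrom": "1", "pval": 1e-10}, {"chrom": "2", "pval": 1e-9}]
        )
        ld = _block_ld(table.snp_ids, 0.9)
        assert ld_clump(table, ld, 0.001, 10_000).n_snps == 2

    def test_r2_below_threshold_keeps_both(self):
        table = make_table([{"pval": 1e-10, "pos": 1000}, {"pval": 1e-9, "pos": 2000}])
        ld = _block_ld(table.snp_ids, 0.0005)
        assert ld_clump(table, ld, 0.001, 10_000).n_snps == 2

    def test_identity_ld_is_identity_on_table(self):
        table = make_table([{"pos": 1000 * i, "pval": 10**-9 - i * 1e-11} for i in range(1, 6)])
        ld = LDMatrix(table.snp_ids, np.eye(5))
        out = ld_clump(table, ld, 0.001, 10_000)
        assert out.snp_ids == table.snp_ids

    def test_snps_missing_from_ld_are_unlinked_with_warning(self):
        table = make_table([{"pval": 1e-10, "pos": 1000}, {"pval": 1e-9, "pos": 2000}])
        ld = LDMatrix(["rs1"], np.eye(1))
        with pytest.warns(UserWarning, match="unlinked"):
            out = ld_clump(table, ld, 0.001, 10_000)
        assert out.n_snps == 2

    def test_window_bound_is_respected(self):
        # linked pair but 20 Mb apart: both kept
        table = make_table([{"pval": 1e-10, "pos": 1000}, {"pval": 1e-9, "pos": 20_001_000}])
        ld = _block_ld(table.snp_ids, 0.9)
        assert ld_clump(table, ld, 0.001, 10_000).n_snps == 2

    def test_invalid_threshold(self):
        table = make_table([{}])
        with pytest.raises(ConfigurationError):
            ld_clump(table, _block_ld(table.snp_ids), 1.5, 10_000)

    def test_retained_set_is_mutually_independent(self):
        rng = np.random.default_rng(0)
        J = 12
        base = rng.uniform(0, 0.9, size=(J, J))
        mat = np.tril(base, -1)
        mat = mat + mat.T
        np.fill_diagonal(mat, 1.0)
        table = make_table(
            [{"pos": 1000 + 500 * i, "pval": float(p)} for i, p in enumerate(rng.uniform(1e-12, 1e-6, J))]
        )
        ld = LDMatrix(table.snp_ids, mat)
        out = ld_clump(table, ld, 0.3, 10_000)
        kept = out.snp_ids
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert ld.lookup(a, b) <= 0.3


class TestBlocklist:
    def test_removal_logged_with_reason(self, tmp_path):
        table = make_table([{}, {}, {}])
        bl = tmp_path / "block.txt"
        bl.write_text("rs2\tassociated with smoking\n")
        out = apply_blocklist(table, bl)
        assert out.snp_ids == ["rs1", "rs3"]
        removed = out.provenance["blocklist"]["removed"]
        assert removed == [{"snp_id": "rs2", "reason": "associated with smoking"}]

    def test_empty_blocklist_is_identity(self, tmp_path):
        table = make_table([{}, {}])
        bl = tmp_path / "block.txt"
        bl.write_text("")
        out = apply_blocklist(table, bl)
        assert out.snp_ids == table.snp_ids

    def test_absent_snp_counted_not_found(self, tmp_path):
        table = make_table([{}])
        bl = tmp_path / "block.txt"
        bl.write_text("rs999\tdiabetes\n")
        out = apply_blocklist(table, bl)
        assert out.n_snps == 1
        assert out.provenance["blocklist"]["not_found"] == 1


class TestInstrumentStrength:
    def test_hand_arithmetic_with_eaf(self):
        # R2 = 2 * 0.5 * 0.5 * 0.1^2 = 0.005; F = 9998 * 0.005/0.995 = 50.24
        table = make_table([{"eaf": 0.5, "beta": 0.1, "n": 10_000}])
        s = compute_instrument_strength(table)
        assert s.per_snp_r2[0] == pytest.approx(0.005)
        assert s.per_snp_f[0] == pytest.approx(9998 * 0.005 / 0.995, rel=1e-12)
        assert s.overall_f == pytest.approx(50.24, abs=0.01)
        assert s.method_note == ["eaf"]

    def test_zscore_fallback_without_eaf(self):
        table = make_table([{"eaf": np.nan, "beta": 0.05, "se": 0.01, "n": 1_000_000}])
        s = compute_instrument_strength(table)
        assert s.per_snp_f[0] == pytest.approx(25.0)
        assert s.method_note == ["zscore_fallback"]

    def test_zero_beta_gives_zero(self):
        table = make_table([{"beta": 0.0, "eaf": 0.4}])
        s = compute_instrument_strength(table)
        assert s.per_snp_r2[0] == 0.0
        assert s.per_snp_f[0] == 0.0

    def test_insufficient_sample_size(self):
        table = make_table([{"n": 3}, {"n": 3}, {"n": 3}])
        with pytest.raises(InputError, match="insufficient sample size"):
            compute_instrument_strength(table)

    @given(
        b1=st.floats(0.01, 1.0),
        factor=st.floats(1.01, 5.0),
        eaf=st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_f_strictly_increases_with_abs_beta(self, b1, factor, eaf):
        t1 = make_table([{"beta": b1, "eaf": eaf, "n": 50_000}])
        t2 = make_table([{"beta": b1 * factor, "eaf": eaf, "n": 50_000}])
        f1 = compute_instrument_strength(t1).per_snp_f[0]
        f2 = compute_instrument_strength(t2).per_snp_f[0]
        assert f2 > f1


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_table(
            [{"effect_allele": "G", "other_allele": "A", "beta": 0.05}],
            trait_id="out",
            trait_role="outcome",
        )
        data = harmonize(exp, out)
        assert data.outcome_betas[0] == pytest.approx(-0.05)
        log = data.orientation_log
        assert "flipped" in log[log["table"] == "out"]["action"].iloc[0]

    def test_strand_complement_aligned(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_table(
            [{"effect_allele": "T", "other_allele": "C", "beta": 0.05}],
            trait_id="out",
            trait_role="outcome",
        )
        data = harmonize(exp, out)
        assert data.outcome_betas[0] == pytest.approx(0.05)

    def test_ambiguous_palindrome_dropped_under_infer_by_eaf(self):
        exp = make_table(
            [
                {"effect_allele": "A", "other_allele": "T", "eaf": 0.48},
                {"effect_allele": "A", "other_allele": "G"},
            ]
        )
        out = make_table(
            [
                {"effect_allele": "A", "other_allele": "T", "eaf": 0.48},
                {"effect_allele": "A", "other_allele": "G"},
            ],
            trait_id="out",
            trait_role="outcome",
        )
        data = harmonize(exp, out, palindrome_policy="infer_by_eaf", eaf_ambiguity=0.08)
        assert data.snp_ids == ["rs2"]
        log = data.orientation_log
        assert "ambiguous palindrome" in set(log[log["snp_id"] == "rs1"]["action"])

    def test_unambiguous_palindrome_aligned_by_frequency(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.2, "beta": 0.1}])
        same = make_table(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.21, "beta": 0.05}],
            trait_id="out",
            trait_role="outcome",
        )
        flipped = make_table(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.79, "beta": 0.05}],
            trait_id="out",
            trait_role="outcome",
        )
        assert harmonize(exp, same).outcome_betas[0] == pytest.approx(0.05)
        assert harmonize(exp, flipped).outcome_betas[0] == pytest.approx(-0.05)

    def test_drop_all_policy_drops_every_palindrome(self):
        exp = make_table(
            [
                {"effect_allele": "C", "other_allele": "G", "eaf": 0.2},
                {"effect_allele": "A", "other_allele": "G"},
            ]
        )
        out = make_table(
            [
                {"effect_allele": "C", "other_allele": "G", "eaf": 0.2},
                {"effect_allele": "A", "other_allele": "G"},
            ],
            trait_id="out",
            trait_role="outcome",
        )
        assert harmonize(exp, out, palindrome_policy="drop_all").snp_ids == ["rs2"]

    def test_allele_mismatch_dropped(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G"}, {}])
        out = make_table(
            [{"effect_allele": "A", "other_allele": "C"}, {}],
            trait_id="out",
            trait_role="outcome",
        )
        data = harmonize(exp, out)
        assert data.snp_ids == ["rs2"]
        log = data.orientation_log
        assert "allele mismatch" in set(log[log["snp_id"] == "rs1"]["action"])

    def test_empty_intersection_is_input_error(self):
        exp = make_table([{}])
        out = make_table([{}], trait_id="out", trait_role="outcome")
        out.data.loc[0, "snp_id"] = "rsX"
        with pytest.raises(InputError, match="intersection"):
            harmonize(exp, out)

    def test_idempotent_on_already_aligned_tables(self):
        exp = make_table([{"beta": 0.1}, {"beta": 0.2, "pos": 2000}])
        out = make_table(
            [{"beta": 0.05}, {"beta": 0.07, "pos": 2000}],
            trait_id="out",
            trait_role="outcome",
        )
        first = harmonize(exp, out)
        # every action is a plain alignment: re-running changes nothing
        again = harmonize(exp, out)
        np.testing.assert_array_equal(first.outcome_betas, again.outcome_betas)
        assert set(first.orientation_log["action"]) == {"aligned"}

    def test_orientation_gauge_symmetry(self):
        """Flipping an outcome row's alleles and beta sign leaves the
        harmonized dataset invariant."""
        exp = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_table(
            [{"effect_allele": "A", "other_allele": "G", "beta": 0.05, "eaf": 0.3}],
            trait_id="out",
            trait_role="outcome",
        )
        flipped = make_table(
            [{"effect_allele": "G", "other_allele": "A", "beta": -0.05, "eaf": 0.7}],
            trait_id="out",
            trait_role="outcome",
        )
        a = harmonize(exp, out)
        b = harmonize(exp, flipped)
        np.testing.assert_allclose(a.outcome_betas, b.outcome_betas)
        np.testing.assert_allclose(a.exposure_betas, b.exposure_betas)

    def test_multiple_exposures_first_is_reference(self):
        e1 = make_table([{"beta": 0.1}], trait_id="e1")
        e2 = make_table(
            [{"effect_allele": "G", "other_allele": "A", "beta": 0.2}], trait_id="e2"
        )
        out = make_table([{"beta": 0.05}], trait_id="out", trait_role="outcome")
        data = harmonize([e1, e2], out)
        assert data.exposure_ids == ["e1", "e2"]
        np.testing.assert_allclose(data.exposure_betas[0], [0.1, -0.2])
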