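import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maternalmr.estimates import MrEstimate
from maternalmr.summary_io import (
    DuplicateSnpError,
    EmptyOverlapError,
    InstrumentSet,
    SnpAssociation,
    SummaryFormatError,
    harmonise,
    read_summary_table,
    rescale_estimate,
    write_summary_table,
)

TSV = (
    "snp\teffect_allele\tother_allele\teaf\tbeta\tse\tp\tn\n"
    "rs1\tA\tG\t0.30\t0.05\t0.004\t1e-8\t10000\n"
    "rs2\tC\tT\t0.62\t0.03\t0.005\t1e-6\t10000\n"
    "rs3\tG\tA\t0.45\t-0.04\t0.006\t1e-7\t10000\n"
)


class TestReadSummaryTable:
    def test_reads_all_valid_rows_in_order(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text(TSV)
        inst = read_summary_table(p, exposure_name="adiposity")
        assert len(inst) == 3
        assert inst.snp_ids == ["rs1", "rs2", "rs3"]
        assert inst.snps[0].beta == 0.05 and inst.snps[2].beta == -0.04
        assert inst.snps[1].eaf == 0.62 and inst.snps[1].n == 10000

    def test_rejects_nonpositive_se_row_with_reason(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text(TSV + "rs4\tA\tC\t0.2\t0.01\t0\t0.5\t10000\n")
        inst = read_summary_table(p)
        assert len(inst) == 3
        assert inst.rejected == [(3, "rs4", "nonpositive SE")]

    def test_rejects_indel_alleles(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text(TSV + "rs5\tAT\tA\t0.2\t0.01\t0.01\t0.5\t10000\n")
        inst = read_summary_table(p)
        assert len(inst) == 3
        assert "biallelic" in inst.rejected[0][2]

    def test_shuffled_columns_with_map_match_canonical(self, tmp_path):
        canonical = tmp_path / "a.tsv"
        canonical.write_text(TSV)
        shuffled = tmp_path / "b.tsv"
        shuffled.write_text(
            "stderr\tvariant\tB\tA1\tA2\tfreq\n"
            "0.004\trs1\t0.05\tA\tG\t0.30\n"
            "0.005\trs2\t0.03\tC\tT\t0.62\n"
            "0.006\trs3\t-0.04\tG\tA\t0.45\n"
        )
        cmap = {"snp": "variant", "effect_allele": "A1", "other_allele": "A2",
                "beta": "B", "se": "stderr", "eaf": "freq"}
        a = read_summary_table(canonical)
        b = read_summary_table(shuffled, column_map=cmap)
        for sa, sb in zip(a.snps, b.snps):
            assert (sa.snp_id, sa.effect_allele, sa.beta, sa.se, sa.eaf) == (
                sb.snp_id, sb.effect_allele, sb.beta, sb.se, sb.eaf
            )

    def test_missing_mapped_column_names_it(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text("snp\teffect_allele\tother_allele\tbeta\n" "rs1\tA\tG\t0.05\n")
        with pytest.raises(SummaryFormatError, match="se"):
            read_summary_table(p)

    def test_duplicate_snp_ids_error_lists_them(self, tmp_path):
        p = tmp_path / "exp.tsv"
        p.write_text(TSV + "rs1\tA\tG\t0.30\t0.05\t0.004\t1e-8\t10000\n")
        with pytest.raises(DuplicateSnpError, match="rs1"):
            read_summary_table(p)

    def test_comma_separated_accepted(self, tmp_path):
        p = tmp_path / "exp.csv"
        p.write_text(TSV.replace("\t", ","))
        assert len(read_summary_table(p)) == 3

    def test_round_trip(self, tmp_path, simple_instruments):
        p = tmp_path / "out.tsv"
        write_summary_table(simple_instruments.snps, p)
        back = read_summary_table(p)
        assert back.snp_ids == simple_instruments.snp_ids
        assert back.snps[2].beta == simple_instruments.snps[2].beta


class TestHarmonise:
    def out(self, ea, oa, beta=0.02, eaf=0.30, snp="rs1", se=0.01):
        return SnpAssociation(snp, ea, oa, beta=beta, se=se, eaf=eaf)

    def exp(self, ea="A", oa="G", beta=0.05, eaf=0.30, snp="rs1"):
        return InstrumentSet("x", "SD", 1.0, [SnpAssociation(snp, ea, oa, beta=beta, se=0.004, eaf=eaf)])

    def test_identity_case(self):
        (rec,) = harmonise(self.exp(), [self.out("A", "G")])
        assert (rec.beta_x, rec.beta_y, rec.flipped, rec.excluded) == (0.05, 0.02, False, False)

    def test_allele_swap_negates_and_reflects_eaf(self):
        (rec,) = harmonise(self.exp(), [self.out("G", "A", eaf=0.3)])
        assert rec.flipped and rec.beta_y == -0.02 and rec.eaf_y == 0.7

    def test_strand_complement_then_match(self):
        # exposure A/G; outcome T/C is the same variant on the other strand
        (rec,) = harmonise(self.exp(), [self.out("T", "C")])
        assert rec.strand_complemented and not rec.flipped and rec.beta_y == 0.02

    def test_complement_plus_swap(self):
        (rec,) = harmonise(self.exp(), [self.out("C", "T", eaf=0.65)])
        assert rec.strand_complemented and rec.flipped
        assert rec.beta_y == -0.02 and rec.eaf_y == pytest.approx(0.35)

    def test_mismatch_excluded(self):
        (rec,) = harmonise(self.exp(), [self.out("A", "C")])
        assert rec.excluded_reason == "allele mismatch"

    def test_missing_in_outcome(self):
        recs = harmonise(
            InstrumentSet("x", "SD", 1.0, [
                SnpAssociation("rs1", "A", "G", beta=0.05, se=0.004),
                SnpAssociation("rs9", "A", "G", beta=0.02, se=0.004),
            ]),
            [self.out("A", "G")],
        )
        assert recs[1].excluded_reason == "missing in outcome"

    def test_empty_overlap_raises(self):
        with pytest.raises(EmptyOverlapError):
            harmonise(self.exp(snp="rs1"), [self.out("A", "G", snp="rs2")])

    def test_palindromic_ambiguous_near_half(self):
        (rec,) = harmonise(self.exp("A", "T", eaf=0.50), [self.out("A", "T", eaf=0.50)],
                           palindromic_eaf_window=0.08)
        assert rec.excluded_reason == "palindromic-ambiguous"

    def test_palindromic_missing_eaf_excluded(self):
        (rec,) = harmonise(self.exp("A", "T", eaf=0.2), [self.out("A", "T", eaf=None)])
        assert rec.excluded_reason == "palindromic-ambiguous"

    def test_palindromic_resolved_by_frequency_agreement(self):
        # same minor side -> same orientation
        (rec,) = harmonise(self.exp("A", "T", eaf=0.20), [self.out("T", "A", eaf=0.25)])
        assert not rec.excluded and rec.beta_y == 0.02
        # opposite sides -> flip
        (rec,) = harmonise(self.exp("A", "T", eaf=0.20), [self.out("A", "T", eaf=0.75)])
        assert not rec.excluded and rec.beta_y == -0.02 and rec.eaf_y == 0.25

    def test_negative_exposure_beta_oriented_to_increasing_allele(self):
        (rec,) = harmonise(self.exp(beta=-0.05, eaf=0.3), [self.out("A", "G", beta=0.02, eaf=0.3)])
        assert rec.beta_x == 0.05 and rec.beta_y == -0.02
        assert (rec.effect_allele, rec.other_allele) == ("G", "A")
        assert rec.eaf_x == pytest.approx(0.7) and rec.eaf_y == pytest.approx(0.7)

    def test_count_conservation(self, simple_instruments):
        outcome = [self.out("A", "G", snp="rs1"), self.out("A", "C", snp="rs2")]
        recs = harmonise(simple_instruments, outcome)
        assert len(recs) == len(simple_instruments)
        assert all(r.excluded_reason for r in recs if r.excluded)

    def test_idempotence(self, simple_instruments):
        outcome = [
            self.out("G", "A", snp="rs1", eaf=0.68),
            self.out("C", "T", snp="rs2", eaf=0.60),
            self.out("G", "A", snp="rs3", eaf=0.44),
        ]
        first = [r for r in harmonise(simple_instruments, outcome) if not r.excluded]
        exp2 = InstrumentSet("x", "SD", 1.0, [
            SnpAssociation(r.snp_id, r.effect_allele, r.other_allele, beta=r.beta_x,
                           se=r.se_x, eaf=r.eaf_x) for r in first
        ])
        out2 = [
            SnpAssociation(r.snp_id, r.effect_allele, r.other_allele, beta=r.beta_y,
                           se=r.se_y, eaf=r.eaf_y) for r in first
        ]
        second = harmonise(exp2, out2)
        for a, b in zip(first, second):
            assert not b.flipped and not b.strand_complemented
            assert (a.beta_x, a.beta_y, a.eaf_x, a.eaf_y) == (b.beta_x, b.beta_y, b.eaf_x, b.eaf_y)

    @given(flip_mask=st.lists(st.booleans(), min_size=3, max_size=3))
    @settings(deadline=None)
    def test_allele_flip_invariance(self, flip_mask):
        """Relabelling input alleles (with negated betas) leaves results unchanged."""
        simple_instruments = InstrumentSet(
            "adiposity", "SD", 6.5,
            [SnpAssociation("rs1", "A", "G", beta=0.05, se=0.004, eaf=0.30),
             SnpAssociation("rs2", "C", "T", beta=0.03, se=0.005, eaf=0.62),
             SnpAssociation("rs3", "G", "A", beta=-0.04, se=0.006, eaf=0.45)],
        )
        outcome = [
            self.out("A", "G", snp="rs1", eaf=0.31),
            self.out("C", "T", snp="rs2", eaf=0.60),
            self.out("G", "A", snp="rs3", eaf=0.44),
        ]
        mutated = []
        for s, flip in zip(simple_instruments.snps, flip_mask):
            if flip:
                mutated.append(dataclasses.replace(
                    s, effect_allele=s.other_allele, other_allele=s.effect_allele,
                    beta=-s.beta, eaf=1 - s.eaf))
            else:
                mutated.append(s)
        base = harmonise(simple_instruments, outcome)
        alt = harmonise(dataclasses.replace(simple_instruments, snps=mutated), outcome)
        for a, b in zip(base, alt):
            assert (a.snp_id, a.beta_x, a.se_x, a.beta_y, a.se_y) == (
                b.snp_id, b.beta_x, b.se_x, b.beta_y, b.se_y)
            assert (a.effect_allele, a.other_allele, a.excluded_reason) == (
                b.effect_allele, b.other_allele, b.excluded_reason)
            # EAF reflection 1-(1-f) is not exact in binary floating point
            assert a.eaf_x == pytest.approx(b.eaf_x, abs=1e-15)
            assert a.eaf_y == pytest.approx(b.eaf_y, abs=1e-15)


class TestRescaleEstimate:
    def est(self, beta, se=0.03):
        return MrEstimate.from_beta_se("wald_ivw_fixed", beta, se, n_snps=14)

    def test_sd_to_grams(self):
        grams = rescale_estimate(self.est(-0.1942), outcome_sd=484)
        assert grams.beta == pytest.approx(-93.99, abs=0.01)
        assert grams.se == pytest.approx(0.03 * 484)
        assert grams.pvalue == self.est(-0.1942).pvalue

    def test_zero_fixed_point_and_identity(self):
        assert rescale_estimate(self.est(0.0), outcome_sd=484).beta == 0.0
        same = rescale_estimate(self.est(0.2), outcome_sd=1.0)
        assert same.beta == 0.2 and same.ci_low == self.est(0.2).ci_low

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            rescale_estimate(self.est(0.1), outcome_sd=0.0)
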