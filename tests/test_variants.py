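"""Variant-TFBS overlap, window filtering and gain/loss analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promkit.match import PWM
from promkit.variants import (
    RefMismatchError,
    STATUS_GAINED,
    STATUS_LOST,
    STATUS_RETAINED,
    TFBSRecord,
    UnsupportedVariantError,
    VariantRecord,
    apply_variants,
    gain_loss_analysis,
    overlap_variants_tfbs,
    read_vcf,
    restrict_to_promoter_window,
    site_relative_position,
)
from promkit.vtss import VTSS

# the four GJB1 promoter point variants inside the Sox10 site on chrX
GJB1_SITE = TFBSRecord("X", 70_443_016, 70_443_033, factor="Sox10")
GJB1_VARIANTS = [
    VariantRecord("X", 70_443_018, "C", "G"),
    VariantRecord("X", 70_443_029, "T", "G"),
    VariantRecord("X", 70_443_029, "T", "C"),
    VariantRecord("X", 70_443_031, "G", "C"),
]

# the seven F7 promoter variants inside the HNF-4 site on chr13
F7_SITE = TFBSRecord("13", 113_760_083, 113_760_109, factor="HNF-4")
F7_VARIANTS = [
    VariantRecord("13", 113_760_091, "G", "C"),
    VariantRecord("13", 113_760_094, "C", "T"),
    VariantRecord("13", 113_760_095, "T", "G"),
    VariantRecord("13", 113_760_096, "T", "G"),
    VariantRecord("13", 113_760_097, "T", "G"),
    VariantRecord("13", 113_760_099, "C", "T"),
    VariantRecord("13", 113_760_101, "C", "T"),
]


class TestSiteRelativePosition:
    def test_f7_worked_example_offset_8(self):
        """chr13:113,760,091 sits at 0-based offset 8 of the HNF-4 site."""
        assert site_relative_position(113_760_091, F7_SITE.start) == 8

    def test_site_start_is_offset_zero(self):
        assert site_relative_position(1000, 1000) == 0

    def test_gjb1_first_variant_offset_2(self):
        assert site_relative_position(70_443_018, GJB1_SITE.start) == 2

    def test_out_of_site_position_rejected(self):
        with pytest.raises(ValueError):
            site_relative_position(999, 1000)
        with pytest.raises(ValueError):
            site_relative_position(1021, 1000, 1020)


class TestOverlap:
    def test_gjb1_sox10_four_overlaps(self):
        overlaps = overlap_variants_tfbs(GJB1_VARIANTS, [GJB1_SITE])
        assert len(overlaps) == 4
        assert {o.site_relative_position for o in overlaps} == {2, 13, 15}

    def test_f7_hnf4_seven_overlaps(self):
        overlaps = overlap_variants_tfbs(F7_VARIANTS, [F7_SITE])
        assert len(overlaps) == 7

    def test_boundaries_inclusive_both_ends(self):
        site = TFBSRecord("1", 100, 110)
        at_start = VariantRecord("1", 100, "A", "C")
        at_end = VariantRecord("1", 110, "A", "C")
        past_end = VariantRecord("1", 111, "A", "C")
        overlaps = overlap_variants_tfbs([at_start, at_end, past_end], [site])
        assert [o.variant.pos for o in overlaps] == [100, 110]

    def test_matches_all_pairs_brute_force(self, rng):
        variants = [
            VariantRecord("1", int(p), "A", "C", f"v{i}")
            for i, p in enumerate(rng.integers(1, 5_000, size=300))
        ]
        sites = [
            TFBSRecord("1", int(s), int(s) + int(w))
            for s, w in zip(
                rng.integers(1, 5_000, size=120), rng.integers(5, 40, size=120)
            )
        ]
        got = {
            (o.variant.variant_id, o.site.start, o.site.end)
            for o in overlap_variants_tfbs(variants, sites)
        }
        expected = {
            (v.variant_id, s.start, s.end)
            for v in variants
            for s in sites
            if s.start <= v.pos <= s.end
        }
        assert got == expected

    def test_disjoint_chromosomes_warn(self, caplog):
        with caplog.at_level("WARNING"):
            out = overlap_variants_tfbs(
                [VariantRecord("chr1", 5, "A", "C")], [TFBSRecord("1", 1, 10)]
            )
        assert out == []
        assert "no shared chromosomes" in caplog.text


class TestPromoterWindow:
    def vtss(self, pos, strand="+"):
        return VTSS("G", "1", strand, pos, 5.0, 100.0, "single")

    @pytest.mark.parametrize(
        "pos,strand,kept",
        [
            (9_600, "+", True),  # d = -400, upstream, inside
            (10_200, "+", False),  # d = +200, too far downstream
            (10_100, "+", True),  # d = +100, boundary inclusive
            (10_400, "-", True),  # d = -400 on the minus strand
            (9_800, "-", False),  # d = +200 on the minus strand
        ],
    )
    def test_strand_oriented_window(self, pos, strand, kept):
        variants = [VariantRecord("1", pos, "A", "C")]
        out = restrict_to_promoter_window(variants, [self.vtss(10_000, strand)])
        assert (len(out) == 1) is kept

    def test_filter_never_grows_and_infinite_window_is_identity(self, rng):
        variants = [
            VariantRecord("1", int(p), "A", "C") for p in rng.integers(1, 10**6, 50)
        ]
        promoters = [self.vtss(500_000)]
        filtered = restrict_to_promoter_window(variants, promoters)
        assert len(filtered) <= len(variants)
        everything = restrict_to_promoter_window(
            variants, promoters, window=(-(10**9), 10**9)
        )
        assert everything == variants


class TestApplyVariants:
    def test_empty_set_is_identity(self):
        assert apply_variants("ACGTACGT", 100, []) == "ACGTACGT"

    def test_single_snv_substitution(self):
        seq = "ACCGTACGTACGTACGTA"  # 18-mer, C>G at offset 2
        out = apply_variants(seq, 1, [VariantRecord("X", 3, "C", "G")])
        assert out == "ACGGTACGTACGTACGTA"
        assert len(out) == len(seq)

    def test_disjoint_snvs_commute(self):
        seq = "ACGTACGT"
        v1 = VariantRecord("1", 2, "C", "T")
        v2 = VariantRecord("1", 7, "G", "A")
        assert apply_variants(seq, 1, [v1, v2]) == apply_variants(seq, 1, [v2, v1])

    def test_ref_mismatch_names_coordinate_and_base(self):
        with pytest.raises(RefMismatchError, match="coordinate 3"):
            apply_variants("ACGT", 1, [VariantRecord("1", 3, "A", "T")])

    def test_indel_rejected(self):
        with pytest.raises(UnsupportedVariantError):
            apply_variants("ACGT", 1, [VariantRecord("1", 2, "CG", "C")])

    @given(st.integers(0, 7))
    @settings(deadline=None)
    def test_ref_equal_alt_is_identity(self, off):
        seq = "ACGTACGT"
        v = VariantRecord("1", off + 1, seq[off], seq[off])
        assert apply_variants(seq, 1, [v]) == seq


def informative_pwm(matrix_id="MX", length=8, top=0.91):
    rng = np.random.default_rng(42)
    cons = rng.integers(0, 4, size=length)
    f = np.full((length, 4), (1 - top) / 3)
    f[np.arange(length), cons] = top
    return PWM(matrix_id, f)


class TestGainLoss:
    def setup_method(self):
        self.pwm = informative_pwm()
        L = len(self.pwm)
        self.cutoffs = {self.pwm.matrix_id: (1 - 1 / (2 * L), 0.5)}
        rng = np.random.default_rng(11)
        bg = "".join(rng.choice(list("ACGT"), size=60))
        self.k = 25
        self.seq = bg[: self.k] + self.pwm.consensus + bg[self.k + L :]

    def lossy_variant(self):
        j = int(np.argmax(self.pwm.information))
        return VariantRecord(
            "1", self.k + j + 1, self.pwm.consensus[j], self.pwm.anti_consensus[j]
        )

    def test_reference_alleles_only_reports_no_change(self):
        rep = gain_loss_analysis(self.seq, 1, [], [self.pwm], self.cutoffs)
        assert rep.lost == [] and rep.gained == []
        assert any(e.status == STATUS_RETAINED for e in rep.entries)

    def test_consensus_breaking_snv_is_lost(self):
        rep = gain_loss_analysis(self.seq, 1, [self.lossy_variant()], [self.pwm], self.cutoffs)
        assert [e.matrix_id for e in rep.lost] == [self.pwm.matrix_id]

    def test_consensus_creating_snv_is_gained(self):
        v = self.lossy_variant()
        broken = apply_variants(self.seq, 1, [v])
        restore = VariantRecord(v.chrom, v.pos, v.alt, v.ref)
        rep = gain_loss_analysis(broken, 1, [restore], [self.pwm], self.cutoffs)
        assert [e.matrix_id for e in rep.gained] == [self.pwm.matrix_id]

    def test_ref_alt_swap_is_involutive(self):
        v = self.lossy_variant()
        fwd = gain_loss_analysis(self.seq, 1, [v], [self.pwm], self.cutoffs)
        alt_seq = apply_variants(self.seq, 1, [v])
        back = gain_loss_analysis(
            alt_seq, 1, [VariantRecord(v.chrom, v.pos, v.alt, v.ref)],
            [self.pwm], self.cutoffs,
        )
        assert {e.matrix_id for e in fwd.lost} == {e.matrix_id for e in back.gained}
        assert {e.matrix_id for e in fwd.gained} == {e.matrix_id for e in back.lost}

    def test_indel_in_scoring_rejected(self):
        with pytest.raises(UnsupportedVariantError):
            gain_loss_analysis(
                self.seq, 1, [VariantRecord("1", 5, "AC", "A")], [self.pwm], self.cutoffs
            )


class TestVcf:
    def test_multiallelic_records_split(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t100\trs1\tA\tC,G\t.\t.\t.\n"
        )
        variants = read_vcf(str(path))
        assert [(v.pos, v.alt) for v in variants] == [(100, "C"), (100, "G")]
        assert all(v.variant_id == "rs1" for v in variants)
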