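import numpy as np
import pytest

from framepool.fixtures import ORACLE_TEST_PARAMS, REF_UTR_RNA
from framepool.synthetic_mpra import oracle_mrl
from framepool.variant_effect import (
    TranscriptUTR,
    Variant,
    apply_variants,
    extract_utr_sequence,
    load_utr_regions,
    load_variants,
    run_vcf_pipeline,
    score_variants,
)


@pytest.fixture(scope="module")
def toy_genome(tmp_path_factory):
    import pyfaidx

    d = tmp_path_factory.mktemp("toygen")
    path = d / "toy.fa"
    path.write_text(">chr1\nACGTACGTAC\n")
    return pyfaidx.Fasta(str(path))


class TestLoadRegions:
    def test_grouping_and_strand(self, fixture_dir):
        utrs = {u.transcript_id: u for u in load_utr_regions(fixture_dir["bed"])}
        assert set(utrs) == {"tx_plus", "tx_minus", "tx_split"}
        assert utrs["tx_split"].exons == ((5, 30), (40, 65))
        assert utrs["tx_minus"].strand == "-"
        assert utrs["tx_plus"].spliced_length == 50

    def test_inconsistent_strand_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t0\t10\ttx\t0\t+\nchr1\t20\t30\ttx\t0\t-\n")
        with pytest.raises(ValueError, match="inconsistent"):
            load_utr_regions(bed)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            TranscriptUTR("tx", "chr1", "+", ((0, 10), (5, 15)))


class TestExtractSequence:
    def test_plus_strand_splice_of_toy_contig(self, toy_genome):
        # contig ACGTACGTAC, exons [0,4)+[6,8) -> ACGT + GT -> RNA ACGUGU
        utr = TranscriptUTR("t", "chr1", "+", ((0, 4), (6, 8)))
        assert str(extract_utr_sequence(utr, toy_genome)) == "ACGUGU"

    def test_minus_strand_is_reverse_complement(self, toy_genome):
        utr = TranscriptUTR("t", "chr1", "-", ((0, 4),))
        assert str(extract_utr_sequence(utr, toy_genome)) == "ACGU"  # revcomp(ACGT)

    def test_missing_contig(self, toy_genome):
        with pytest.raises(KeyError):
            extract_utr_sequence(TranscriptUTR("t", "chrX", "+", ((0, 4),)), toy_genome)

    def test_out_of_bounds_interval(self, toy_genome):
        with pytest.raises(ValueError, match="exceeds"):
            extract_utr_sequence(TranscriptUTR("t", "chr1", "+", ((0, 99),)), toy_genome)


class TestApplyVariants:
    utr = TranscriptUTR("t", "chr1", "+", ((100, 150),))

    def test_empty_variant_list_round_trip(self):
        assert apply_variants(self.utr, REF_UTR_RNA, []) == REF_UTR_RNA

    def test_identity_edit(self):
        v = Variant("chr1", 101, "C", "C", "id0")
        assert str(apply_variants(self.utr, REF_UTR_RNA, [v])) == REF_UTR_RNA

    def test_snv_plus_strand(self):
        v = Variant("chr1", 112, "C", "T", "snv")  # transcript position 11
        alt = apply_variants(self.utr, REF_UTR_RNA, [v])
        assert alt.bases[10:13] == "AUG"

    def test_insertion_lengthens_and_shifts_5prime_frames(self):
        v = Variant("chr1", 112, "C", "CAA", "ins")
        alt = apply_variants(self.utr, REF_UTR_RNA, [v])
        assert len(alt) == 52
        assert alt.bases[11:14] == "CAA"  # REF C kept, AA inserted
        assert alt.bases[14:] == REF_UTR_RNA[12:]

    def test_deletion(self):
        v = Variant("chr1", 111, "ACG", "A", "del")
        alt = apply_variants(self.utr, REF_UTR_RNA, [v])
        assert len(alt) == 48

    def test_ref_mismatch_reports_expected_vs_found(self):
        v = Variant("chr1", 112, "G", "T", "bad")
        with pytest.raises(ValueError, match="expected G, found C"):
            apply_variants(self.utr, REF_UTR_RNA, [v])

    def test_minus_strand_edits_reverse_complement(self):
        utr = TranscriptUTR("t", "chr1", "-", ((100, 150),))
        # genomic pos 149 (1-based 150) is transcript position 0
        v = Variant("chr1", 150, "G", "C", "m")
        ref = REF_UTR_RNA  # transcript-space sequence
        # transcript base 0 is C; genomic plus-strand REF must be its complement G
        alt = apply_variants(utr, ref, [v])
        assert alt.bases[0] == "G"  # complement of alt C
        assert alt.bases[1:] == ref[1:]

    def test_overlapping_variants_rejected(self):
        vs = [Variant("chr1", 111, "AC", "A", "a"), Variant("chr1", 112, "C", "T", "b")]
        with pytest.raises(ValueError, match="overlapping"):
            apply_variants(self.utr, REF_UTR_RNA, vs)

    def test_exon_boundary_span_rejected(self):
        utr = TranscriptUTR("t", "chr1", "+", ((100, 125), (130, 155)))
        v = Variant("chr1", 124, "CACC", "C", "span")
        with pytest.raises(ValueError, match="exon boundary"):
            apply_variants(utr, REF_UTR_RNA, [v])


class TestScoreVariants:
    def test_identical_sequences_score_zero(self, oracle_predictor):
        eff = score_variants(oracle_predictor, REF_UTR_RNA, REF_UTR_RNA)
        assert eff.log2fc == 0 == eff.log2fc_shift1 == eff.log2fc_shift2

    def test_created_oof_uaug_matches_hand_value(self, oracle_predictor):
        alt = REF_UTR_RNA[:11] + "U" + REF_UTR_RNA[12:]
        eff = score_variants(oracle_predictor, REF_UTR_RNA, alt)
        assert eff.mrl_ref == 6.0 and eff.mrl_alt == pytest.approx(2.4)
        assert eff.log2fc == pytest.approx(np.log2(2.4 / 6), abs=1e-12)

    def test_in_frame_uaug_zero_unshifted_negative_shifted(self, oracle_predictor):
        alt = REF_UTR_RNA[:21] + "U" + REF_UTR_RNA[22:]
        eff = score_variants(oracle_predictor, REF_UTR_RNA, alt)
        assert eff.log2fc == 0
        assert eff.log2fc_shift1 == pytest.approx(np.log2(2.4 / 6))
        assert eff.log2fc_shift2 == pytest.approx(np.log2(2.4 / 6))


class TestPipeline:
    def test_full_toy_run_matches_oracle_values(self, fixture_dir, oracle_predictor):
        table = run_vcf_pipeline(
            fixture_dir["vcf"], fixture_dir["bed"], fixture_dir["fasta"], oracle_predictor
        )
        # deterministic order: transcript id, then position
        assert list(table.transcript_id) == sorted(table.transcript_id)
        expected_oof = np.log2(2.4 / 6)
        by_id = {(r.transcript_id, r.variant_id, r.alt): r for r in table.itertuples()}
        oof = by_id[("tx_plus", "var_oof_uaug", "T")]
        assert oof.log2fc == pytest.approx(expected_oof, abs=1e-12)
        assert oof.log2fc_shift2 == 0
        neutral = by_id[("tx_plus", "var_oof_uaug", "A")]  # multi-allelic split
        assert neutral.log2fc == 0
        inframe = by_id[("tx_plus", "var_if_uaug", "T")]
        assert inframe.log2fc == 0
        assert inframe.log2fc_shift1 == pytest.approx(expected_oof)
        minus = by_id[("tx_minus", "var_minus_oof", "A")]
        assert minus.log2fc == pytest.approx(expected_oof)
        split = by_id[("tx_split", "var_split_oof", "T")]
        assert split.log2fc == pytest.approx(expected_oof)
        assert "var_outside" not in set(table.variant_id)

    def test_insertion_scored_via_independent_string_edit(self, fixture_dir, oracle_predictor):
        table = run_vcf_pipeline(
            fixture_dir["vcf"], fixture_dir["bed"], fixture_dir["fasta"], oracle_predictor
        )
        row = table[table.variant_id == "var_ins"].iloc[0]
        alt_seq = REF_UTR_RNA[:31] + "A" + REF_UTR_RNA[31:]  # insert after position 30
        expected = np.log2(
            oracle_mrl(alt_seq, ORACLE_TEST_PARAMS) / oracle_mrl(REF_UTR_RNA, ORACLE_TEST_PARAMS)
        )
        assert row.log2fc == pytest.approx(expected)

    def test_empty_intersection_returns_empty_table(self, fixture_dir, tmp_path, oracle_predictor):
        vcf = tmp_path / "none.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=70>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t5\tv\tG\tA\t.\tPASS\t.\n"
        )
        table = run_vcf_pipeline(
            vcf, fixture_dir["bed"], fixture_dir["fasta"], oracle_predictor
        )
        assert len(table) == 0

    def test_strand_mirroring_gives_identical_scores(self, fixture_dir, oracle_predictor):
        # tx_plus (chr1:22 C>T) and tx_minus (chr2:49 G>A) encode the same
        # transcript-space variant on opposite strands
        table = run_vcf_pipeline(
            fixture_dir["vcf"], fixture_dir["bed"], fixture_dir["fasta"], oracle_predictor
        )
        plus = table[(table.transcript_id == "tx_plus") & (table.alt == "T") & (table.pos == 22)]
        minus = table[table.transcript_id == "tx_minus"]
        for col in ("mrl_ref", "mrl_alt", "log2fc", "log2fc_shift1", "log2fc_shift2"):
            assert plus.iloc[0][col] == minus.iloc[0][col]


class TestLoadVariants:
    def test_multiallelic_split(self, fixture_dir):
        variants = load_variants(fixture_dir["vcf"])
        alts = [v.alt for v in variants if v.pos == 22 and v.chrom == "chr1"]
        assert sorted(alts) == ["A", "T"]
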