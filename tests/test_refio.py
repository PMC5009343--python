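"""Format readers/writers: contracts, error reporting, round trips."""

import pytest

from refconcord.refio import (
    ChainBlock, ChainMap, FormatError, SiteRecord, decode_pileup_bases,
    read_chain, read_fasta, read_genepred, read_pileup, read_report,
    read_vcf_biallelic, write_report,
)


class TestFasta:
    def test_case_folding_and_multi_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nacgt\n")
        assert read_fasta(p) == {"x": "ACGT"}
        p.write_text(">x\nAC\nGT\n>y\nNN\n")
        assert read_fasta(p) == {"x": "ACGT", "y": "NN"}

    def test_ambiguity_codes_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nACRT\n")
        with pytest.raises(FormatError, match=":2"):
            read_fasta(p)

    @pytest.mark.parametrize("text", [">x\n>y\nACGT\n", "ACGT\n", ">\nACGT\n"])
    def test_malformed_records(self, tmp_path, text):
        p = tmp_path / "a.fa"
        p.write_text(text)
        with pytest.raises(FormatError):
            read_fasta(p)


class TestGenePred:
    ROW = "G1\tNM_1\tchr1\t{strand}\t10\t80\t{cs}\t{ce}\t2\t10,50,\t30,80,\n"

    def test_two_exon_row(self, tmp_path):
        p = tmp_path / "rf.txt"
        p.write_text(self.ROW.format(strand="+", cs=12, ce=75))
        (m,) = read_genepred(p)
        assert m.exons == [(10, 30), (50, 80)]
        assert (m.cds_start, m.cds_end) == (12, 75)
        assert m.is_coding and m.source == "UCSC"

    def test_noncoding_flagged_and_excludable(self, tmp_path):
        p = tmp_path / "rf.txt"
        p.write_text(
            self.ROW.format(strand="+", cs=12, ce=75)
            + self.ROW.format(strand="+", cs=30, ce=30).replace("NM_1", "NR_1")
            + self.ROW.format(strand="-", cs=11, ce=60).replace("NM_1", "NM_2")
        )
        models = read_genepred(p)
        assert len(models) == 3
        coding = [m for m in models if m.is_coding]
        assert [m.transcript_id for m in coding] == ["NM_1", "NM_2"]

    def test_invalid_strand_rejected(self, tmp_path):
        p = tmp_path / "rf.txt"
        p.write_text(self.ROW.format(strand=".", cs=12, ce=75))
        with pytest.raises(FormatError, match="strand"):
            read_genepred(p)

    def test_exon_count_mismatch_rejected(self, tmp_path):
        p = tmp_path / "rf.txt"
        p.write_text("G1\tNM_1\tchr1\t+\t10\t80\t12\t75\t3\t10,50,\t30,80,\n")
        with pytest.raises(FormatError, match="exonCount"):
            read_genepred(p)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000>\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="AC">\n'
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="AN">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestVcf:
    def test_af_and_multiallelic_split(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "chr1\t11\t.\tA\tG\t.\tPASS\tAF=0.97\n"
            + "chr1\t21\t.\tA\tG,T\t.\tPASS\tAF=0.5,0.3\n"
        )
        recs = read_vcf_biallelic(p, "panel")
        assert len(recs) == 3
        assert recs[0].pos == 10 and recs[0].aaf == pytest.approx(0.97)
        assert not recs[0].multiallelic_origin
        assert recs[1].multiallelic_origin and recs[2].multiallelic_origin
        assert (recs[1].alt_base, recs[2].alt_base) == ("G", "T")
        assert (recs[1].aaf, recs[2].aaf) == (pytest.approx(0.5), pytest.approx(0.3))

    def test_ac_an_fallback_and_skip(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "chr1\t11\t.\tA\tG\t.\tPASS\tAC=10;AN=100\n"
            + "chr1\t21\t.\tA\tG\t.\tPASS\t.\n"  # neither AF nor AC/AN: skipped
        )
        recs = read_vcf_biallelic(p, "panel")
        assert len(recs) == 1 and recs[0].aaf == pytest.approx(0.1)

    def test_non_snv_alleles_dropped_and_count_contract(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "chr1\t11\t.\tA\tG,AT\t.\tPASS\tAF=0.2,0.1\n"
            + "chr1\t21\t.\tAT\tA\t.\tPASS\tAF=0.3\n"
        )
        recs = read_vcf_biallelic(p, "panel")
        # output count equals the number of (row, alt) SNV pairs
        assert len(recs) == 1 and recs[0].alt_base == "G"


CHAIN_IDENTITY = "chain 100 chr1 1000 + 0 1000 chr1 1000 + 0 1000 1\n1000\n\n"


class TestChain:
    def test_identity_single_block(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text(CHAIN_IDENTITY)
        cm = read_chain(p)
        assert len(cm.blocks) == 1
        b = cm.blocks[0]
        assert (b.source_start, b.source_end, b.target_strand) == (0, 1000, "+")

    def test_negative_strand_target(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 100 chrA 500 + 100 200 chrB 400 - 50 150 1\n100\n\n")
        (b,) = read_chain(p).blocks
        assert b.target_strand == "-"
        # reversed-strand query coordinates converted to forward
        assert (b.target_start, b.target_end) == (250, 350)

    def test_bookkeeping_mismatch_rejected(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 100 chr1 1000 + 0 1000 chr1 1000 + 0 1000 1\n900\n\n")
        with pytest.raises(FormatError, match="bookkeeping"):
            read_chain(p)

    def test_blocks_tile_source_extent(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 9 chr1 100 + 10 70 chr2 100 + 0 55 1\n20 10 5\n30\n\n")
        cm = read_chain(p)
        assert sum(b.source_end - b.source_start for b in cm.blocks) == 50
        assert sum(b.target_end - b.target_start for b in cm.blocks) == 50

    def test_overlapping_source_blocks_rejected(self):
        blocks = [
            ChainBlock("c", 0, 50, "c", 0, 50, "+"),
            ChainBlock("c", 40, 90, "c", 60, 110, "+"),
        ]
        with pytest.raises(FormatError, match="overlap"):
            ChainMap(blocks=blocks)


class TestPileup:
    def test_read_start_markers_stripped(self):
        # hand-parsed: ^] starts a read (marker + mapq char), $ ends one
        entries = decode_pileup_bases("^].,$.Gg*", "A")
        assert entries == [
            ("A", False), ("A", False), ("A", False),
            ("G", False), ("G", False), ("*", False),
        ]

    def test_insertion_flag_and_deletion_descriptor(self):
        entries = decode_pileup_bases(".+2ACt-1a,", "C")
        assert entries == [("C", True), ("T", False), ("C", False)]

    def test_hand_parsed_fixture(self, tmp_path):
        p = tmp_path / "p.txt"
        p.write_text(
            "chr1\t100\tA\t4\t..Gg\tIIII\n"
            "chr1\t101\tC\t3\t^].,T\tII#\tAA]\n"
            "chr2\t50\tG\t2\t.a\tII\n"
            "chr2\t51\tT\t1\t*\tI\n"
            "chr2\t52\tT\t2\t.$.\tII\n"
        )
        rows = read_pileup(p)
        assert [r.pos for r in rows] == [99, 100, 49, 50, 51]
        assert rows[1].map_quals == "AA]"
        assert rows[3].bases == "*"

    def test_bad_character_rejected(self):
        with pytest.raises(FormatError):
            decode_pileup_bases(".?,", "A")


class TestReports:
    def test_round_trip_byte_for_byte(self, tmp_path):
        rows = [
            {"a": "1", "b": "x"},
            {"a": "2", "b": "y z"},
        ]
        p1, p2 = tmp_path / "r1.tsv", tmp_path / "r2.tsv"
        write_report(rows, p1)
        write_report(read_report(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSiteRecord:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SiteRecord("chr1", 10, "A", "A", 0.5, "p")
        with pytest.raises(ValueError):
            SiteRecord("chr1", 10, "A", "G", 1.5, "p")
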