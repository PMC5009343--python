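"""Spliced CDS extraction, comparison, locus choice and class reconciliation."""

import pytest

from refconcord.geneloci import (
    align_correspondence, best_locus_comparison, compare_cds, compare_to_model,
    extract_spliced_cds, find_best_locus, mini_spliced_match, reconcile_classes,
    report_missing_segments,
)
from refconcord.refio import Assembly, GeneModel, TranscriptSeq, revcomp

from conftest import dp_spliced_counts


def asm(seq, name="chr1", canonical=("chr1",), **extra):
    seqs = {name: seq, **extra}
    return Assembly("a", seqs, frozenset(c for c in canonical if c in seqs))


def model(exons, cds, strand="+", chrom="chr1", tid="t", source="UCSC"):
    return GeneModel(tid, "g", chrom, strand, exons, cds[0], cds[1], source)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestExtract:
    def test_single_exon_plus_and_minus(self):
        a = asm("CCCATGTAA")
        m = model([(0, 9)], (3, 9))
        assert extract_spliced_cds(m, a) == "ATGTAA"
        m2 = model([(0, 9)], (3, 9), strand="-")
        assert extract_spliced_cds(m2, a) == "TTACAT"

    def test_intron_skipped_matches_masking_oracle(self, rng):
        seq = random_dna(rng, 300)
        a = asm(seq)
        m = model([(10, 60), (100, 170), (200, 260)], (25, 230))
        # oracle: mask intronic/UTR positions and read off the rest
        keep = sorted(
            p for s, e in m.exons for p in range(s, e) if 25 <= p < 230
        )
        assert extract_spliced_cds(m, a) == "".join(seq[p] for p in keep)

    def test_strand_involution(self, rng):
        seq = random_dna(rng, 200)
        a_fwd = asm(seq)
        a_rev = asm(revcomp(seq))
        n = len(seq)
        m_plus = model([(20, 60), (90, 140)], (25, 130))
        mirrored = [(n - e, n - s) for s, e in reversed(m_plus.exons)]
        m_minus = model(mirrored, (n - 130, n - 25), strand="-")
        assert extract_spliced_cds(m_plus, a_fwd) == extract_spliced_cds(m_minus, a_rev)

    def test_bounds_error(self):
        a = asm("ACGT")
        with pytest.raises(ValueError, match="exceed"):
            extract_spliced_cds(model([(0, 10)], (0, 10)), a)


class TestCompare:
    def test_identical_is_class_1(self, rng):
        cds = random_dna(rng, 300)
        c = compare_cds(cds, cds, list(range(300)), model=model([(0, 300)], (0, 300)))
        assert (c.cds_class, c.n_mismatch, c.n_missing) == (1, 0, 0)

    def test_single_substitution_is_class_2(self, rng):
        g = random_dna(rng, 300)
        m = g[:150] + ("A" if g[150] != "A" else "C") + g[151:]
        c = compare_cds(m, g, list(range(300)), model=model([(0, 300)], (0, 300)))
        assert c.cds_class == 2
        assert c.mismatches == [(150, g[150], m[150], 150)]

    def test_inserted_gga_is_class_3(self):
        genome = "ATGAAATTTTAA"
        mrna = "ATGAAAGGATTTTAA"
        corr = align_correspondence(mrna, genome)
        c = compare_cds(mrna, genome, corr, model=model([(0, 12)], (0, 12)))
        assert c.cds_class == 3
        assert c.n_missing == 3 and c.n_mismatch == 0
        assert [b for _, b in c.missing_segments] == ["GGA"]

    def test_genome_only_bases_are_not_mismatches(self):
        # genome longer than mRNA: the extra run reads as an intronic gap
        mrna = "ATGAAATTTTAA"
        genome = "ATGAAACCCCCCCCCCCCCCCCCCCCCCCCTTTTAA"
        corr = align_correspondence(mrna, genome)
        c = compare_cds(mrna, genome, corr, model=model([(0, 36)], (0, 36)))
        assert (c.cds_class, c.n_mismatch, c.n_missing) == (1, 0, 0)

    def test_partial_correspondence_is_contract_error(self):
        with pytest.raises(ValueError, match="correspondence"):
            compare_cds("ACGT", "ACGT", [0, 1, 2])


class TestBestLocus:
    def _setup(self, rng):
        cds = "ATG" + random_dna(rng, 294) + "TAA"
        filler = random_dna(rng, 1000)
        chr1 = filler[:200] + cds + filler[200:500]
        mutated = cds[:50] + ("A" if cds[50] != "A" else "C") + cds[51:]
        chr1 += random_dna(rng, 50) + mutated + random_dna(rng, 50)
        alt = random_dna(rng, 100) + cds + random_dna(rng, 100)
        a = Assembly("a", {"chr1": chr1, "chr1_alt": alt}, frozenset({"chr1"}))
        mrna = TranscriptSeq("t", cds)
        exact = model([(200, 500)], (200, 500))
        worse_start = 200 + 300 + 500 + 50
        worse = model([(worse_start, worse_start + 300)], (worse_start, worse_start + 300))
        on_alt = model([(100, 400)], (100, 400), chrom="chr1_alt")
        return a, mrna, exact, worse, on_alt

    def test_minimal_score_wins(self, rng):
        a, mrna, exact, worse, _ = self._setup(rng)
        assert find_best_locus(mrna, [worse, exact], a) is exact

    def test_canonical_preferred_on_tie(self, rng):
        a, mrna, exact, _, on_alt = self._setup(rng)
        assert find_best_locus(mrna, [on_alt, exact], a) is exact

    def test_no_candidates_is_class_4(self, rng):
        _, mrna, *_ = self._setup(rng)
        c = best_locus_comparison(mrna, [], asm("ACGTACGT"))
        assert c.cds_class == 4 and c.model is None

    def test_deterministic_tie_break_by_coordinates(self, rng):
        cds = "ATG" + random_dna(rng, 60) + "TAA"
        seq = random_dna(rng, 50) + cds + random_dna(rng, 30) + cds + random_dna(rng, 30)
        a = asm(seq)
        m1 = model([(50, 50 + 66)], (50, 50 + 66))
        m2 = model([(146, 146 + 66)], (146, 146 + 66))
        best = find_best_locus(TranscriptSeq("t", cds), [m2, m1], a)
        assert best is m1  # smaller cds_start


class TestReconcile:
    @pytest.mark.parametrize(
        "per_source,final,source",
        [
            ({"CCDS": 2, "UCSC": 1, "ALIGNER": 1}, 2, "CCDS"),
            ({"CCDS": 4, "UCSC": 3, "ALIGNER": 2}, 2, "ALIGNER"),
            ({"UCSC": 4, "ALIGNER": 4}, 4, "UCSC"),
            ({"CCDS": 4, "UCSC": 2, "ALIGNER": 2}, 2, "UCSC"),
        ],
    )
    def test_rules(self, per_source, final, source):
        a = reconcile_classes(per_source)
        assert (a.final_class, a.chosen_source) == (final, source)
        assert a.final_class in per_source.values()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reconcile_classes({})


class TestMiniSplicedMatch:
    def _planted(self, rng, n_exons=3, sub_at=None):
        cds = "ATG" + random_dna(rng, 294) + "TAA"
        chrom = list(random_dna(rng, 20000))
        sizes = [100, 100, 100]
        start = 5000
        coords = []
        cur = start
        pieces = [cds[:100], cds[100:200], cds[200:]]
        for j, sz in enumerate(sizes):
            coords.append((cur, cur + sz))
            for k in range(sz):
                chrom[cur + k] = pieces[j][k]
            if j < n_exons - 1:
                intron = int(rng.integers(80, 400))
                chrom[cur + sz], chrom[cur + sz + 1] = "G", "T"
                chrom[cur + sz + intron - 2], chrom[cur + sz + intron - 1] = "A", "G"
                cur += sz + intron
        a = asm("".join(chrom))
        mrna = cds
        if sub_at is not None:
            b = "A" if cds[sub_at] != "A" else "C"
            mrna = cds[:sub_at] + b + cds[sub_at + 1 :]
        return a, mrna, coords

    def test_planted_cds_recovered_exactly(self, rng):
        a, mrna, coords = self._planted(rng)
        (m,) = mini_spliced_match(mrna, a, transcript_id="t")
        assert m.exons == coords and m.strand == "+"
        c = compare_to_model(TranscriptSeq("t", mrna), m, a)
        assert c.cds_class == 1

    def test_planted_with_substitution(self, rng):
        a, mrna, _ = self._planted(rng, sub_at=150)
        models = mini_spliced_match(mrna, a, transcript_id="t")
        assert models
        c = best_locus_comparison(TranscriptSeq("t", mrna), models, a)
        assert (c.cds_class, c.n_mismatch) == (2, 1)
        assert c.mismatches[0][3] == 150

    def test_minus_strand_recovery(self, rng):
        a, mrna, coords = self._planted(rng)
        a_rc = asm(revcomp(a.sequences["chr1"]))
        models = mini_spliced_match(mrna, a_rc, transcript_id="t")
        assert models and models[0].strand == "-"
        c = best_locus_comparison(TranscriptSeq("t", mrna), models, a_rc)
        assert c.cds_class == 1

    def test_absent_cds_yields_no_models(self, rng):
        a = asm(random_dna(rng, 20000))
        mrna = "ATG" + random_dna(rng, 294) + "TAA"
        assert mini_spliced_match(mrna, a, transcript_id="t") == []

    def test_query_shorter_than_seed_rejected(self, rng):
        with pytest.raises(ValueError):
            mini_spliced_match("ACGT", asm(random_dna(rng, 100)))


class TestDPOracleEquivalence:
    """The seed-and-chain route must agree with brute-force DP alignment."""

    @pytest.mark.parametrize("case", ["exact", "subs", "insertion", "one_exon_sub"])
    def test_counts_match_dp(self, case, rng):
        cds = "ATG" + random_dna(rng, 294) + "TAA"
        chrom = list(random_dna(rng, 4000))
        pieces = [cds[:120], cds[120:210], cds[210:]]
        cur = 500
        for j, piece in enumerate(pieces):
            for k, ch in enumerate(piece):
                chrom[cur + k] = ch
            if j < 2:
                intron = 150
                chrom[cur + len(piece)] = "G"
                chrom[cur + len(piece) + 1] = "T"
                chrom[cur + len(piece) + intron - 2] = "A"
                chrom[cur + len(piece) + intron - 1] = "G"
                cur += len(piece) + intron
        genome = "".join(chrom)
        a = asm(genome)
        mrna = cds
        if case == "subs":
            for p in (50, 160, 260):
                mrna = mrna[:p] + ("A" if mrna[p] != "A" else "C") + mrna[p + 1 :]
        elif case == "insertion":
            mrna = mrna[:150] + "GGATTC" + mrna[150:]
        elif case == "one_exon_sub":
            mrna = mrna[:40] + ("G" if mrna[40] != "G" else "T") + mrna[41:]
        models = mini_spliced_match(mrna, a, transcript_id="t")
        assert models
        c = best_locus_comparison(TranscriptSeq("t", mrna), models, a)
        mm, ms = dp_spliced_counts(mrna, genome)
        assert (c.n_mismatch, c.n_missing) == (mm, ms)


class TestMissingReport:
    def _cmp(self, tid, segs, chrom="chr2", strand="+"):
        from refconcord.geneloci import LocusComparison

        m = model([(0, 100)], (0, 100), strand=strand, chrom=chrom, tid=tid)
        c = LocusComparison(transcript_id=tid, model=m)
        c.missing_segments.extend(segs)
        return c

    def test_single_inserted_base(self):
        rows = report_missing_segments(
            [self._cmp("NM_1", [(133257520, "G")])], {"NM_1": ("ABO1", "toy gene")}
        )
        assert rows == [
            {
                "gene": "ABO1", "description": "toy gene", "n_missing": 1,
                "chrom": "chr2", "strand": "+", "positions": "133257521:133257521",
                "missing_bases": "G", "mrnas": "NM_1", "in_frame": False,
            }
        ]

    def test_isoforms_merged_and_in_frame_flag(self):
        rows = report_missing_segments(
            [
                self._cmp("NM_1", [(100, "GAGGAGGAGGAG")]),
                self._cmp("NM_2", [(100, "GAGGAGGAGGAG")]),
            ],
            {"NM_1": ("G1", ""), "NM_2": ("G1", "")},
        )
        assert len(rows) == 1
        assert rows[0]["n_missing"] == 12
        assert rows[0]["in_frame"] is True
        assert rows[0]["mrnas"] == "NM_1, NM_2"

    def test_in_frame_arithmetic_matches_brute_force(self, rng):
        for n in range(1, 16):
            seg = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            rows = report_missing_segments(
                [self._cmp("NM_1", [(10, seg)])], {"NM_1": ("G", "")}
            )
            assert rows[0]["in_frame"] == (len(seg) % 3 == 0)
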