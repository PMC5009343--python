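"""Coordinate lifting, inversion detection and allele reconciliation."""

import pytest

from refconcord.liftmap import (
    detect_inversion, hamming, lift_position, reconcile_alleles,
)
from refconcord.refio import ChainBlock, ChainMap, SiteRecord, revcomp


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestLiftPosition:
    IDENTITY = ChainMap([ChainBlock("chr1", 0, 1000, "chrN", 0, 1000, "+")])

    def test_identity(self):
        assert lift_position(self.IDENTITY, "chr1", 123) == ("chrN", 123, "+")

    def test_gap_and_unknown_chrom_unmapped(self):
        cm = ChainMap([
            ChainBlock("chr1", 0, 100, "chrN", 0, 100, "+"),
            ChainBlock("chr1", 200, 300, "chrN", 150, 250, "+"),
        ])
        assert lift_position(cm, "chr1", 150) is None
        assert lift_position(cm, "chr2", 50) is None
        assert lift_position(cm, "chr1", 250) == ("chrN", 200, "+")

    def test_minus_strand_mirrors_within_block(self):
        cm = ChainMap([ChainBlock("chr1", 100, 200, "chrN", 500, 600, "-")])
        assert lift_position(cm, "chr1", 100) == ("chrN", 599, "-")
        assert lift_position(cm, "chr1", 199) == ("chrN", 500, "-")

    def test_round_trip_through_inverse_chain(self, rng):
        blocks = [
            ChainBlock("chr1", 0, 400, "chrN", 100, 500, "+"),
            ChainBlock("chr1", 500, 900, "chrN", 600, 1000, "-"),
        ]
        fwd = ChainMap(blocks)
        inv = ChainMap([
            ChainBlock(b.target_chrom, b.target_start, b.target_end,
                       b.source_chrom, b.source_start, b.source_end,
                       b.target_strand)
            for b in blocks
        ])
        positions = rng.integers(0, 900, size=1000)
        for pos in positions:
            mapped = lift_position(fwd, "chr1", int(pos))
            if mapped is None:
                assert 400 <= pos < 500
                continue
            chrom, tpos, _ = mapped
            back = lift_position(inv, chrom, tpos)
            assert back is not None and back[1] == pos


class TestDetectInversion:
    def test_identical_forward_not_inverted(self):
        w = "ACGTACGTACGTACGTACGTA"
        assert detect_inversion(w, w, revcomp(w)) is False

    def test_constructed_inversion_detected(self, rng):
        old = random_dna(rng, 21)
        new = revcomp(old)
        assert detect_inversion(new, old, revcomp(old)) is True

    def test_tie_is_not_inverted(self):
        new = "A" * 21
        fwd = "A" * 10 + "C" * 11
        rev = "C" * 11 + "A" * 10
        assert hamming(new, fwd) == hamming(new, rev)
        assert detect_inversion(new, fwd, rev) is False

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detect_inversion("ACGT", "ACGTA", "ACGTA")

    def test_matches_bruteforce_oracle_on_random_triples(self, rng):
        # oracle: independent distance comparison per triple
        for _ in range(10_000):
            a, f, r = (random_dna(rng, 21) for _ in range(3))
            d_f = sum(x != y for x, y in zip(a, f))
            d_r = sum(x != y for x, y in zip(a, r))
            assert detect_inversion(a, f, r) is (d_r < d_f)


class TestReconcileAlleles:
    def site(self, aaf=0.97):
        return SiteRecord("chr1", 100, "A", "G", aaf, "p")

    def test_no_switch(self):
        ls = reconcile_alleles(self.site(), "A", inverted=False)
        assert not ls.allele_switched and not ls.allele_mismatch
        assert (ls.lifted.ref_base, ls.lifted.alt_base) == ("A", "G")
        assert ls.lifted.aaf == pytest.approx(0.97)

    def test_switch_swaps_alleles_and_frequencies(self):
        ls = reconcile_alleles(self.site(), "G", inverted=False)
        assert ls.allele_switched
        assert (ls.lifted.ref_base, ls.lifted.alt_base) == ("G", "A")
        # frequency conservation: the two allele frequencies still sum to 1
        assert ls.lifted.aaf + ls.source.aaf == pytest.approx(1.0)

    def test_inverted_then_switched(self):
        # A/G complemented to T/C, then the new base C matches alt: switch to C/T
        ls = reconcile_alleles(self.site(), "C", inverted=True)
        assert ls.inverted and ls.allele_switched
        assert (ls.lifted.ref_base, ls.lifted.alt_base) == ("C", "T")
        assert ls.lifted.aaf == pytest.approx(0.03)

    def test_neither_allele_flags_mismatch(self):
        ls = reconcile_alleles(self.site(), "T", inverted=False)
        assert ls.status == "ok" and ls.allele_mismatch and not ls.allele_switched

    def test_reconcile_is_idempotent_with_consistent_base(self):
        ls1 = reconcile_alleles(self.site(), "G", inverted=False)
        ls2 = reconcile_alleles(ls1.lifted, "G", inverted=False)
        assert not ls2.allele_switched
        assert ls2.lifted.ref_base == ls1.lifted.ref_base
        assert ls2.lifted.aaf == pytest.approx(ls1.lifted.aaf)


class TestGeneratorRecovery:
    """Inversion and switch flags recovered exactly from the synthetic chain."""

    def test_flags_match_ground_truth(self, universe):
        from refconcord.liftmap import lift_sites
        from refconcord.refio import load_assembly, read_chain, read_vcf_biallelic

        truth = universe.truth
        sites = read_vcf_biallelic(truth.files["vcf"], "synthpanel")
        chain = read_chain(truth.files["chain"])
        old = load_assembly(truth.files["genome_old"], "old")
        new = load_assembly(truth.files["genome_new"], "new")
        lifted = lift_sites(sites, chain, old, new)
        by_key = {(s.chrom, s.pos, s.alt): s for s in truth.sites}
        n_checked = 0
        for ls in lifted:
            assert ls.status == "ok"
            st = by_key.get((ls.lifted.chrom, ls.lifted.pos, ls.lifted.alt_base))
            if st is None:  # the first allele of a triallelic row has no truth row
                continue
            assert ls.inverted == st.inverted
            assert ls.allele_switched == st.switched
            assert not ls.allele_mismatch
            n_checked += 1
        assert n_checked == len(truth.sites)

    def test_lifted_frequencies_conserve_source_total(self, universe):
        from refconcord.liftmap import lift_sites
        from refconcord.refio import load_assembly, read_chain, read_vcf_biallelic

        truth = universe.truth
        sites = read_vcf_biallelic(truth.files["vcf"], "synthpanel")
        chain = read_chain(truth.files["chain"])
        lifted = lift_sites(
            sites, chain,
            load_assembly(truth.files["genome_old"], "old"),
            load_assembly(truth.files["genome_new"], "new"),
        )
        for ls in lifted:
            ref_freq = 1.0 - ls.lifted.aaf
            source_total = 1.0
            assert ls.lifted.aaf + ref_freq == pytest.approx(source_total, abs=1e-12)
            if ls.allele_switched:
                assert ls.lifted.aaf == pytest.approx(1.0 - ls.source.aaf, abs=1e-12)
            else:
                assert ls.lifted.aaf == pytest.approx(ls.source.aaf, abs=1e-12)
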