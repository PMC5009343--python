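"""Discordant-variant calling and genome/mRNA/protein concordance summaries.

A *discordant variant* is a genomic position at which the reference genome
and the mRNA reference database represent different alleles.  Class-2
transcript mismatches are deduplicated across isoforms into genomic
substitutions, annotated as synonymous or non-synonymous, and joined with
lifted population sites to decide whether each substitution is a known
variant (and whether it matches one alternative of a triallelic site).  For
non-synonymous variants the protein database's allele is determined by exact
full-length match or by a same-length >=95%-identity scan, and the
old-genome / mRNA / protein statuses relative to the current genome are
tabulated over the eight possible concordance categories.  AAF summaries
mirror the standard presentation: 5% density panels, 1% count curves above
50% AAF, and the discordant fraction per 1% bin.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .codonlib import NON_SYNONYMOUS, classify_substitution
from .geneloci import LocusComparison
from .refio import SiteRecord, TranscriptSeq

logger = logging.getLogger("refconcord")

COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

REF, ALT, UNDETERMINED = "Ref", "Alt", "undetermined"

#: Table-1 style category order: (old genome, mRNA db, protein db)
CATEGORY_ORDER: tuple[tuple[str, str, str], ...] = (
    (REF, REF, REF), (ALT, REF, REF), (REF, ALT, REF), (ALT, ALT, REF),
    (REF, REF, ALT), (ALT, REF, ALT), (REF, ALT, ALT), (ALT, ALT, ALT),
)


@dataclass
class DiscordantVariant:
    """One genomic substitution where mRNA and genome disagree.

    Bases are on the genome forward strand; ``strand`` is the transcript
    strand of the member isoforms (used to recover codon context).
    """

    chrom: str
    pos: int
    genome_base: str
    mrna_base: str
    strand: str
    effect: str  # synonymous | non-synonymous
    known: bool = False
    triallelic: bool = False
    aaf_by_panel: dict[str, float] = field(default_factory=dict)
    member_transcripts: list[str] = field(default_factory=list)
    occurrences: list[tuple[str, int]] = field(default_factory=list)  # (tid, cds_offset)
    isoform_conflict: bool = False
    effect_conflict: bool = False


def _mismatch_effect(mrna: TranscriptSeq, cds_offset: int, genome_base_t: str) -> str:
    """Effect of replacing one mRNA CDS base by the genome base (both on the
    transcript strand), in the transcript's reading frame."""
    ci, off = divmod(cds_offset, 3)
    mrna_codon = mrna.cds_sequence[3 * ci : 3 * ci + 3]
    if len(mrna_codon) < 3:
        return NON_SYNONYMOUS  # truncated terminal codon; treat conservatively
    genome_codon = mrna_codon[:off] + genome_base_t + mrna_codon[off + 1 :]
    return classify_substitution(genome_codon, mrna_codon, off)


def call_discordant(
    comparisons: Sequence[LocusComparison],
    sites: Sequence[SiteRecord],
    transcripts: Mapping[str, TranscriptSeq],
) -> list[DiscordantVariant]:
    """Group class-2 mismatches into deduplicated genomic substitutions.

    Mismatches are keyed by (chrom, pos, genome base, mRNA base) on the
    forward strand, so isoforms of the same gene collapse into one variant.
    Two isoforms implying *different* mRNA bases at one position are kept as
    separate variants, both flagged ``isoform_conflict``.  The effect is the
    per-transcript majority (conflicts flagged); known/triallelic status
    comes from the site join.
    """
    site_index: dict[tuple[str, int], list[SiteRecord]] = {}
    for s in sites:
        site_index.setdefault((s.chrom, s.pos), []).append(s)

    variants: dict[tuple[str, int, str, str], DiscordantVariant] = {}
    effects: dict[tuple[str, int, str, str], list[str]] = {}
    for cmp in comparisons:
        if cmp.cds_class != 2 or cmp.model is None:
            continue
        mrna = transcripts[cmp.transcript_id]
        strand = cmp.model.strand
        for gpos, gbase_t, mbase_t, cds_off in cmp.mismatches:
            if strand == "-":
                gbase_f, mbase_f = COMPLEMENT_BASE[gbase_t], COMPLEMENT_BASE[mbase_t]
            else:
                gbase_f, mbase_f = gbase_t, mbase_t
            key = (cmp.model.chrom, gpos, gbase_f, mbase_f)
            v = variants.get(key)
            if v is None:
                v = DiscordantVariant(
                    chrom=cmp.model.chrom, pos=gpos,
                    genome_base=gbase_f, mrna_base=mbase_f,
                    strand=strand, effect="",
                )
                variants[key] = v
                effects[key] = []
            v.member_transcripts.append(cmp.transcript_id)
            v.occurrences.append((cmp.transcript_id, cds_off))
            try:
                effects[key].append(_mismatch_effect(mrna, cds_off, gbase_t))
            except ValueError:
                logger.warning(
                    "%s: non-comparable codon at CDS offset %d", cmp.transcript_id, cds_off
                )

    for key, v in variants.items():
        tally = Counter(effects[key])
        if tally:
            v.effect = tally.most_common(1)[0][0]
            v.effect_conflict = len(tally) > 1
        else:
            v.effect = NON_SYNONYMOUS
        for s in site_index.get((v.chrom, v.pos), []):
            v.aaf_by_panel.setdefault(s.panel, s.aaf)
            if s.alt_base == v.mrna_base and s.ref_base == v.genome_base:
                v.known = True
                if s.multiallelic_origin:
                    v.triallelic = True

    # flag positions where isoforms imply different mRNA bases
    by_pos: dict[tuple[str, int], list[DiscordantVariant]] = {}
    for v in variants.values():
        by_pos.setdefault((v.chrom, v.pos), []).append(v)
    for vs in by_pos.values():
        if len({v.mrna_base for v in vs}) > 1:
            for v in vs:
                v.isoform_conflict = True

    return sorted(variants.values(), key=lambda v: (v.chrom, v.pos, v.mrna_base))


# ---------------------------------------------------------------------------
# Protein database allele
# ---------------------------------------------------------------------------

def sequence_identity(a: str, b: str) -> float:
    """Exact residue matches / length, defined for same-length pairs only."""
    if len(a) != len(b):
        raise ValueError("identity is defined for same-length sequences")
    if not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def protein_allele_status(
    refseq_protein: str,
    protein_db_entries: Mapping[str, str],
    codon_index: int,
    genome_residue: str,
    alt_residue: str,
    min_identity: float = 0.95,
) -> tuple[str, Optional[str]]:
    """Which allele does the protein database carry at a variant codon?

    An exact full-length match supports the mRNA translation at every
    position; otherwise the best same-length entry with identity >=
    ``min_identity`` is compared position-wise and its residue at the
    variant codon decides.  Equal-identity ties prefer the entry whose
    variant-codon residue equals the mRNA translation (conservative toward
    concordance).  Returns (Ref|Alt|undetermined, entry name or None).
    """
    if codon_index >= len(refseq_protein):
        # variant in the (stripped) terminal stop codon: no residue to compare
        return UNDETERMINED, None
    mrna_residue = refseq_protein[codon_index]
    best: Optional[tuple[float, int, str]] = None
    for name, seq in protein_db_entries.items():
        if len(seq) != len(refseq_protein):
            continue
        ident = sequence_identity(refseq_protein, seq)
        if ident < min_identity:
            continue
        tie_pref = 1 if (codon_index < len(seq) and seq[codon_index] == mrna_residue) else 0
        cand = (ident, tie_pref, name)
        if best is None or cand > best:
            best = cand
    if best is None:
        return UNDETERMINED, None
    name = best[2]
    residue = protein_db_entries[name][codon_index]
    if residue == genome_residue:
        return REF, name
    if residue == alt_residue:
        return ALT, name
    return UNDETERMINED, name


# ---------------------------------------------------------------------------
# Concordance table
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceRow:
    """Per-SNV allele status of each database relative to the current genome.

    'Ref' means the column's reference sequence matches the current genome
    base; 'Alt' means it carries the alternative allele.
    """

    chrom: str
    pos: int
    status_old_genome: str
    status_mrna: str
    status_protein: str
    aaf: float


def concordance_table(rows: Sequence[ConcordanceRow]) -> dict[tuple[str, str, str], int]:
    """Occurrence counts over the 2^3 (old genome, mRNA, protein) categories.

    Every category is present in the result, zero when unobserved.  Rows
    with an undetermined protein status are excluded.
    """
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for r in rows:
        key = (r.status_old_genome, r.status_mrna, r.status_protein)
        if UNDETERMINED in key:
            continue
        counts[key] += 1
    return counts


# ---------------------------------------------------------------------------
# AAF histograms
# ---------------------------------------------------------------------------

@dataclass
class HistogramSummary:
    """Binned AAF summary for one stratum.

    Bins are half-open [lo, hi) with the final bin closed.  ``densities``
    are counts normalised to sum to 1 over the stratum (zeros when empty).
    """

    stratum: str
    bin_edges: np.ndarray
    counts: np.ndarray
    densities: np.ndarray

    def to_rows(self) -> list[dict[str, object]]:
        return [
            {
                "stratum": self.stratum,
                "bin_lo": f"{self.bin_edges[i]:.2f}",
                "bin_hi": f"{self.bin_edges[i + 1]:.2f}",
                "count": int(self.counts[i]),
                "density": f"{self.densities[i]:.6g}",
            }
            for i in range(len(self.counts))
        ]


def _histogram(aafs: Sequence[float], lo: float, hi: float, width: float, stratum: str) -> HistogramSummary:
    edges = np.round(np.arange(lo, hi + width / 2, width), 10)
    counts, _ = np.histogram(np.asarray(list(aafs), dtype=float), bins=edges)
    total = counts.sum()
    dens = counts / total if total else np.zeros_like(counts, dtype=float)
    return HistogramSummary(stratum=stratum, bin_edges=edges, counts=counts, densities=dens)


def aaf_histograms(
    all_sites: Sequence[tuple[float, str]],
    discordant_sites: Sequence[tuple[float, str]],
) -> dict[str, HistogramSummary]:
    """AAF summaries for all-vs-discordant x synonymous-vs-non-synonymous.

    Inputs are (aaf, effect) pairs over biallelic sites.  Produces, per
    effect stratum: 5% density panels ("all"/"disc"), 1% count curves for
    AAF > 50%, and the discordant fraction per 1% bin (0 when the
    denominator is 0).
    """
    out: dict[str, HistogramSummary] = {}
    for effect in ("synonymous", "non-synonymous"):
        allv = [a for a, e in all_sites if e == effect]
        disc = [a for a, e in discordant_sites if e == effect]
        out[f"all:{effect}:5pct"] = _histogram(allv, 0.0, 1.0, 0.05, f"all:{effect}:5pct")
        out[f"disc:{effect}:5pct"] = _histogram(disc, 0.0, 1.0, 0.05, f"disc:{effect}:5pct")
        h_all = _histogram(allv, 0.5, 1.0, 0.01, f"all:{effect}:1pct_high")
        h_disc = _histogram(disc, 0.5, 1.0, 0.01, f"disc:{effect}:1pct_high")
        out[h_all.stratum] = h_all
        out[h_disc.stratum] = h_disc
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(h_all.counts > 0, h_disc.counts / np.maximum(h_all.counts, 1), 0.0)
        out[f"fraction:{effect}:1pct_high"] = HistogramSummary(
            stratum=f"fraction:{effect}:1pct_high",
            bin_edges=h_all.bin_edges,
            counts=h_disc.counts,
            densities=frac,
        )
    return out
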