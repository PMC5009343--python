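"""RNA-editing evidence at discordant sites unexplained by known variants.

A-to-I editing reads out as A-to-G: where the genome has A on the transcript
strand but the mRNA database has G, and no population variant is known at
the position, aligned RNA-seq reads carrying G are evidence that the mRNA
base arose post-transcriptionally.  Pileup bases are filtered with mapping
quality >= 30, base quality >= 30, and reads carrying an insertion at the
position are excluded; the retained G fraction on the transcript strand is
tiered at 0.05 (strong) and 0.01 (weak).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .refio import PileupRow, PileupSite, decode_pileup_bases

COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}

TIER_STRONG, TIER_WEAK, TIER_NONE = "editing-strong", "editing-weak", "none"

DEFAULT_THRESHOLDS = (0.05, 0.01)


@dataclass
class EditingCall:
    site: tuple[str, int]
    genome_base: str  # transcript strand
    mrna_base: str  # transcript strand
    counts: Optional[PileupSite]
    genome_fraction: float
    mrna_fraction: float
    tier: str
    flags: list[str] = field(default_factory=list)


def filter_and_count(row: PileupRow, min_mapq: int = 30, min_baseq: int = 30) -> PileupSite:
    """Decode one pileup row into filtered per-base counts.

    Reads are excluded in order: mapping quality < ``min_mapq``, base
    quality < ``min_baseq``, insertion at the position.  Deletion
    placeholders (*) and N bases are dropped without being counted as
    exclusions.  Qualities are Phred+33; counts are on the reference-forward
    orientation.
    """
    entries = decode_pileup_bases(row.bases, row.ref)
    if len(entries) != len(row.base_quals):
        raise ValueError(
            f"{row.chrom}:{row.pos + 1}: {len(entries)} bases vs "
            f"{len(row.base_quals)} base-quality chars"
        )
    if row.map_quals is not None and len(row.map_quals) != len(entries):
        raise ValueError(f"{row.chrom}:{row.pos + 1}: mapping-quality column length mismatch")
    counts: dict[str, int] = {}
    n_mapq = n_baseq = n_ins = 0
    for i, (base, has_ins) in enumerate(entries):
        if row.map_quals is not None and ord(row.map_quals[i]) - 33 < min_mapq:
            n_mapq += 1
            continue
        if ord(row.base_quals[i]) - 33 < min_baseq:
            n_baseq += 1
            continue
        if has_ins:
            n_ins += 1
            continue
        if base in "ACGT":
            counts[base] = counts.get(base, 0) + 1
    return PileupSite(
        chrom=row.chrom,
        pos=row.pos,
        counts=counts,
        n_excluded_mapq=n_mapq,
        n_excluded_baseq=n_baseq,
        n_excluded_insertion=n_ins,
    )


def pool_counts(sites: Sequence[PileupSite]) -> PileupSite:
    """Sum filtered counts over individuals covering the same position."""
    if not sites:
        raise ValueError("nothing to pool")
    first = sites[0]
    if any((s.chrom, s.pos) != (first.chrom, first.pos) for s in sites):
        raise ValueError("pooling requires a single position")
    counts: dict[str, int] = {}
    for s in sites:
        for b, n in s.counts.items():
            counts[b] = counts.get(b, 0) + n
    return PileupSite(
        chrom=first.chrom,
        pos=first.pos,
        counts=counts,
        n_excluded_mapq=sum(s.n_excluded_mapq for s in sites),
        n_excluded_baseq=sum(s.n_excluded_baseq for s in sites),
        n_excluded_insertion=sum(s.n_excluded_insertion for s in sites),
    )


def call_editing(
    variants: Sequence,
    pileup_sites: Mapping[tuple[str, int], PileupSite],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> list[EditingCall]:
    """Tier unexplained discordant substitutions by transcript-strand G fraction.

    ``variants`` need (chrom, pos, genome_base, mrna_base, strand, known)
    attributes (forward-strand bases, as produced by discordance calling).
    Only genome-A-to-mRNA-G substitutions on the transcript strand at
    positions with no known variant are eligible for an editing tier; other
    substitutions are reported with their counts and tier ``none``.  The
    thresholds (strong, weak) are inclusive.
    """
    strong, weak = thresholds
    calls: list[EditingCall] = []
    for v in variants:
        if v.strand == "-":
            g_t, m_t = COMPLEMENT_BASE[v.genome_base], COMPLEMENT_BASE[v.mrna_base]
        else:
            g_t, m_t = v.genome_base, v.mrna_base
        eligible = (g_t, m_t) == ("A", "G") and not v.known
        pile = pileup_sites.get((v.chrom, v.pos))
        flags: list[str] = []
        if pile is None or pile.depth == 0:
            if eligible:
                flags.append("no-coverage")
            calls.append(
                EditingCall(
                    site=(v.chrom, v.pos), genome_base=g_t, mrna_base=m_t,
                    counts=pile, genome_fraction=0.0, mrna_fraction=0.0,
                    tier=TIER_NONE, flags=flags,
                )
            )
            continue
        # complement counts onto the transcript strand for minus-strand genes
        if v.strand == "-":
            counts_t = {COMPLEMENT_BASE[b]: n for b, n in pile.counts.items()}
        else:
            counts_t = pile.counts
        depth = sum(counts_t.values())
        g_frac = counts_t.get(g_t, 0) / depth
        m_frac = counts_t.get(m_t, 0) / depth
        if not eligible:
            tier = TIER_NONE
        elif m_frac >= strong:
            tier = TIER_STRONG
        elif m_frac >= weak:
            tier = TIER_WEAK
        else:
            tier = TIER_NONE
        calls.append(
            EditingCall(
                site=(v.chrom, v.pos), genome_base=g_t, mrna_base=m_t,
                counts=pile, genome_fraction=g_frac, mrna_fraction=m_frac,
                tier=tier, flags=flags,
            )
        )
    return calls
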