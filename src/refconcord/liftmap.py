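"""Mapping variant sites between assembly versions.

Positions are lifted through chain-file alignment blocks.  Because some
regions are inverted between assembly versions, the 21-nucleotide context
(ten bases each side) around each lifted variant is compared against the
old assembly's forward and reverse strands: when the new-assembly context is
strictly more similar to the old reverse strand, the site is flagged
inverted and its alleles complemented.  Afterwards, if the new assembly's
base equals the (possibly complemented) alternative allele, the reference
and alternative alleles have switched roles between versions, so alleles and
their frequencies are swapped (AAF becomes 1 - AAF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .refio import Assembly, ChainMap, SiteRecord, revcomp

logger = logging.getLogger("refconcord")

COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: flank width (bases each side) of the inversion-detection context window
INVERSION_FLANK = 10


@dataclass
class LiftedSite:
    """A source site carried to the new assembly with allele adjustments."""

    source: SiteRecord
    target_chrom: Optional[str] = None
    target_pos: Optional[int] = None
    inverted: bool = False
    allele_switched: bool = False
    allele_mismatch: bool = False
    lifted: Optional[SiteRecord] = None
    status: str = "ok"  # ok | unmapped


def lift_position(chain: ChainMap, chrom: str, pos: int) -> Optional[tuple[str, int, str]]:
    """Map a 0-based source position through the chain.

    Positions inside an alignment block map affinely (mirror-wise within
    minus-strand blocks); positions in inter-block gaps are unmapped (None).
    """
    block = chain.block_at(chrom, pos)
    if block is None:
        return None
    off = pos - block.source_start
    if block.target_strand == "+":
        return block.target_chrom, block.target_start + off, "+"
    return block.target_chrom, block.target_end - 1 - off, "-"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"window length mismatch ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def detect_inversion(seq_new_window: str, seq_old_fwd_window: str,
                     seq_old_rev_window: str) -> bool:
    """True iff the new-assembly context is strictly closer (Hamming) to the
    old assembly's reverse strand than to its forward strand; ties are not
    inverted."""
    d_fwd = hamming(seq_new_window, seq_old_fwd_window)
    d_rev = hamming(seq_new_window, seq_old_rev_window)
    return d_rev < d_fwd


def reconcile_alleles(site: SiteRecord, target_base_at_pos: str, inverted: bool) -> LiftedSite:
    """Adjust a lifted site's alleles against the new assembly's base.

    Inverted sites first have both alleles complemented.  If the new base
    then equals the alternative allele, ref/alt have switched between
    versions: alleles are swapped and the AAF becomes 1 - AAF.  A new base
    matching neither allele keeps status ok but is flagged
    ``allele_mismatch`` (such sites are excluded from concordance tallies).
    """
    ref, alt = site.ref_base, site.alt_base
    if inverted:
        ref, alt = COMPLEMENT_BASE[ref], COMPLEMENT_BASE[alt]
    switched = False
    mismatch = False
    aaf = site.aaf
    if target_base_at_pos == alt:
        ref, alt = alt, ref
        aaf = 1.0 - aaf
        switched = True
    elif target_base_at_pos != ref:
        mismatch = True
    lifted = SiteRecord(
        chrom=site.chrom,
        pos=site.pos,
        ref_base=ref,
        alt_base=alt,
        aaf=aaf,
        panel=site.panel,
        multiallelic_origin=site.multiallelic_origin,
    )
    return LiftedSite(
        source=site,
        inverted=inverted,
        allele_switched=switched,
        allele_mismatch=mismatch,
        lifted=lifted,
        status="ok",
    )


def lift_sites(
    sites: Sequence[SiteRecord],
    chain: ChainMap,
    old_assembly: Assembly,
    new_assembly: Assembly,
) -> list[LiftedSite]:
    """Lift sites to the new assembly with inversion and switch handling.

    Context windows are truncated symmetrically near contig ends, using the
    largest flank shared by both assemblies, so the compared windows always
    have equal length.  Tie counts of the inversion comparison are logged.
    """
    out: list[LiftedSite] = []
    n_ties = 0
    for site in sites:
        mapped = lift_position(chain, site.chrom, site.pos)
        if mapped is None:
            out.append(LiftedSite(source=site, status="unmapped"))
            continue
        t_chrom, t_pos, _ = mapped
        w_new, k_new = new_assembly.window(t_chrom, t_pos, INVERSION_FLANK)
        w_old, k_old = old_assembly.window(site.chrom, site.pos, INVERSION_FLANK)
        k = min(k_new, k_old)
        if k < k_new:
            c = k_new - k
            w_new = w_new[c:-c]
        if k < k_old:
            c = k_old - k
            w_old = w_old[c:-c]
        w_old_rev = revcomp(w_old)
        d_fwd = hamming(w_new, w_old)
        d_rev = hamming(w_new, w_old_rev)
        if d_fwd == d_rev:
            n_ties += 1
        inverted = d_rev < d_fwd
        lifted = reconcile_alleles(site, new_assembly.base(t_chrom, t_pos), inverted)
        lifted.target_chrom, lifted.target_pos = t_chrom, t_pos
        lifted.lifted.chrom, lifted.lifted.pos = t_chrom, t_pos
        out.append(lifted)
    if n_ties:
        logger.info("inversion detection: %d window-distance ties (treated as not inverted)", n_ties)
    return out
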