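"""Readers and writers for the external formats the pipeline touches.

Every downstream module consumes only the domain types defined here:
:class:`Assembly`, :class:`GeneModel`, :class:`TranscriptSeq`,
:class:`SiteRecord`, :class:`ChainMap` and :class:`PileupRow`/:class:`PileupSite`.

Coordinate convention
---------------------
All in-memory coordinates are 0-based half-open.  VCF and pileup positions
are converted on read (``pos - 1``) and on write (``pos + 1``); refFlat and
chain files are already 0-based half-open and are kept as-is.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

logger = logging.getLogger("refconcord")

DNA_ALPHABET = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: canonical human-style chromosome names: autosomes plus the two sex
#: chromosomes; everything else (alt loci, unplaced scaffolds) is
#: non-canonical for locus tie-breaking.
CANONICAL_HUMAN = frozenset({f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY"})


class FormatError(ValueError):
    """A file violated its declared format."""


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Assembly:
    """A genome assembly: named chromosome sequences plus the canonical set.

    ``sequences`` holds uppercase DNA over {A,C,G,T,N}; ``canonical_set`` is
    the subset of chromosome names considered canonical (autosomes + sex
    chromosomes as opposed to alternative loci and unplaced scaffolds).
    """

    name: str
    sequences: dict[str, str]
    canonical_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.canonical_set) - set(self.sequences)
        if bad:
            raise ValueError(f"canonical chromosomes absent from assembly: {sorted(bad)}")

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]

    def window(self, chrom: str, pos: int, flank: int) -> tuple[str, int]:
        """Sequence around ``pos`` with up to ``flank`` bases each side.

        Truncated symmetrically at contig ends: both sides use the largest
        shared flank that fits.  Returns (window, actual_flank).
        """
        seq = self.sequences[chrom]
        k = min(flank, pos, len(seq) - 1 - pos)
        return seq[pos - k : pos + k + 1], k


@dataclass
class GeneModel:
    """One transcript locus: exon structure, CDS bounds, strand, provenance.

    Coordinates are 0-based half-open genome positions; exons are sorted and
    non-overlapping.  ``source`` records which annotation produced the model
    (UCSC refFlat, CCDS, or the built-in spliced aligner).
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    source: str  # UCSC | CCDS | ALIGNER

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.transcript_id}: invalid strand {self.strand!r}")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if not (a < b <= c < d):
                raise FormatError(f"{self.transcript_id}: exons not sorted/disjoint")

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    def cds_exons(self) -> list[tuple[int, int]]:
        """Exon pieces clipped to [cds_start, cds_end)."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out


@dataclass
class TranslationExceptions:
    """Irregular-translation flags carried by a transcript.

    ``frameshift_offset`` is (0-based CDS position, shift in {-1,+1}) where a
    ribosomal slip changes the reading frame; ``stop_codon_redefined_to_sec``
    lists codon indices whose TAG encodes selenocysteine; ``non_atg_start``
    forces the first residue to Met.
    """

    frameshift_offset: Optional[tuple[int, int]] = None
    stop_codon_redefined_to_sec: tuple[int, ...] = ()
    non_atg_start: bool = False


@dataclass
class TranscriptSeq:
    """An mRNA's CDS on the transcript strand plus translation exceptions."""

    transcript_id: str
    cds_sequence: str
    exceptions: TranslationExceptions = field(default_factory=TranslationExceptions)

    def __post_init__(self) -> None:
        if len(self.cds_sequence) < 3:
            raise ValueError(f"{self.transcript_id}: CDS shorter than one codon")
        if self.exceptions.frameshift_offset is None and len(self.cds_sequence) % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds_sequence)} not a "
                "multiple of 3 and no frameshift declared"
            )


@dataclass
class SiteRecord:
    """One biallelic variant site (multiallelic rows are split on read).

    ``pos`` is 0-based; ``aaf`` is the alternative allele frequency in the
    panel named by ``panel``; ``multiallelic_origin`` marks records that came
    from a multiallelic VCF row.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    aaf: float
    panel: str
    multiallelic_origin: bool = False

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt ({self.ref_base})")
        if not 0.0 <= self.aaf <= 1.0:
            raise ValueError(f"{self.chrom}:{self.pos}: AAF {self.aaf} outside [0,1]")


@dataclass(frozen=True)
class ChainBlock:
    source_chrom: str
    source_start: int
    source_end: int
    target_chrom: str
    target_start: int
    target_end: int
    target_strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.source_end - self.source_start != self.target_end - self.target_start:
            raise FormatError("chain block source/target lengths differ")


@dataclass
class ChainMap:
    """Ordered, source-disjoint alignment blocks between two assemblies.

    Target coordinates are stored on the target forward strand; a block with
    ``target_strand == '-'`` maps positions mirror-wise within the block.
    """

    blocks: list[ChainBlock]
    _by_chrom: dict[str, tuple[list[int], list[ChainBlock]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        by: dict[str, list[ChainBlock]] = {}
        for b in self.blocks:
            by.setdefault(b.source_chrom, []).append(b)
        self._by_chrom = {}
        for chrom, bl in by.items():
            bl.sort(key=lambda b: b.source_start)
            for x, y in zip(bl, bl[1:]):
                if y.source_start < x.source_end:
                    raise FormatError(f"chain blocks overlap on source {chrom}")
            self._by_chrom[chrom] = ([b.source_start for b in bl], bl)

    def block_at(self, chrom: str, pos: int) -> Optional[ChainBlock]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, bl = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and bl[i].source_start <= pos < bl[i].source_end:
            return bl[i]
        return None


@dataclass
class PileupRow:
    """One raw mpileup-style row, markers not yet decoded.

    ``map_quals`` is the optional per-base mapping-quality column emitted by
    ``samtools mpileup -s``; when absent every read passes the mapq filter.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    depth: int
    bases: str
    base_quals: str
    map_quals: Optional[str] = None


@dataclass
class PileupSite:
    """Filtered base counts at one genomic position (forward orientation)."""

    chrom: str
    pos: int  # 0-based
    counts: dict[str, int]
    n_excluded_mapq: int = 0
    n_excluded_baseq: int = 0
    n_excluded_insertion: int = 0

    def __post_init__(self) -> None:
        if not set(self.counts) <= set("ACGT"):
            raise ValueError(f"pileup counts contain non-ACGT keys: {self.counts}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative pileup count")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}.

    Sequences are case-folded to upper; any character outside {A,C,G,T,N}
    (including other IUPAC ambiguity codes) raises :class:`FormatError`
    naming the offending line.
    """
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        if name is None:
            return
        if not chunks:
            raise FormatError(f"{path}:{header_line}: empty record {name!r}")
        sequences[name] = "".join(chunks)

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(i)
                name = line[1:].split()[0] if line[1:].strip() else None
                if name is None:
                    raise FormatError(f"{path}:{i}: FASTA header with no name")
                if name in sequences:
                    raise FormatError(f"{path}:{i}: duplicate record {name!r}")
                header_line = i
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{i}: sequence before any header")
                seq = line.strip().upper()
                if not set(seq) <= DNA_ALPHABET:
                    bad = sorted(set(seq) - DNA_ALPHABET)
                    raise FormatError(
                        f"{path}:{i}: non-ACGTN characters {bad} (ambiguity codes rejected)"
                    )
                chunks.append(seq)
        flush(-1)
    return sequences


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path) -> dict[str, str]:
    """Read a protein FASTA (no alphabet restriction beyond letters/*)."""
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{i}: sequence before any header")
                chunks.append(line.upper())
        if name is not None:
            sequences[name] = "".join(chunks)
    return sequences


def load_assembly(path, name: str, canonical: Optional[Iterable[str]] = None) -> Assembly:
    """Read a genome FASTA into an :class:`Assembly`.

    When ``canonical`` is None, chromosomes matching the human canonical
    naming convention (chr1..chr22, chrX, chrY) are flagged canonical.
    """
    seqs = read_fasta(path)
    if canonical is None:
        canon = frozenset(c for c in seqs if c in CANONICAL_HUMAN)
    else:
        canon = frozenset(canonical)
    return Assembly(name=name, sequences=seqs, canonical_set=canon)


# ---------------------------------------------------------------------------
# refFlat / genePred and CCDS-style tables
# ---------------------------------------------------------------------------

def _int_list(field_val: str, path, line_no: int) -> list[int]:
    try:
        return [int(x) for x in field_val.rstrip(",").split(",") if x != ""]
    except ValueError as exc:
        raise FormatError(f"{path}:{line_no}: bad integer list {field_val!r}") from exc


def read_genepred(path, source_tag: str = "UCSC") -> list[GeneModel]:
    """Read a refFlat/genePred TSV into GeneModels.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds.  Coordinates are kept 0-based
    half-open as in the file; trailing commas in exon lists are tolerated.
    Rows with cdsStart == cdsEnd are returned with ``is_coding`` False and
    should be excluded from CDS analyses by callers.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise FormatError(f"{path}:{i}: expected 11 columns, got {len(f)}")
            gene, tid, chrom, strand = f[0], f[1], f[2], f[3]
            if strand not in "+-":
                raise FormatError(f"{path}:{i}: invalid strand {strand!r}")
            cds_start, cds_end = int(f[6]), int(f[7])
            n_exon = int(f[8])
            starts = _int_list(f[9], path, i)
            ends = _int_list(f[10], path, i)
            if len(starts) != n_exon or len(ends) != n_exon:
                raise FormatError(
                    f"{path}:{i}: exonCount {n_exon} does not match exon lists "
                    f"({len(starts)}/{len(ends)})"
                )
            models.append(
                GeneModel(
                    transcript_id=tid,
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=list(zip(starts, ends)),
                    cds_start=cds_start,
                    cds_end=cds_end,
                    source=source_tag,
                )
            )
    return models


def read_ccds(path) -> list[GeneModel]:
    """Read a CCDS-style TSV into GeneModels (source ``CCDS``).

    Columns (tab-separated, with header): transcript_id, gene, chrom,
    strand, cds_exons, status.  ``cds_exons`` is a comma-separated list of
    ``start-end`` 0-based half-open CDS exon intervals.  Rows whose status is
    not ``Public`` are skipped.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: j for j, c in enumerate(header)}
        required = {"transcript_id", "gene", "chrom", "strand", "cds_exons", "status"}
        if not required <= set(idx):
            raise FormatError(f"{path}: missing columns {sorted(required - set(idx))}")
        for i, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if f[idx["status"]] != "Public":
                continue
            exons = []
            for piece in f[idx["cds_exons"]].rstrip(",").split(","):
                a, b = piece.split("-")
                exons.append((int(a), int(b)))
            models.append(
                GeneModel(
                    transcript_id=f[idx["transcript_id"]],
                    gene=f[idx["gene"]],
                    chrom=f[idx["chrom"]],
                    strand=f[idx["strand"]],
                    exons=exons,
                    cds_start=exons[0][0],
                    cds_end=exons[-1][1],
                    source="CCDS",
                )
            )
    return models


# ---------------------------------------------------------------------------
# mRNA CDS sidecar
# ---------------------------------------------------------------------------

def read_cds_sidecar(path, mrna_sequences: Mapping[str, str]) -> list[TranscriptSeq]:
    """Combine an mRNA FASTA with its CDS-coordinate sidecar TSV.

    Sidecar columns (with header): transcript_id, cds_start, cds_end
    (0-based half-open within the mRNA), and optional exception columns
    ``frameshift`` ("pos:shift"), ``sec_codons`` (comma-separated codon
    indices) and ``non_atg_start`` (0/1).
    """
    out: list[TranscriptSeq] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: j for j, c in enumerate(header)}
        for i, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            tid = f[idx["transcript_id"]]
            if tid not in mrna_sequences:
                raise FormatError(f"{path}:{i}: transcript {tid!r} absent from mRNA FASTA")
            a, b = int(f[idx["cds_start"]]), int(f[idx["cds_end"]])
            seq = mrna_sequences[tid][a:b]
            exc = TranslationExceptions()
            if "frameshift" in idx and f[idx["frameshift"]]:
                p, s = f[idx["frameshift"]].split(":")
                exc.frameshift_offset = (int(p), int(s))
            if "sec_codons" in idx and f[idx["sec_codons"]]:
                exc.stop_codon_redefined_to_sec = tuple(
                    int(x) for x in f[idx["sec_codons"]].split(",")
                )
            if "non_atg_start" in idx and f[idx["non_atg_start"]] == "1":
                exc.non_atg_start = True
            out.append(TranscriptSeq(transcript_id=tid, cds_sequence=seq, exceptions=exc))
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_biallelic(path, panel: str) -> list[SiteRecord]:
    """Read a VCF into biallelic SiteRecords, one per (row, alt) SNV pair.

    Multiallelic rows are split with ``multiallelic_origin=True``.  The AAF
    is taken from the AF INFO key, falling back to AC/AN when AF is absent;
    rows with neither are skipped with a warning.  Non-SNV alleles
    (ref or alt length != 1) are dropped and counted in the log.
    """
    records: list[SiteRecord] = []
    n_non_snv = 0
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            multi = len(alts) > 1
            afs = rec.info.get("AF")
            if afs is None:
                ac, an = rec.info.get("AC"), rec.info.get("AN")
                if ac is None or an in (None, 0):
                    logger.warning(
                        "%s:%d: no AF and no AC/AN; row skipped", rec.chrom, rec.pos
                    )
                    n_skipped += 1
                    continue
                afs = tuple(a / an for a in ac)
            elif not isinstance(afs, tuple):
                afs = (afs,)
            for alt, af in zip(alts, afs):
                if len(rec.ref) != 1 or len(alt) != 1:
                    n_non_snv += 1
                    continue
                records.append(
                    SiteRecord(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,  # to 0-based
                        ref_base=rec.ref.upper(),
                        alt_base=alt.upper(),
                        aaf=float(af),
                        panel=panel,
                        multiallelic_origin=multi,
                    )
                )
    if n_non_snv:
        logger.info("%s: dropped %d non-SNV alleles", path, n_non_snv)
    if n_skipped:
        logger.info("%s: skipped %d rows lacking AF and AC/AN", path, n_skipped)
    return records


def write_vcf(records: Sequence, path, assembly_name: str = "lifted") -> None:
    """Write lifted sites as a plain-text VCF with INV/SWAP INFO flags.

    Accepts :class:`~refconcord.liftmap.LiftedSite` objects (uses the
    post-adjustment record) or bare SiteRecords.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=refconcord lift ({assembly_name})\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternative allele frequency">\n')
        fh.write('##INFO=<ID=INV,Number=0,Type=Flag,Description="Site lies in an inverted region">\n')
        fh.write('##INFO=<ID=SWAP,Number=0,Type=Flag,Description="Ref/alt switched between assemblies">\n')
        fh.write('##INFO=<ID=MISMATCH,Number=0,Type=Flag,Description="New assembly base matches neither allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for item in records:
            site = getattr(item, "lifted", item)
            if site is None:
                continue
            info = [f"AF={site.aaf:.6g}"]
            if getattr(item, "inverted", False):
                info.append("INV")
            if getattr(item, "allele_switched", False):
                info.append("SWAP")
            if getattr(item, "allele_mismatch", False):
                info.append("MISMATCH")
            fh.write(
                f"{site.chrom}\t{site.pos + 1}\t.\t{site.ref_base}\t{site.alt_base}"
                f"\t.\tPASS\t{';'.join(info)}\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

def read_chain(path) -> ChainMap:
    """Parse a UCSC chain file into a :class:`ChainMap`.

    The chain's target side (tName) is treated as the lift source (old
    assembly) and the query side (qName) as the lift target (new assembly),
    matching how over.chain files are oriented for liftOver.  Negative-strand
    query coordinates are converted to the forward strand.
    """
    blocks: list[ChainBlock] = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise FormatError(f"{path}:{i}: expected chain header, got {line!r}")
        f = line.split()
        if len(f) < 12:
            raise FormatError(f"{path}:{i}: truncated chain header")
        (t_name, t_size, t_strand, t_start, t_end) = (
            f[2], int(f[3]), f[4], int(f[5]), int(f[6]),
        )
        (q_name, q_size, q_strand, q_start, q_end) = (
            f[7], int(f[8]), f[9], int(f[10]), int(f[11]),
        )
        if t_strand != "+":
            raise FormatError(f"{path}:{i}: chain target strand must be '+'")
        t_pos, q_pos = t_start, q_start
        while i < n:
            row = lines[i].strip()
            i += 1
            if not row:
                break
            parts = row.split()
            size = int(parts[0])
            if q_strand == "+":
                qs, qe = q_pos, q_pos + size
            else:
                # q coords are on the reversed strand; convert to forward
                qs, qe = q_size - (q_pos + size), q_size - q_pos
            blocks.append(
                ChainBlock(
                    source_chrom=t_name,
                    source_start=t_pos,
                    source_end=t_pos + size,
                    target_chrom=q_name,
                    target_start=qs,
                    target_end=qe,
                    target_strand=q_strand,
                )
            )
            t_pos += size
            q_pos += size
            if len(parts) == 3:
                t_pos += int(parts[1])
                q_pos += int(parts[2])
            elif len(parts) == 1:
                break
            else:
                raise FormatError(f"{path}:{i}: malformed chain data line {row!r}")
        if t_pos != t_end or q_pos != q_end:
            raise FormatError(
                f"{path}: chain bookkeeping mismatch (t {t_pos}!={t_end}, q {q_pos}!={q_end})"
            )
    return ChainMap(blocks=blocks)


# ---------------------------------------------------------------------------
# Pileup text
# ---------------------------------------------------------------------------

def read_pileup(path) -> list[PileupRow]:
    """Read samtools-mpileup-like text into raw rows.

    Columns: chrom, pos (1-based in the file), ref, depth, bases, baseQuals
    and optionally mapQuals (``mpileup -s``).  Positions are converted to
    0-based.
    """
    rows: list[PileupRow] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) not in (6, 7):
                raise FormatError(f"{path}:{i}: expected 6 or 7 columns, got {len(f)}")
            rows.append(
                PileupRow(
                    chrom=f[0],
                    pos=int(f[1]) - 1,
                    ref=f[2].upper(),
                    depth=int(f[3]),
                    bases=f[4],
                    base_quals=f[5],
                    map_quals=f[6] if len(f) == 7 else None,
                )
            )
    return rows


def decode_pileup_bases(bases: str, ref: str):
    """Decode an mpileup base string into per-read entries.

    Returns a list of (base, has_insertion) where ``base`` is the
    forward-strand base ('.'/',' resolved to the reference base, lowercase
    folded to upper) or '*' for a deletion placeholder.  Read-start markers
    (``^`` + mapq char) and end markers (``$``) are stripped; ``+n``/``-n``
    indel descriptors following a base set/clear the insertion flag for that
    read (only insertions are flagged).
    """
    out: list[tuple[str, bool]] = []
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # skip marker + mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in ".,":
            base = ref
        elif c.upper() in "ACGTN":
            base = c.upper()
        elif c == "*":
            base = "*"
        else:
            raise FormatError(f"unexpected pileup character {c!r} at offset {i}")
        i += 1
        has_ins = False
        while i < n and bases[i] in "+-":
            sign = bases[i]
            i += 1
            j = i
            while j < n and bases[j].isdigit():
                j += 1
            length = int(bases[i:j])
            i = j + length
            if sign == "+":
                has_ins = True
        out.append((base, has_ins))
    return out


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_report(rows: Sequence[Mapping[str, object]], path,
                 columns: Optional[Sequence[str]] = None) -> None:
    """Write rows as a TSV with a header and stable column order.

    Column order is ``columns`` if given, else the key order of the first
    row.  All values are serialized with ``str``.
    """
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(c, "")) for c in columns) + "\n")


def read_report(path) -> list[dict[str, str]]:
    """Read a TSV written by :func:`write_report` (all values as strings)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        out = []
        for raw in fh:
            vals = raw.rstrip("\n").split("\t")
            out.append(dict(zip(header, vals)))
    return out
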