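"""Transcript-vs-genome CDS comparison and four-class assignment.

Each mRNA's protein-coding sequence is compared with the spliced genomic
sequence of its candidate loci.  The outcome per transcript is one of four
classes: exact match (1), substitutions only (2), mRNA bases missing from
the genome (3), or no locus at all (4).  Multiple annotation sources (UCSC
refFlat, CCDS, and the built-in spliced aligner) are reconciled with CCDS
taking precedence when it annotates the transcript, otherwise the better of
the remaining classes.

The spliced aligner here is a deliberately bounded k-mer seed-and-chain
matcher for desk-scale genomes; it recovers any locus whose exons each
contain at least one exact seed and whose per-exon mismatch rate is modest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib

from .refio import Assembly, GeneModel, TranscriptSeq, revcomp

logger = logging.getLogger("refconcord")

SOURCE_ORDER = ("CCDS", "UCSC", "ALIGNER")


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------

def extract_spliced_cds(model: GeneModel, assembly: Assembly) -> str:
    """Concatenate the exonic bases within [cds_start, cds_end), 5'->3' on
    the transcript strand (minus-strand models are reverse-complemented)."""
    if model.chrom not in assembly.sequences:
        raise KeyError(f"{model.transcript_id}: chromosome {model.chrom!r} not in assembly")
    chrom_seq = assembly.sequences[model.chrom]
    if model.tx_end > len(chrom_seq) or model.tx_start < 0:
        raise ValueError(
            f"{model.transcript_id}: coordinates exceed {model.chrom} length {len(chrom_seq)}"
        )
    parts = [chrom_seq[s:e] for s, e in model.cds_exons()]
    seq = "".join(parts)
    return revcomp(seq) if model.strand == "-" else seq


def cds_genome_positions(model: GeneModel) -> list[int]:
    """Genomic position of each CDS base, ordered along the transcript."""
    pos: list[int] = []
    for s, e in model.cds_exons():
        pos.extend(range(s, e))
    if model.strand == "-":
        pos.reverse()
    return pos


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

@dataclass
class LocusComparison:
    """Outcome of aligning one mRNA CDS against one genomic locus.

    ``mismatches`` are (genome_pos, genome_base, mrna_base, cds_offset)
    tuples with bases on the transcript strand and genome_pos genomic
    (0-based).  ``missing_segments`` are (genome_pos_anchor, mrna_bases)
    runs of mRNA bases absent from the genome.
    """

    transcript_id: str
    model: Optional[GeneModel]
    mismatches: list[tuple[int, str, str, int]] = field(default_factory=list)
    missing_segments: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)

    @property
    def n_missing(self) -> int:
        return sum(len(b) for _, b in self.missing_segments)

    @property
    def cds_class(self) -> int:
        if self.model is None:
            return 4
        if self.n_missing:
            return 3
        if self.n_mismatch:
            return 2
        return 1

    @property
    def score(self) -> int:
        return self.n_mismatch + self.n_missing


def align_correspondence(mrna_cds: str, genome_cds: str) -> list[Optional[int]]:
    """Per-base correspondence from mRNA CDS to genome CDS indices.

    A global edit-distance alignment decides: aligned pairs map index to
    index, mRNA insertions map to None (absent from genome), and genome-only
    stretches are skipped (treated downstream as unannotated intronic gaps,
    not mismatches).  Isolated substitutions cost less than a gap pair, so
    substitution-only pairs keep the positional correspondence.
    """
    if mrna_cds == genome_cds:
        return list(range(len(mrna_cds)))
    res = edlib.align(mrna_cds, genome_cds, mode="NW", task="path")
    corr: list[Optional[int]] = []
    qi = ti = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=XM":
            corr.extend(range(ti, ti + n))
            qi += n
            ti += n
        elif ch == "I":  # present in mRNA, absent from genome
            corr.extend([None] * n)
            qi += n
        elif ch == "D":  # genome-only stretch
            ti += n
        else:  # pragma: no cover
            raise ValueError(f"unexpected cigar op {ch!r}")
    assert qi == len(mrna_cds)
    return corr


def compare_cds(
    mrna_cds: str,
    genome_cds: str,
    correspondence: Sequence[Optional[int]],
    *,
    genome_positions: Optional[Sequence[int]] = None,
    model: Optional[GeneModel] = None,
    transcript_id: str = "",
) -> LocusComparison:
    """Walk a per-base correspondence and collect mismatches and missing runs.

    ``correspondence[i]`` is the genome-CDS index aligned to mRNA CDS base
    ``i`` or None when the base is absent from the genome.  ``genome_positions``
    maps genome-CDS indices to genomic coordinates (defaults to the indices
    themselves).  The class follows from the tallies: any missing base makes
    class 3, else any mismatch class 2, else class 1.
    """
    if len(correspondence) != len(mrna_cds):
        raise ValueError(
            f"correspondence covers {len(correspondence)} of {len(mrna_cds)} mRNA CDS bases"
        )
    gp = genome_positions if genome_positions is not None else list(range(len(genome_cds)))
    cmp = LocusComparison(transcript_id=transcript_id, model=model)
    gap_start: Optional[int] = None
    for i, ti in enumerate(correspondence):
        if ti is None:
            if gap_start is None:
                gap_start = i
            continue
        if gap_start is not None:
            cmp.missing_segments.append((gp[ti], mrna_cds[gap_start:i]))
            gap_start = None
        if mrna_cds[i] != genome_cds[ti]:
            cmp.mismatches.append((gp[ti], genome_cds[ti], mrna_cds[i], i))
    if gap_start is not None:
        # trailing gap: anchor just past the last aligned genomic base
        last = next((correspondence[j] for j in range(gap_start - 1, -1, -1)
                     if correspondence[j] is not None), None)
        anchor = gp[last] + 1 if last is not None else 0
        cmp.missing_segments.append((anchor, mrna_cds[gap_start:]))
    return cmp


def compare_to_model(mrna: TranscriptSeq, model: GeneModel, assembly: Assembly) -> LocusComparison:
    """Full comparison of an mRNA CDS against one gene model."""
    genome_cds = extract_spliced_cds(model, assembly)
    corr = align_correspondence(mrna.cds_sequence, genome_cds)
    return compare_cds(
        mrna.cds_sequence,
        genome_cds,
        corr,
        genome_positions=cds_genome_positions(model),
        model=model,
        transcript_id=mrna.transcript_id,
    )


# ---------------------------------------------------------------------------
# Best locus
# ---------------------------------------------------------------------------

def _locus_sort_key(assembly: Assembly, cmp: LocusComparison):
    m = cmp.model
    canonical_rank = 0 if m.chrom in assembly.canonical_set else 1
    return (cmp.score, canonical_rank, m.chrom, m.cds_start)


def best_locus_comparison(
    mrna: TranscriptSeq, candidate_models: Sequence[GeneModel], assembly: Assembly
) -> LocusComparison:
    """Comparison against the best candidate locus (class 4 when none).

    The best locus minimises mismatching + missing CDS bases; on a tie a
    canonical-chromosome locus beats an alternative scaffold, and remaining
    ties break deterministically by (chrom, cds_start).
    """
    comparisons = []
    for m in candidate_models:
        if not m.is_coding:
            continue
        try:
            comparisons.append(compare_to_model(mrna, m, assembly))
        except (KeyError, ValueError) as exc:
            logger.warning("%s: candidate locus skipped: %s", mrna.transcript_id, exc)
    if not comparisons:
        return LocusComparison(transcript_id=mrna.transcript_id, model=None)
    comparisons.sort(key=lambda c: _locus_sort_key(assembly, c))
    return comparisons[0]


def find_best_locus(
    mrna: TranscriptSeq, candidate_models: Sequence[GeneModel], assembly: Assembly
) -> Optional[GeneModel]:
    return best_locus_comparison(mrna, candidate_models, assembly).model


# ---------------------------------------------------------------------------
# Bounded spliced matcher (BLAT stand-in for desk-scale genomes)
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index over an assembly's forward strands.

    K-mers occurring more than ``max_hits`` times are masked as repetitive;
    unique flanking seeds still anchor repeat-containing queries.
    """

    def __init__(self, assembly: Assembly, k: int = 16, max_hits: int = 64):
        self.k = k
        self.max_hits = max_hits
        self.index: dict[str, list[tuple[str, int]]] = {}
        overflow: set[str] = set()
        for chrom, seq in assembly.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in overflow or "N" in kmer:
                    continue
                hits = self.index.setdefault(kmer, [])
                hits.append((chrom, i))
                if len(hits) > max_hits:
                    del self.index[kmer]
                    overflow.add(kmer)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def _chain_runs(runs: list[tuple[int, int, int, int]], max_intron: int):
    """Greedy-DP colinear chaining of (qstart, qend, gstart, gend) runs,
    maximising covered query length.  Runs may overlap slightly (repeat
    edges); the later run is trimmed on both coordinates when chained."""
    if not runs:
        return [], 0
    runs.sort(key=lambda r: (r[0], r[2]))
    n = len(runs)
    best = [r[1] - r[0] for r in runs]
    prev = [-1] * n
    for j in range(n):
        qs, qe, gs, ge = runs[j]
        for i in range(j):
            pqs, pqe, pgs, pge = runs[i]
            if qe > pqe and ge > pge and 0 <= gs - pgs and gs - pge <= max_intron:
                cand = best[i] + (qe - max(qs, pqe))
                if cand > best[j]:
                    best[j] = cand
                    prev[j] = i
    j = max(range(n), key=lambda i: best[i])
    total = best[j]
    chain = []
    while j != -1:
        chain.append(runs[j])
        j = prev[j]
    chain.reverse()
    # trim overlaps so downstream blocks are strictly increasing
    trimmed = [chain[0]]
    for qs, qe, gs, ge in chain[1:]:
        pqe = trimmed[-1][1]
        if qs < pqe:
            d = pqe - qs
            qs, gs = qs + d, gs + d
        if qe > qs and ge > gs:
            trimmed.append((qs, qe, gs, ge))
    return trimmed, total


def mini_spliced_match(
    mrna_cds: str,
    assembly: Assembly,
    seed_len: int = 16,
    max_intron: int = 1_000_000,
    *,
    index: Optional[GenomeIndex] = None,
    min_coverage: float = 0.5,
    min_intron: int = 20,
    transcript_id: str = "aligned",
) -> list[GeneModel]:
    """Locate candidate gene loci for an mRNA CDS by exact k-mer seeding
    and colinear chaining, on both strands.

    Returns zero or more ``source='ALIGNER'`` GeneModels whose exon blocks
    cover the CDS.  Seed chains covering less than ``min_coverage`` of the
    query are discarded; genome gaps larger than ``min_intron`` relative to
    the query gap become introns (up to ``max_intron``).
    """
    if len(mrna_cds) < seed_len:
        raise ValueError(f"CDS shorter than seed length {seed_len}")
    if index is None:
        index = GenomeIndex(assembly, k=seed_len)
    elif index.k != seed_len:
        raise ValueError("prebuilt index k does not match seed_len")

    models: list[GeneModel] = []
    L = len(mrna_cds)
    for strand in "+-":
        query = mrna_cds if strand == "+" else revcomp(mrna_cds)
        # collect seed hits grouped by (chrom, diagonal)
        by_chrom: dict[str, dict[int, list[int]]] = {}
        for q in range(0, L - seed_len + 1):
            for chrom, g in index.lookup(query[q : q + seed_len]):
                by_chrom.setdefault(chrom, {}).setdefault(g - q, []).append(q)
        for chrom, diags in by_chrom.items():
            # merge same-diagonal seeds into maximal runs
            runs: list[tuple[int, int, int, int]] = []
            for d, qoffs in diags.items():
                qoffs.sort()
                rs = qoffs[0]
                re = qoffs[0] + seed_len
                for q in qoffs[1:]:
                    if q <= re:
                        re = q + seed_len
                    else:
                        runs.append((rs, re, rs + d, re + d))
                        rs, re = q, q + seed_len
                runs.append((rs, re, rs + d, re + d))
            chain, covered = _chain_runs(runs, max_intron)
            if not chain or covered < min_coverage * L:
                continue
            # convert the chain into exon blocks in query coordinates
            chrom_seq = assembly.sequences[chrom]
            chrom_len = len(chrom_seq)
            exons: list[list[int]] = []
            cur = None  # [qstart, qend, gstart, gend]
            for qs, qe, gs, ge in chain:
                if cur is None:
                    cur = [qs, qe, gs, ge]
                    continue
                q_gap = qs - cur[1]
                g_gap = gs - cur[3]
                if g_gap - q_gap > min_intron:
                    # intron: split the unseeded query bases between the two
                    # flanking exons at the split that maximises base matches
                    # (substitutions near a boundary leave such a gap), with
                    # a bonus for canonical splice signals at the implied
                    # intron edges (GT..AG; CT..AC for minus-strand queries)
                    donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
                    lpref = [0]
                    for i in range(q_gap):
                        lpref.append(lpref[-1] + (query[cur[1] + i] == chrom_seq[cur[3] + i]))
                    rsuf = [0]
                    for i in range(q_gap):
                        rsuf.append(rsuf[-1] + (query[qs - 1 - i] == chrom_seq[gs - 1 - i]))
                    rsuf.reverse()

                    def _split_score(s: int) -> tuple[int, int]:
                        i0 = cur[3] + s
                        i1 = gs - (q_gap - s)
                        bonus = 3 * (chrom_seq[i0 : i0 + 2] == donor)
                        bonus += 3 * (chrom_seq[i1 - 2 : i1] == acceptor)
                        return (lpref[s] + rsuf[s] + bonus, -s)

                    split = max(range(q_gap + 1), key=_split_score)
                    cur[1] += split
                    cur[3] += split
                    exons.append(cur)
                    ext_r = q_gap - split
                    cur = [qs - ext_r, qe, gs - ext_r, ge]
                else:
                    cur[1], cur[3] = qe, ge
            exons.append(cur)
            # extend outer blocks so the model spans the full query
            exons[0][2] = max(0, exons[0][2] - exons[0][0])
            exons[0][0] = 0
            tail = L - exons[-1][1]
            exons[-1][3] = min(chrom_len, exons[-1][3] + tail)
            exons[-1][1] = L
            gexons = sorted((e[2], e[3]) for e in exons)
            if any(a >= b for a, b in gexons):
                continue
            if any(y0 < x1 for (x0, x1), (y0, y1) in zip(gexons, gexons[1:])):
                continue  # degenerate chain (blocks overlap after extension)
            models.append(
                GeneModel(
                    transcript_id=transcript_id,
                    gene=transcript_id,
                    chrom=chrom,
                    strand=strand,
                    exons=[tuple(e) for e in gexons],
                    cds_start=gexons[0][0],
                    cds_end=gexons[-1][1],
                    source="ALIGNER",
                )
            )
    return models


# ---------------------------------------------------------------------------
# Class reconciliation across annotation sources
# ---------------------------------------------------------------------------

@dataclass
class ClassAssignment:
    transcript_id: str
    per_source: dict[str, int]
    final_class: int
    chosen_source: str


def reconcile_classes(per_source: dict[str, int], transcript_id: str = "") -> ClassAssignment:
    """Combine per-annotation classes into one final class.

    CCDS wins whenever it annotates the transcript (its class < 4) because
    it is the most intensively curated source; otherwise the better (lower)
    class among UCSC and the aligner is used, preferring UCSC on ties.
    """
    if not per_source:
        raise ValueError("per_source must be non-empty")
    ccds = per_source.get("CCDS", 4)
    if ccds < 4:
        return ClassAssignment(transcript_id, dict(per_source), ccds, "CCDS")
    rest = [(per_source[s], rank, s)
            for rank, s in enumerate(("UCSC", "ALIGNER")) if s in per_source]
    if not rest:
        # only CCDS present, and it is class 4
        return ClassAssignment(transcript_id, dict(per_source), 4, "CCDS")
    cls, _, src = min(rest)
    return ClassAssignment(transcript_id, dict(per_source), cls, src)


def classify_transcript(
    mrna: TranscriptSeq,
    models_by_source: dict[str, list[GeneModel]],
    assembly: Assembly,
) -> tuple[ClassAssignment, dict[str, LocusComparison]]:
    """Per-source best-locus comparison and final reconciled class.

    Returns the assignment and the per-source comparisons (the comparison of
    the chosen source is the one downstream discordance calling uses).
    """
    per_source: dict[str, int] = {}
    comparisons: dict[str, LocusComparison] = {}
    for source in SOURCE_ORDER:
        models = models_by_source.get(source) or []
        cmp = best_locus_comparison(mrna, models, assembly)
        per_source[source] = cmp.cds_class
        comparisons[source] = cmp
    assignment = reconcile_classes(per_source, mrna.transcript_id)
    return assignment, comparisons


# ---------------------------------------------------------------------------
# Missing-segment (class 3) reporting
# ---------------------------------------------------------------------------

def report_missing_segments(
    comparisons: Sequence[LocusComparison],
    gene_index: dict[str, tuple[str, str]],
) -> list[dict[str, object]]:
    """One report row per gene with mRNA bases missing from the genome.

    Segments identical across isoforms of the same gene are merged; the
    in-frame flag marks genes whose total missing-base count is a multiple
    of three (amino-acid insertion/deletion polymorphisms).  Positions are
    printed 1-based as ``anchor:anchor``.
    """
    by_gene: dict[str, dict] = {}
    for cmp in comparisons:
        if cmp.cds_class != 3 or cmp.model is None:
            continue
        gene, desc = gene_index.get(cmp.transcript_id, (cmp.model.gene, ""))
        entry = by_gene.setdefault(
            gene,
            {"desc": desc, "chrom": cmp.model.chrom, "strand": cmp.model.strand,
             "segments": {}, "mrnas": set()},
        )
        entry["mrnas"].add(cmp.transcript_id)
        for anchor, bases in cmp.missing_segments:
            entry["segments"][(anchor, bases)] = True
    rows = []
    for gene in sorted(by_gene):
        e = by_gene[gene]
        segs = sorted(e["segments"])
        n_missing = sum(len(b) for _, b in segs)
        rows.append(
            {
                "gene": gene,
                "description": e["desc"],
                "n_missing": n_missing,
                "chrom": e["chrom"],
                "strand": e["strand"],
                "positions": ", ".join(f"{a + 1}:{a + 1}" for a, _ in segs),
                "missing_bases": ", ".join(b for _, b in segs),
                "mrnas": ", ".join(sorted(e["mrnas"])),
                "in_frame": n_missing % 3 == 0,
            }
        )
    return rows
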