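"""Synthetic input universe with ground truth for end-to-end testing.

The generator emulates the study conditions of a reference-concordance
audit: a current genome assembly carrying gene loci; mRNA sequences whose
CDS may match the genome exactly (class 1), carry substitutions (class 2),
contain bases missing from the genome (class 3) or have no locus at all
(class 4); a population variant panel whose AAF distribution is bimodal
(a rare-variant excess plus a near-1 spike); an older assembly version with
shifted and inverted blocks and ref/alt-switched sites; a protein database
whose entries pick the alternative allele with a configurable probability;
and RNA-seq pileups at planted editing sites.

Every random draw flows from one seed; identical seeds give byte-identical
output files.  Ground truth (per-transcript class, per-site concordance
category, inversion and switch flags, per-editing-site fraction) is recorded
at construction time and written alongside the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .codonlib import codon_to_aa
from .refio import revcomp, write_fasta, write_report

COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Generator parameters; the defaults define the standard study conditions.

    AAF mixture: with weight ``aaf_rare_weight`` a site's AAF is drawn from
    Beta(0.3, 3) (rare-variant excess) and otherwise from Beta(50, 1) (the
    near-1 spike of sites where the reference carries the minor allele).
    ``p_old_genome``, ``p_mrna`` and ``p_prot`` are the independent per-site
    probabilities that the old assembly, the mRNA database and the protein
    database represent the alternative allele.  ``switch_fraction`` is the
    same quantity as ``p_old_genome`` seen from the liftover side: a site's
    ref/alt switch between versions iff the old assembly carries the
    alternative allele.
    """

    seed: int = 17
    n_chroms: int = 2
    chrom_len: int = 160_000
    include_alt_scaffold: bool = True
    n_alt_duplicates: int = 2
    n_genes: int = 200
    exons_per_gene: int = 3
    cds_len: int = 300
    utr_len: int = 30
    ccds_fraction: float = 0.9
    n_sites: int = 5000
    aaf_rare_weight: float = 0.85
    aaf_rare_beta: tuple[float, float] = (0.3, 3.0)
    aaf_spike_beta: tuple[float, float] = (50.0, 1.0)
    p_mrna: float = 0.004
    p_prot: float = 0.01
    p_old_genome: float = 0.02
    n_class2: int = 20
    n_class3: int = 6
    n_class4: int = 1
    known_fraction: float = 0.9
    n_triallelic: int = 2
    inversion_block_count: int = 3
    editing_fractions: tuple[float, ...] = (0.9, 0.5, 0.3, 0.1, 0.03)
    read_depth: int = 100
    n_decoy_proteins: int = 20

    @property
    def switch_fraction(self) -> float:
        return self.p_old_genome

    def validate(self) -> None:
        for name in ("p_mrna", "p_prot", "p_old_genome", "known_fraction",
                     "aaf_rare_weight", "ccds_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.cds_len % 3:
            raise ValueError("cds_len must be a multiple of 3")
        if min(self.chrom_len, self.cds_len, self.n_genes, self.read_depth) <= 0:
            raise ValueError("lengths and counts must be positive")
        n_special = self.n_class2 + self.n_class3 + self.n_class4
        n_edit = len(self.editing_fractions)
        if n_special + n_edit > self.n_genes:
            raise ValueError(
                f"n_class2+n_class3+n_class4+editing hosts ({n_special + n_edit}) "
                f"exceeds n_genes ({self.n_genes})"
            )
        # worst-case layout: introns < 300, intergenic gap < 300, 400 margin
        span = self.cds_len + 2 * self.utr_len + 300 * (self.exons_per_gene - 1) + 300
        if self.n_genes * span + 400 * self.n_chroms > self.n_chroms * self.chrom_len:
            raise ValueError("genes do not fit in the genome; increase chrom_len")


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class SiteTruth:
    chrom: str
    pos: int  # 0-based, new assembly
    ref: str
    alt: str
    aaf: float
    panel: str
    inverted: bool
    switched: bool  # old assembly carries the alternative allele
    mrna_alt: bool
    prot_alt: bool
    effect: str
    transcript_id: str
    cds_offset: int
    triallelic: bool = False
    #: True for the forced class-2 substitutions whose AAF comes from the
    #: spike component (the background sites draw from the full mixture)
    planted: bool = False


@dataclass
class EditingTruth:
    chrom: str
    pos: int  # 0-based, new assembly
    strand: str
    fraction: float
    transcript_id: str


@dataclass
class GroundTruth:
    config: SynthConfig
    true_class: dict[str, int] = field(default_factory=dict)
    chosen_chrom: dict[str, str] = field(default_factory=dict)
    sites: list[SiteTruth] = field(default_factory=list)
    editing: list[EditingTruth] = field(default_factory=list)
    files: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Internal gene bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    tid: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genome order, incl. UTR parts
    cds_start: int
    cds_end: int
    utr5: str
    utr3: str
    mrna_cds: list[str]  # mutable, transcript strand
    genome_cds: str  # transcript strand (the allele written to the genome)
    cds_positions: list[int]  # genome position of each genome-CDS base, tx order
    true_class: int
    in_ccds: bool = True
    planted_subs: list[int] = field(default_factory=list)  # mRNA cds offsets


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    inner = []
    while len(inner) < n_codons - 2:
        codon = "".join(BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in STOPS and codon != "ATG":
            inner.append(codon)
    return "ATG" + "".join(inner) + "TAA"


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


class SynthesisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def generate(config: SynthConfig, outdir) -> GroundTruth:
    """Generate the full synthetic input universe under ``outdir``.

    Emits: new/old assembly FASTAs, a UCSC chain (old -> new), refFlat and
    CCDS TSVs, mRNA FASTA plus CDS sidecar, protein FASTA, a VCF on old
    coordinates with AF INFO fields, pileup text at the editing sites, and
    ground-truth TSVs.  Returns the in-memory :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth(config=config)

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chroms = {c: list(_random_dna(rng, config.chrom_len)) for c in chrom_names}

    # --- class designation ------------------------------------------------
    n_edit = len(config.editing_fractions)
    classes: list[int] = []
    for i in range(config.n_genes):
        if i < config.n_class4:
            classes.append(4)
        elif i < config.n_class4 + config.n_class3:
            classes.append(3)
        elif i < config.n_class4 + config.n_class3 + config.n_class2:
            classes.append(2)
        else:
            classes.append(1)
    # editing hosts: the last n_edit class-1 genes
    editing_hosts = list(range(config.n_genes - n_edit, config.n_genes))

    # --- build genes -------------------------------------------------------
    genes: list[_Gene] = []
    cursors = {c: 200 for c in chrom_names}
    chrom_cycle = 0
    for i in range(config.n_genes):
        tid = f"NM_{i + 1:06d}"
        gname = f"GENE{i + 1:04d}"
        cls = classes[i]
        strand = "+" if rng.random() < 0.5 else "-"
        mrna_cds = _random_orf(rng, config.cds_len // 3)

        if cls == 4:
            # no locus: the mRNA exists only in the FASTA
            genes.append(_Gene(tid, gname, "", strand, [], 0, 0, "", "",
                               list(mrna_cds), "", [], 4))
            continue

        genome_cds = mrna_cds
        planted: list[int] = []
        if cls == 2:
            n_sub = int(rng.integers(1, 4))
            # substitution positions spaced >= 3 apart, away from start/stop
            offs: list[int] = []
            while len(offs) < n_sub:
                p = int(rng.integers(3, config.cds_len - 3))
                if all(abs(p - q) >= 3 for q in offs):
                    offs.append(p)
            offs.sort()
            gl = list(genome_cds)
            for p in offs:
                ci = p // 3
                for _ in range(20):
                    b = BASES[rng.integers(0, 4)]
                    cod = gl[3 * ci] + gl[3 * ci + 1] + gl[3 * ci + 2]
                    cand = cod[: p % 3] + b + cod[p % 3 + 1 :]
                    if b != mrna_cds[p] and cand not in STOPS:
                        gl[p] = b
                        break
            genome_cds = "".join(gl)
            planted = offs
        elif cls == 3:
            unit = int(rng.choice([1, 3, 6, 12]))
            # the genome allele lacks `unit` mRNA bases (deletion polymorphism);
            # the mRNA CDS itself stays a whole number of codons
            p = int(rng.integers(30, config.cds_len - 30 - unit))
            genome_cds = mrna_cds[:p] + mrna_cds[p + unit :]

        # exon layout on the genome
        g_len = len(genome_cds)
        n_e = config.exons_per_gene
        base_sz = g_len // n_e
        cds_sizes = [base_sz + (g_len - base_sz * n_e if j == 0 else 0) for j in range(n_e)]
        utr5 = _random_dna(rng, config.utr_len)
        utr3 = _random_dna(rng, config.utr_len)
        tx_sizes = list(cds_sizes)
        tx_sizes[0] += config.utr_len
        tx_sizes[-1] += config.utr_len
        intron_lens = [int(rng.integers(50, 300)) for _ in range(n_e - 1)]
        tx_seq = utr5 + genome_cds + utr3

        chrom = chrom_names[chrom_cycle % len(chrom_names)]
        chrom_cycle += 1
        span = sum(tx_sizes) + sum(intron_lens)
        start = cursors[chrom] + int(rng.integers(100, 300))
        if start + span > config.chrom_len - 200:
            raise SynthesisError(f"chromosome {chrom} overflow; increase chrom_len")
        cursors[chrom] = start + span

        sizes_genome_order = tx_sizes if strand == "+" else tx_sizes[::-1]
        coords: list[tuple[int, int]] = []
        cur = start
        for j, sz in enumerate(sizes_genome_order):
            coords.append((cur, cur + sz))
            cur += sz + (intron_lens[j] if j < n_e - 1 else 0)
        tx_map: list[int] = []
        if strand == "+":
            for s, e in coords:
                tx_map.extend(range(s, e))
        else:
            for s, e in reversed(coords):
                tx_map.extend(range(e - 1, s - 1, -1))
        arr = chroms[chrom]
        for t, g in enumerate(tx_map):
            arr[g] = tx_seq[t] if strand == "+" else COMPLEMENT_BASE[tx_seq[t]]
        # canonical GT..AG splice signals (forward-strand CT..AC for minus genes)
        donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
        for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
            arr[e1], arr[e1 + 1] = donor[0], donor[1]
            arr[s2 - 2], arr[s2 - 1] = acceptor[0], acceptor[1]
        cds_positions = tx_map[config.utr_len : config.utr_len + g_len]
        cds_gpos = (min(cds_positions), max(cds_positions) + 1)
        genes.append(
            _Gene(tid, gname, chrom, strand, coords, cds_gpos[0], cds_gpos[1],
                  utr5, utr3, list(mrna_cds), genome_cds, cds_positions, cls,
                  in_ccds=bool(rng.random() < config.ccds_fraction),
                  planted_subs=planted)
        )

    # --- alternative scaffold with duplicated loci -------------------------
    alt_rows: list[tuple[_Gene, list[tuple[int, int]]]] = []
    if config.include_alt_scaffold and config.n_alt_duplicates:
        candidates = [g for g in genes if g.true_class == 1
                      and genes.index(g) not in editing_hosts]
        picked = candidates[: config.n_alt_duplicates]
        alt_seq: list[str] = list(_random_dna(rng, 200))
        for g in picked:
            lo = g.exons[0][0] - 50
            hi = g.exons[-1][1] + 50
            offset = len(alt_seq) - lo
            alt_seq.extend(chroms[g.chrom][lo:hi])
            alt_seq.extend(_random_dna(rng, 200))
            shifted = [(s + offset, e + offset) for s, e in g.exons]
            alt_rows.append((g, shifted))
        chroms["chr1_alt"] = alt_seq

    # --- population sites ---------------------------------------------------
    def draw_aaf(n: int) -> np.ndarray:
        rare = rng.beta(*config.aaf_rare_beta, size=n)
        spike = rng.beta(*config.aaf_spike_beta, size=n)
        pick = rng.random(n) < config.aaf_rare_weight
        return np.where(pick, rare, spike)

    def tx_base(g: _Gene, off: int) -> str:
        return g.mrna_cds[off]

    def fwd(base_t: str, strand: str) -> str:
        return base_t if strand == "+" else COMPLEMENT_BASE[base_t]

    def pick_alt(g: _Gene, off: int, ref_t: str) -> Optional[str]:
        """Alternative allele (transcript strand) that creates no stop codon."""
        ci = off // 3
        codon = "".join(g.mrna_cds[3 * ci : 3 * ci + 3])
        cands = [b for b in BASES if b != ref_t]
        rng.shuffle(cands)
        for b in cands:
            cod = codon[: off % 3] + b + codon[off % 3 + 1 :]
            if cod not in STOPS:
                return b
        return None

    site_truths: list[SiteTruth] = []
    used_positions: set[tuple[str, int]] = set()

    # (a) planted class-2 substitutions, known with probability known_fraction
    for gi, g in enumerate(genes):
        for off in g.planted_subs:
            gp = g.cds_positions[off]
            key = (g.chrom, gp)
            used_positions.add(key)
            if rng.random() >= config.known_fraction:
                continue  # novel substitution: mRNA differs, panel silent
            ref_t, alt_t = g.genome_cds[off], g.mrna_cds[off]
            aaf = float(rng.beta(*config.aaf_spike_beta))
            site_truths.append(SiteTruth(
                chrom=g.chrom, pos=gp, ref=fwd(ref_t, g.strand), alt=fwd(alt_t, g.strand),
                aaf=aaf, panel="synthpanel",
                inverted=False, switched=bool(rng.random() < config.p_old_genome),
                mrna_alt=True, prot_alt=bool(rng.random() < config.p_prot),
                effect=_effect(g, off, ref_t, alt_t), transcript_id=g.tid,
                cds_offset=off, planted=True,
            ))

    # (b) background sites across class-1/2 CDS (editing hosts excluded)
    eligible = sorted(
        (g.chrom, gp, gi, off)
        for gi, g in enumerate(genes)
        if g.true_class in (1, 2) and gi not in editing_hosts
        for off, gp in enumerate(g.cds_positions)
        if (g.chrom, gp) not in used_positions
    )
    n_bg = config.n_sites - len(site_truths) - config.n_triallelic
    if n_bg < 0:
        raise SynthesisError("n_sites too small for the planted substitutions")
    chosen = rng.choice(len(eligible), size=min(n_bg, len(eligible)), replace=False)
    chosen.sort()
    aafs = draw_aaf(len(chosen))
    for k, idx in enumerate(chosen):
        chrom, gp, gi, off = eligible[idx]
        g = genes[gi]
        ref_t = tx_base(g, off)
        alt_t = pick_alt(g, off, ref_t)
        if alt_t is None:
            continue
        mrna_alt = bool(rng.random() < config.p_mrna)
        st = SiteTruth(
            chrom=chrom, pos=gp, ref=fwd(ref_t, g.strand), alt=fwd(alt_t, g.strand),
            aaf=float(aafs[k]), panel="synthpanel",
            inverted=False, switched=bool(rng.random() < config.p_old_genome),
            mrna_alt=mrna_alt, prot_alt=bool(rng.random() < config.p_prot),
            effect=_effect(g, off, ref_t, alt_t), transcript_id=g.tid, cds_offset=off,
        )
        site_truths.append(st)
        used_positions.add((chrom, gp))
        if mrna_alt:
            g.mrna_cds[off] = alt_t

    # (c) triallelic sites: mRNA matches the second alternative allele
    tri_pool = [e for e in eligible if (e[0], e[1]) not in used_positions]
    tri_idx = rng.choice(len(tri_pool), size=config.n_triallelic, replace=False)
    tri_rows: list[tuple[SiteTruth, str, float]] = []  # (truth for alt2, alt1, af1)
    for idx in sorted(tri_idx):
        chrom, gp, gi, off = tri_pool[idx]
        g = genes[gi]
        ref_t = tx_base(g, off)
        others = [b for b in BASES if b != ref_t]
        rng.shuffle(others)
        alt1_t, alt2_t = others[0], others[1]
        ci = off // 3
        codon = "".join(g.mrna_cds[3 * ci : 3 * ci + 3])
        if codon[: off % 3] + alt2_t + codon[off % 3 + 1 :] in STOPS:
            alt1_t, alt2_t = alt2_t, alt1_t
            if codon[: off % 3] + alt2_t + codon[off % 3 + 1 :] in STOPS:
                continue
        af1 = float(rng.beta(*config.aaf_rare_beta))
        af2 = float(rng.beta(*config.aaf_spike_beta)) * (1 - af1)
        st = SiteTruth(
            chrom=chrom, pos=gp, ref=fwd(ref_t, g.strand), alt=fwd(alt2_t, g.strand),
            aaf=af2, panel="synthpanel", inverted=False, switched=False,
            mrna_alt=True, prot_alt=False, effect=_effect(g, off, ref_t, alt2_t),
            transcript_id=g.tid, cds_offset=off, triallelic=True,
        )
        g.mrna_cds[off] = alt2_t
        site_truths.append(st)
        used_positions.add((chrom, gp))
        tri_rows.append((st, fwd(alt1_t, g.strand), af1))

    # (d) editing sites: genome A, mRNA G on the transcript strand, unknown
    editing_truths: list[EditingTruth] = []
    for host_rank, frac in enumerate(config.editing_fractions):
        gi = editing_hosts[host_rank]
        g = genes[gi]
        offs = []
        for o, b in enumerate(g.mrna_cds):
            if b != "A" or not 3 <= o < len(g.mrna_cds) - 3:
                continue
            if (g.chrom, g.cds_positions[o]) in used_positions:
                continue
            ci, j = divmod(o, 3)
            codon = "".join(g.mrna_cds[3 * ci : 3 * ci + 3])
            if codon[:j] + "G" + codon[j + 1 :] not in STOPS:
                offs.append(o)
        if not offs:
            raise SynthesisError(f"no editable A in {g.tid}")
        off = offs[int(rng.integers(0, len(offs)))]
        g.mrna_cds[off] = "G"
        gp = g.cds_positions[off]
        used_positions.add((g.chrom, gp))
        editing_truths.append(EditingTruth(g.chrom, gp, g.strand, frac, g.tid))

    # recompute every site effect against the final mRNA codon context, so
    # the recorded effect equals what the pipeline will compute
    gene_by_tid = {g.tid: g for g in genes}
    for st in site_truths:
        g = gene_by_tid[st.transcript_id]
        ref_t = st.ref if g.strand == "+" else COMPLEMENT_BASE[st.ref]
        alt_t = st.alt if g.strand == "+" else COMPLEMENT_BASE[st.alt]
        st.effect = _effect(g, st.cds_offset, ref_t, alt_t)

    # --- final per-transcript class truth -----------------------------------
    for gi, g in enumerate(genes):
        if g.true_class in (3, 4):
            cls = g.true_class
        else:
            cls = 2 if any(m != gc for m, gc in zip(g.mrna_cds, g.genome_cds)) else 1
        g.true_class = cls
        truth.true_class[g.tid] = cls
        if g.chrom:
            truth.chosen_chrom[g.tid] = g.chrom

    # --- old assembly, inverted blocks, chain -------------------------------
    site_by_chrom: dict[str, list[SiteTruth]] = {}
    for st in site_truths:
        site_by_chrom.setdefault(st.chrom, []).append(st)

    inv_blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    placed = 0
    guard = 0
    while placed < config.inversion_block_count and guard < 10_000:
        guard += 1
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        blen = int(rng.integers(1000, 3000))
        s = int(rng.integers(100, config.chrom_len - 100 - blen))
        e = s + blen
        ok = all(e + 50 < bs or be + 50 < s for bs, be in inv_blocks[chrom])
        # keep block edges clear of sites so the 21-nt windows are unambiguous
        ok = ok and all(not (abs(st.pos - s) < 15 or abs(st.pos - e) < 15)
                        for st in site_by_chrom.get(chrom, []))
        if ok:
            inv_blocks[chrom].append((s, e))
            placed += 1
    for c in inv_blocks:
        inv_blocks[c].sort()

    old_chroms: dict[str, str] = {}
    chain_lines: list[str] = []
    new_to_old: dict[str, list[tuple[int, int, int, bool]]] = {}
    for chrom in chrom_names:
        new_seq = chroms[chrom]
        bounds = [0]
        for s, e in inv_blocks[chrom]:
            bounds.extend([s, e])
        bounds.append(len(new_seq))
        inverted_set = set(inv_blocks[chrom])
        pieces: list[str] = []
        old_pos = 0
        segs: list[tuple[int, int, int, bool]] = []
        old_name = f"{chrom}_old"
        for a, b in zip(bounds, bounds[1:]):
            if a == b:
                continue
            spacer = _random_dna(rng, int(rng.integers(37, 200)))
            pieces.append(spacer)
            old_pos += len(spacer)
            seg = new_seq[a:b]
            seg = list(seg)
            for st in site_by_chrom.get(chrom, []):
                if a <= st.pos < b and st.switched:
                    seg[st.pos - a] = st.alt
            inverted = (a, b) in inverted_set
            seg_str = "".join(seg)
            if inverted:
                seg_str = revcomp(seg_str)
            pieces.append(seg_str)
            segs.append((a, b, old_pos, inverted))
            old_pos += b - a
        pieces.append(_random_dna(rng, int(rng.integers(37, 200))))
        old_chroms[old_name] = "".join(pieces)
        new_to_old[chrom] = segs
        for a, b, op, inverted in segs:
            size = b - a
            old_len = len(old_chroms[old_name])
            if not inverted:
                chain_lines.append(
                    f"chain 1000 {old_name} {old_len} + {op} {op + size} "
                    f"{chrom} {len(new_seq)} + {a} {a + size} {len(chain_lines) + 1}"
                )
            else:
                # query coords on the reversed strand
                qs = len(new_seq) - b
                chain_lines.append(
                    f"chain 1000 {old_name} {old_len} + {op} {op + size} "
                    f"{chrom} {len(new_seq)} - {qs} {qs + size} {len(chain_lines) + 1}"
                )
            chain_lines.append(f"{size}")
            chain_lines.append("")

    def to_old(chrom: str, pos: int) -> tuple[str, int, bool]:
        for a, b, op, inverted in new_to_old[chrom]:
            if a <= pos < b:
                if inverted:
                    return f"{chrom}_old", op + (b - 1 - pos), True
                return f"{chrom}_old", op + (pos - a), False
        raise SynthesisError(f"position {chrom}:{pos} outside chain segments")

    for st in site_truths:
        _, _, inv = to_old(st.chrom, st.pos)
        st.inverted = inv

    # --- emit files ----------------------------------------------------------
    new_sequences = {c: "".join(chroms[c]) for c in chroms}
    f_new = outdir / "genome_new.fa"
    f_old = outdir / "genome_old.fa"
    write_fasta(new_sequences, f_new)
    write_fasta(old_chroms, f_old)
    f_chain = outdir / "old_to_new.chain"
    f_chain.write_text("\n".join(chain_lines) + "\n")

    # refFlat + CCDS
    refflat_rows: list[str] = []
    ccds_rows: list[str] = ["transcript_id\tgene\tchrom\tstrand\tcds_exons\tstatus"]

    def _refflat_line(g: _Gene, chrom: str, exons: list[tuple[int, int]],
                      cds_start: int, cds_end: int) -> str:
        starts = ",".join(str(s) for s, _ in exons) + ","
        ends = ",".join(str(e) for _, e in exons) + ","
        return (f"{g.gene}\t{g.tid}\t{chrom}\t{g.strand}\t{exons[0][0]}\t{exons[-1][1]}"
                f"\t{cds_start}\t{cds_end}\t{len(exons)}\t{starts}\t{ends}")

    for g in genes:
        if g.true_class == 4:
            continue
        refflat_rows.append(_refflat_line(g, g.chrom, g.exons, g.cds_start, g.cds_end))
        if g.in_ccds:
            cds_ex = []
            for s, e in g.exons:
                s2, e2 = max(s, g.cds_start), min(e, g.cds_end)
                if s2 < e2:
                    cds_ex.append(f"{s2}-{e2}")
            ccds_rows.append(
                f"{g.tid}\t{g.gene}\t{g.chrom}\t{g.strand}\t{','.join(cds_ex)}\tPublic"
            )
    for g, shifted in alt_rows:
        off0 = shifted[0][0] - g.exons[0][0]
        refflat_rows.append(
            _refflat_line(g, "chr1_alt", shifted, g.cds_start + off0, g.cds_end + off0)
        )
    # one non-coding row exercises the cdsStart == cdsEnd exclusion
    refflat_rows.append("NCGENE1\tNR_000001\tchr1\t+\t10\t150\t10\t10\t1\t10,\t150,")

    f_refflat = outdir / "refflat.tsv"
    f_refflat.write_text("\n".join(refflat_rows) + "\n")
    f_ccds = outdir / "ccds.tsv"
    f_ccds.write_text("\n".join(ccds_rows) + "\n")

    # mRNA FASTA + sidecar
    mrna_seqs: dict[str, str] = {}
    sidecar = ["transcript_id\tcds_start\tcds_end"]
    for g in genes:
        cds = "".join(g.mrna_cds)
        mrna_seqs[g.tid] = g.utr5 + cds + g.utr3 if g.true_class != 4 else cds
        a = len(g.utr5) if g.true_class != 4 else 0
        sidecar.append(f"{g.tid}\t{a}\t{a + len(cds)}")
    f_mrna = outdir / "mrna.fa"
    write_fasta(mrna_seqs, f_mrna)
    f_sidecar = outdir / "cds_sidecar.tsv"
    f_sidecar.write_text("\n".join(sidecar) + "\n")

    # protein database
    proteins: dict[str, str] = {}
    site_by_tid: dict[str, list[SiteTruth]] = {}
    for st in site_truths:
        site_by_tid.setdefault(st.transcript_id, []).append(st)
    for k, g in enumerate(genes):
        if g.true_class == 4:
            continue
        prot_cds = list(g.mrna_cds)
        if g.true_class != 3:
            for st in site_by_tid.get(g.tid, []):
                ref_t = st.ref if g.strand == "+" else COMPLEMENT_BASE[st.ref]
                alt_t = st.alt if g.strand == "+" else COMPLEMENT_BASE[st.alt]
                prot_cds[st.cds_offset] = alt_t if st.prot_alt else ref_t
        prot = _translate_plain("".join(prot_cds))
        proteins[f"UP{k + 1:05d}"] = prot
    for d in range(config.n_decoy_proteins):
        n_aa = config.cds_len // 3 - 1 if d % 2 == 0 else int(rng.integers(40, 200))
        aas = "ACDEFGHIKLMNPQRSTVWY"
        proteins[f"DECOY{d + 1:03d}"] = "".join(
            aas[i] for i in rng.integers(0, len(aas), size=n_aa)
        )
    f_prot = outdir / "proteins.fa"
    with open(f_prot, "w") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n{seq}\n")

    # VCF on old coordinates
    vcf_entries: list[tuple[str, int, str, str, str]] = []
    tri_handled = {id(st): (alt1, af1) for st, alt1, af1 in tri_rows}
    for st in site_truths:
        old_chrom, old_pos, inv = to_old(st.chrom, st.pos)
        ref_f = st.alt if st.switched else st.ref
        alt_f = st.ref if st.switched else st.alt
        af = 1.0 - st.aaf if st.switched else st.aaf
        if inv:
            ref_f, alt_f = COMPLEMENT_BASE[ref_f], COMPLEMENT_BASE[alt_f]
        if id(st) in tri_handled:
            alt1, af1 = tri_handled[id(st)]
            if inv:
                alt1 = COMPLEMENT_BASE[alt1]
            vcf_entries.append(
                (old_chrom, old_pos, ref_f, f"{alt1},{alt_f}", f"{af1:.6g},{af:.6g}")
            )
        else:
            vcf_entries.append((old_chrom, old_pos, ref_f, alt_f, f"{af:.6g}"))
    vcf_entries.sort(key=lambda r: (r[0], r[1]))
    f_vcf = outdir / "sites_old.vcf"
    with open(f_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=refconcord simulate\n")
        for name, seq in old_chroms.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternative allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, af in vcf_entries:
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\tAF={af}\n")

    # pileup text at editing sites (new coordinates, mpileup -s style)
    f_pileup = outdir / "pileup.txt"
    with open(f_pileup, "w") as fh:
        for et in editing_truths:
            ref_fwd = new_sequences[et.chrom][et.pos]
            edited_fwd = "G" if et.strand == "+" else "C"
            n_g = int(rng.binomial(config.read_depth, et.fraction))
            n_ref = config.read_depth - n_g
            entries = ["."] * n_ref + [edited_fwd] * n_g
            order = rng.permutation(len(entries))
            entries = [entries[i] for i in order]
            quals = ["I"] * len(entries)
            mapqs = ["]"] * len(entries)
            # decorate with reads the filters must exclude
            entries = ["^]" + entries[0]] + entries[1:]
            entries.append(".")  # low base quality
            quals.append("#")
            mapqs.append("]")
            entries.append(edited_fwd)  # low mapping quality
            quals.append("I")
            mapqs.append("&")
            entries.append(".+2AC")  # read with an insertion here
            quals.append("I")
            mapqs.append("]")
            fh.write(
                f"{et.chrom}\t{et.pos + 1}\t{ref_fwd}\t{len(quals)}\t"
                f"{''.join(entries)}\t{''.join(quals)}\t{''.join(mapqs)}\n"
            )

    # ground truth TSVs
    truth.sites = site_truths
    truth.editing = editing_truths
    f_truth_tx = outdir / "truth_transcripts.tsv"
    write_report(
        [{"transcript_id": t, "true_class": c} for t, c in truth.true_class.items()],
        f_truth_tx,
    )
    f_truth_sites = outdir / "truth_sites.tsv"
    write_report([_site_row(st) for st in site_truths], f_truth_sites)
    f_truth_edit = outdir / "truth_editing.tsv"
    write_report(
        [{"chrom": e.chrom, "pos1": e.pos + 1, "strand": e.strand,
          "fraction": e.fraction, "transcript_id": e.transcript_id}
         for e in editing_truths],
        f_truth_edit,
    )

    truth.files = {
        "genome_new": f_new, "genome_old": f_old, "chain": f_chain,
        "refflat": f_refflat, "ccds": f_ccds, "mrna": f_mrna,
        "cds_sidecar": f_sidecar, "proteins": f_prot, "vcf": f_vcf,
        "pileup": f_pileup, "truth_transcripts": f_truth_tx,
        "truth_sites": f_truth_sites, "truth_editing": f_truth_edit,
    }
    return truth


def _site_row(st: SiteTruth) -> dict[str, object]:
    d = asdict(st)
    d["pos1"] = st.pos + 1
    del d["pos"]
    for flag in ("inverted", "switched", "mrna_alt", "prot_alt", "triallelic", "planted"):
        d[flag] = int(d[flag])
    return d


def _translate_plain(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = codon_to_aa(cds[i : i + 3])
        if aa == "*" and i == len(cds) - 3:
            break
        aas.append(aa)
    return "".join(aas)


def _effect(g: _Gene, off: int, ref_t: str, alt_t: str) -> str:
    """Synonymous / non-synonymous status of ref->alt in the mRNA codon context."""
    ci = off // 3
    codon = "".join(g.mrna_cds[3 * ci : 3 * ci + 3])
    j = off % 3
    a = codon_to_aa(codon[:j] + ref_t + codon[j + 1 :])
    b = codon_to_aa(codon[:j] + alt_t + codon[j + 1 :])
    return "synonymous" if a == b else "non-synonymous"
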