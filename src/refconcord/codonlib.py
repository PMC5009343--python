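"""CDS translation with irregular-translation rules, plus codon utilities.

Known RefSeq mRNAs depart from plain standard-table translation in three
ways, all of which are honoured here: (i) a ribosomal slip can shift the
reading frame at a declared CDS position, (ii) a declared TAG codon encodes
selenocysteine (U) rather than termination, and (iii) a non-ATG first codon
is nevertheless translated to methionine.  Premature stops outside these
exceptions are flagged on the result, never raised, so that stop-loss
phenomena (e.g. RNA editing converting a premature TAG to TGG) can be
observed by comparing results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Data.CodonTable import standard_dna_table

from .refio import TranscriptSeq

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

SYNONYMOUS = "synonymous"
NON_SYNONYMOUS = "non-synonymous"


def codon_to_aa(codon: str) -> str:
    """Translate one codon; stops give '*', any N gives 'X'."""
    codon = codon.upper()
    if "N" in codon:
        return "X"
    if codon in _STOP_CODONS:
        return "*"
    try:
        return _CODON_TABLE[codon]
    except KeyError as exc:
        raise ValueError(f"not a DNA codon: {codon!r}") from exc


@dataclass
class TranslationResult:
    protein: str
    applied_exceptions: list[str] = field(default_factory=list)
    premature_stop_at: Optional[int] = None  # codon index of first unexplained stop


def _effective_cds(seq: str, frameshift: Optional[tuple[int, int]]) -> tuple[str, bool]:
    """Apply a ribosomal slip: at CDS position ``pos`` the frame moves by
    ``shift`` (+1 skips a base, -1 re-reads the previous base)."""
    if frameshift is None:
        return seq, False
    pos, shift = frameshift
    if shift not in (-1, 1):
        raise ValueError(f"frameshift shift must be ±1, got {shift}")
    if not 0 < pos < len(seq):
        raise ValueError(f"frameshift position {pos} outside CDS")
    if shift == 1:
        return seq[:pos] + seq[pos + 1 :], True
    return seq[:pos] + seq[pos - 1 :], True


def translate_cds(t: TranscriptSeq) -> TranslationResult:
    """Translate a CDS honouring the transcript's declared exceptions.

    The terminal stop codon is stripped from the protein.  An internal stop
    not covered by a selenocysteine exception is kept as '*' in the protein
    and reported via ``premature_stop_at`` (first such codon index).
    """
    exc = t.exceptions
    applied: list[str] = []
    seq, shifted = _effective_cds(t.cds_sequence.upper(), exc.frameshift_offset)
    if shifted:
        applied.append("frameshift")
    if len(seq) % 3:
        # frameshifted CDS may leave a dangling tail; translate whole codons
        seq = seq[: len(seq) - len(seq) % 3]
    sec = set(exc.stop_codon_redefined_to_sec)
    residues: list[str] = []
    premature: Optional[int] = None
    n_codons = len(seq) // 3
    for ci in range(n_codons):
        codon = seq[3 * ci : 3 * ci + 3]
        if ci in sec:
            if codon != "TAG":
                raise ValueError(
                    f"{t.transcript_id}: selenocysteine declared at codon {ci} "
                    f"but codon is {codon}, not TAG"
                )
            residues.append("U")
            if "selenocysteine" not in applied:
                applied.append("selenocysteine")
            continue
        aa = codon_to_aa(codon)
        if aa == "*":
            if ci == n_codons - 1:
                break  # terminal stop stripped
            if premature is None:
                premature = ci
        residues.append(aa)
    if exc.non_atg_start and residues:
        if residues[0] != "M":
            residues[0] = "M"
            applied.append("non_atg_start")
    return TranslationResult(
        protein="".join(residues),
        applied_exceptions=applied,
        premature_stop_at=premature,
    )


def classify_substitution(genome_codon: str, mrna_codon: str, codon_offset: int) -> str:
    """Classify a single-base codon substitution as synonymous or not.

    The two codons must differ at exactly ``codon_offset`` (a single SNV);
    anything else is a contract error.  Codons containing N are
    non-comparable and raise ValueError.
    """
    genome_codon, mrna_codon = genome_codon.upper(), mrna_codon.upper()
    if len(genome_codon) != 3 or len(mrna_codon) != 3:
        raise ValueError("codons must be length 3")
    diffs = [i for i in range(3) if genome_codon[i] != mrna_codon[i]]
    if diffs != [codon_offset]:
        raise ValueError(
            f"codons {genome_codon}/{mrna_codon} do not differ exactly at "
            f"offset {codon_offset} (differ at {diffs})"
        )
    a, b = codon_to_aa(genome_codon), codon_to_aa(mrna_codon)
    if "X" in (a, b):
        raise ValueError("codon containing N is non-comparable")
    return SYNONYMOUS if a == b else NON_SYNONYMOUS


def longest_homopolymer_run(protein: str, residue: str) -> int:
    """Length of the longest run of ``residue`` in ``protein`` (0 if absent)."""
    if len(residue) != 1:
        raise ValueError("residue must be a single amino-acid letter")
    best = cur = 0
    for aa in protein:
        cur = cur + 1 if aa == residue else 0
        best = max(best, cur)
    return best
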