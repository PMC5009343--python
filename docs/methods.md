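# Methods

This note documents the models and procedures `refconcord` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Coordinates and containers

All in-memory coordinates are 0-based half-open on the forward strand.  VCF
and pileup positions are converted on read (−1) and write (+1); refFlat and
chain files are natively 0-based and pass through unchanged.  A single
convention removes the off-by-one churn that otherwise accumulates across
refFlat (0-based), VCF (1-based) and pileup (1-based) inputs.

## Transcript-vs-genome comparison

The spliced CDS of a gene model is the concatenation of exonic bases within
`[cds_start, cds_end)`, reverse-complemented for minus-strand models.  An
mRNA CDS is compared to it through a per-base correspondence:

* equal sequences correspond positionally;
* otherwise a global edit-distance alignment (edlib, unit costs) decides.
  An isolated substitution costs 1 while a gap pair costs 2, so
  substitution-only pairs keep the positional correspondence; runs of mRNA
  bases absent from the genome surface as `I` operations and are recorded as
  missing segments; genome-only stretches are treated as unannotated
  intronic gaps, not as errors, because only mRNA bases missing from the
  genome count toward class 3.

Classes are exclusive in order: any missing base ⇒ class 3, else any
mismatch ⇒ class 2, else class 1; a transcript with no locus is class 4.

**Best locus.**  Score = mismatching + missing bases.  Ties prefer canonical
chromosomes (autosomes + sex chromosomes) over alternative scaffolds, then
break deterministically by (chromosome name, CDS start).

**Reconciliation.**  Per-source classes (UCSC refFlat, CCDS, internal
aligner) combine as: CCDS wins whenever it annotates the transcript (class
< 4), because it is the most intensively curated source; otherwise the
better (lower) class of the remaining sources, preferring the curated UCSC
annotation over the aligner on ties.

**Spliced matcher.**  A deliberately bounded stand-in for a genome-scale
aligner, adequate for desk-scale genomes (hundreds of kilobases): exact
k-mer seeding (default `seed_len = 16`, k-mers occurring > 64 times masked),
colinear chaining maximising covered query length (introns up to 1 Mb, the
scale of the longest known introns), and exon-block construction.  Unseeded
query bases at an exon boundary (a substitution near the boundary destroys
all seeds covering it) are split between the flanking exons at the split
maximising base matches, with a +3 bonus per canonical splice signal (GT..AG
on the transcript strand) at the implied intron edges.  Chains covering
< 50 % of the query are discarded.  The matcher guarantees recovery of loci
whose exons each contain at least one exact seed; its known limitation is
that a substitution immediately adjacent to an exon boundary can
occasionally be absorbed into a shifted boundary (the alignment with fewer
mismatches is genuinely ambiguous there).  In the full pipeline the curated
annotations dominate through reconciliation, which is precisely why multiple
sources are reconciled rather than trusting any single aligner.

## Translation

Standard nuclear codon table (via Biopython's table), with three irregular
patterns honoured per transcript: a ribosomal frameshift declared as
(0-based CDS position, ±1 shift; one per transcript), TAG codons at declared
indices read as selenocysteine (U), and a non-ATG first codon forced to Met.
The terminal stop is stripped; an internal stop outside the declared
exceptions is kept as `*` and flagged (`premature_stop_at`) rather than
raised, so stop-loss phenomena (e.g. editing TAG→TGG) are observable by
comparing translations.  Codons containing N translate to X and are excluded
from synonymous/non-synonymous tallies.

## Liftover, inversions, allele switches

Positions map affinely within chain blocks (mirror-wise within minus-strand
blocks); inter-block gaps are unmapped.  Inversion detection compares the
21-nt context of the lifted site (10 bases each side) on the new assembly
against the old assembly's forward and reverse strands using Hamming
distance — deterministic, and matched to the fixed-width window design; ties
count as "not inverted" and are logged.  Windows are truncated symmetrically
at contig ends to the largest shared flank, avoiding padding bias.  After
complementing the alleles of inverted sites, a new-assembly base equal to
the alternative allele marks a ref/alt switch: alleles are swapped and
AAF ← 1 − AAF, conserving the two allele frequencies' total.  A new-assembly
base matching neither allele is kept but flagged `allele_mismatch` and
excluded from concordance tallies.

## Protein allele determination

Exact full-length match to any database entry supports the mRNA translation
at every position.  Otherwise all same-length entries are scanned directly
(a pre-filter adds nothing at desk scale) and the best entry with identity
≥ 0.95 decides by its residue at the variant codon; equal-identity ties
prefer the entry agreeing with the mRNA translation (conservative toward
concordance).  Entries of different length never qualify — substitution
candidates must be same-length by construction — and a variant in the
stripped terminal stop codon has no residue to compare; both cases are
"undetermined" and excluded from the concordance table.

## AAF summaries

Bins are half-open `[lo, hi)` with the final bin closed (so AAF = 1.0 falls
in the last bin).  Products per effect stratum: 5 % density panels
(densities normalised to sum to 1 within a stratum) for all sites and for
discordant sites; 1 % count curves above 50 % AAF; and the discordant
fraction per 1 % bin, defined as 0 where the denominator is 0.

## RNA editing

Pileup reads are excluded in order: mapping quality < 30, base quality < 30
(Phred+33), insertion at the position; deletion placeholders and N bases are
dropped without counting as exclusions.  Counts are kept in forward
orientation and complemented onto the transcript strand for minus-strand
genes (A→G editing reads as T→C forward).  Only genome-A/mRNA-G
substitutions with no known variant are tier-eligible; the retained G
fraction is tiered at ≥ 0.05 (strong) and ≥ 0.01 (weak), thresholds exposed
as parameters.  Counts pool additively across individuals.

## Synthetic data generator

The generator emulates the input universe the audit needs, with recorded
ground truth; its defaults are the package's standard study conditions:

* **Genome**: 2 chromosomes × 160 kb plus an alternative scaffold carrying
  duplicated copies of two loci (exercising the canonical-preference rule);
  200 genes of 3 exons, 300-nt CDS, 30-nt UTRs, introns of 50–300 nt with
  canonical splice dinucleotides.
* **Classes**: 20 transcripts with 1–3 planted substitutions (class 2), 6
  with genome-side deletions of {1, 3, 6, 12} bases (class 3, exercising the
  in-frame logic), 1 with no locus (class 4).  Planted substitutions are
  known population sites with probability 0.9, mirroring the ~90 % of
  observed mRNA/genome substitutions that match known variants.
* **Sites**: 5 000 biallelic coding sites.  AAF ~ 0.85·Beta(0.3, 3) +
  0.15·Beta(50, 1): a rare-variant excess plus a near-1 spike, the
  qualitative shape of population panels (parameters are the package's
  choice; panels publish shapes, not these parameters).  Alternative alleles
  never create stop codons, keeping every translation comparable.
* **Per-database allele choices**, independent per site: old assembly 0.02,
  mRNA 0.004, protein 0.01.  Desk-scale rates chosen large enough to
  populate all eight concordance categories at n = 5 000 while keeping
  discordance rare; the old-assembly probability doubles as the
  allele-switch fraction, since a site switches ref/alt between versions
  exactly when the old assembly carries the alternative allele.
* **Old assembly**: built from the new one with random 37–200-nt spacers
  between alignment blocks (coordinate shifts) and 3 inverted blocks of
  1–3 kb (kept ≥ 15 nt clear of site positions so the 21-nt windows are
  unambiguous); the chain file is emitted alongside.
* **Editing**: 5 sites with true fractions (0.9, 0.5, 0.3, 0.1, 0.03) at
  read depth 100, plus decoy reads that the quality/insertion filters must
  remove.
* Two triallelic sites where the mRNA matches the second alternative allele.

Features of real data deliberately not emulated: linkage disequilibrium,
diploid genotypes, haplotype structure, sequencing error in the pileups
beyond the planted low-quality reads, micro-exons, alternative splicing
within a gene, and non-coding variation.  Passing tests therefore
demonstrate correctness of the audit machinery under clean conditions, not
robustness to alignment artefacts or annotation noise in real databases.

All randomness flows from a single seed (default 17); identical seeds give
byte-identical output files.

## Problem sizes

The standard conditions (200 transcripts, 5 000 sites, ~320 kb genome) were
chosen so the whole universe generates in under a second and the full
pipeline runs in a few seconds, which keeps exact-recovery and statistical
tests (99 % binomial confidence intervals) practical as ordinary unit tests.

## Known limitations

* The spliced matcher's boundary ambiguity described above: on its own it
  can mis-place an exon boundary next to a substitution; reconciliation with
  curated annotations resolves every such case in the test universe.
* Micro-exon rescue is out of scope: an apparent boundary mismatch that a
  short exon inside the intron would explain is reported as a mismatch.
* Only one frameshift per transcript is supported, matching known
  ribosomal-slip cases.
* Protein allele determination requires a same-length database entry;
  length-changing alleles (class 3) are not pushed through the protein
  comparison.
* Pileup parsing covers the mpileup dialect emitted by the generator
  (optional mapping-quality column); BAM/CRAM decoding is intentionally not
  part of the package — pileup text is the contract.
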