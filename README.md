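# refconcord

A concordance audit of the three kinds of reference sequence a genome
project maintains: the genome assembly itself, the mRNA database derived
from independent transcript evidence, and the protein database.  Because
each database fixed its reference sequences from different biological
materials, they disagree at polymorphic positions: one database may carry
the minor allele of a common variant as its "reference".  Such *discordant
variants* silently bias downstream annotation — a functional study may
characterise a rare allele believing it to be the canonical protein.

`refconcord` is for computational biologists who want to quantify and
localise these disagreements.  It takes a genome (two assembly versions),
transcript models (refFlat and a CCDS-style table), mRNA sequences with CDS
bounds, protein sequences, population variant panels (VCF with allele
frequencies), an assembly-to-assembly chain file and RNA-seq pileups, and
produces per-transcript concordance classes, per-site allele concordance
tables, allele-frequency summaries and RNA-editing evidence.

## The method

**Transcript classes.** Each mRNA's protein-coding sequence (CDS) is
compared against the spliced genomic sequence of its best locus and assigned
one of four classes:

1. CDS and genome match exactly;
2. substitutions only — every mRNA base aligns to the genome;
3. at least one mRNA base is missing from the genome (deletion
   polymorphisms, tandem-repeat length differences, unfinished genome
   sequence);
4. no locus found.

The best locus minimises (mismatching + missing) CDS bases; on a tie a
canonical chromosome beats an alternative scaffold.  Classes are computed
per annotation source (refFlat, CCDS, and a built-in k-mer seed-and-chain
spliced matcher) and reconciled: the CCDS class wins when CCDS annotates the
transcript, otherwise the better of the remaining classes.

**Allele frequencies across assembly versions.** Variant panels published on
the older assembly are lifted through the chain file.  The 21-nucleotide
context (ten bases each side) of each lifted site is compared against the
old assembly's forward and reverse strands; when it is strictly closer to
the reverse strand the region is inverted and the alleles are complemented.
If the new assembly's base then equals the alternative allele, reference and
alternative have switched roles between versions, so the alleles are swapped
and the alternative allele frequency (AAF) becomes 1 − AAF.

**Four-way concordance.** For each non-synonymous known site the allele
carried by the old genome, the mRNA database and the protein database is
expressed relative to the current genome (`Ref`/`Alt`) and tallied over the
2³ categories.  The protein allele is decided by exact full-length match or,
failing that, by the best same-length entry with ≥ 95 % sequence identity.

**RNA editing.** Discordant A→G substitutions (transcript strand) with no
known variant are tested against RNA-seq pileups filtered at mapping
quality ≥ 30 and base quality ≥ 30, excluding reads with an insertion at the
position.  The retained G fraction is tiered at 0.05 (strong) and 0.01
(weak).

Translation honours the irregular patterns real transcript records declare:
ribosomal frameshifts, TAG read as selenocysteine, and non-ATG start codons
translated to methionine.

## Worked example

The classic missing-bases case is a glutamate repeat: the mRNA reference
allele carries thirteen GAG codons where the genome carries twelve, both
followed by one GAA and three GAG codons.

```python
from refconcord import TranscriptSeq, translate_cds, longest_homopolymer_run

mrna   = "ATG" + "GAG"*13 + "GAA" + "GAG"*3 + "TAA"   # mRNA reference allele
genome = "ATG" + "GAG"*12 + "GAA" + "GAG"*3 + "TAA"   # genome reference allele
for name, cds in [("mRNA allele", mrna), ("genome allele", genome)]:
    protein = translate_cds(TranscriptSeq(name, cds)).protein
    print(f"{name}: {len(cds)} nt -> {protein}")
    print(f"  longest Glu run: {longest_homopolymer_run(protein, 'E')}")
```

prints

```
mRNA allele: 57 nt -> MEEEEEEEEEEEEEEEEE
  longest Glu run: 17
genome allele: 54 nt -> MEEEEEEEEEEEEEEEE
  longest Glu run: 16
```

i.e. the two alleles encode 17 versus 16 consecutive glutamates, and a
spliced comparison of the two CDS sequences reports three mRNA bases missing
from the genome — an in-frame amino-acid insertion/deletion polymorphism.

## Command line

Everything is also scriptable end to end:

```sh
refconcord simulate --seed 17 --out sim/          # synthetic universe + truth
refconcord report --config run.toml --out out/    # classify, lift, concord, rnaedit
refconcord classify --genome g.fa --mrna m.fa --cds-sidecar cds.tsv \
    --refflat rf.tsv --ccds ccds.tsv --out classes.tsv
refconcord lift --chain old_to_new.chain --vcf sites.vcf \
    --genome-new new.fa --genome-old old.fa --out lifted.vcf
```

`report` writes `classes.tsv`, `missing.tsv` (per-gene missing segments),
`lifted.vcf` (with `INV`/`SWAP` flags), `table1.tsv` (the eight concordance
categories), `hist.tsv` (AAF panels), `editing.tsv` and `manifest.json`
(input checksums and per-stage row accounting).

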