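# varsieve

Recessive-disease variant prioritization from a **single affected proband**.

When one animal (or patient) presents with a suspected autosomal-recessive
Mendelian disease and whole-genome sequencing yields millions of variant
calls, the causal allele is found not by statistics but by a disciplined
cascade of filters: remove what is common in the population, keep what
damages a protein, demand a genotype configuration compatible with recessive
inheritance (homozygous, or two hets *in trans* in one gene), distrust genes
with known reference-assembly problems, require two independent annotation
sources to agree, and finally intersect with the genes known to cause the
phenotype. `varsieve` implements that cascade as a tested, auditable
library and command-line tool, from VCF to a nominated candidate, with every
step's counts recorded in a ledger.

The motivating use case is a canine lysosomal storage disease
(mucopolysaccharidosis type I) caused by a homozygous 8-nt frameshift
insertion in the first coding exon of *IDUA* (alpha-L-iduronidase),
`c.19_20insCGGCCCCC`. That allele exercises almost everything the package
does:

* the locus is repetitive — CDS bases 4–19 are two tandem copies of the
  insert — so the insertion is equivalently placeable after any base from
  3 to 19 (`PlacementRange`), and VCF left-alignment and the HGVS 3' rule
  pick opposite ends of the run;
* the gene is on the genomic minus strand, so the transcript insert
  `CGGCCCCC` appears in genomic coordinates as its reverse complement
  `GGGGGCCG`;
* the insertion length (8 ≡ 2 mod 3) shifts the reading frame after codon 6
  and translation runs into a premature stop, truncating the protein.

## What it computes

For a variant $g.$`pos`$\,\mathrm{REF}{>}\mathrm{ALT}$ and a transcript with
spliced CDS $S$, the engine edits $S$ in transcript orientation, translates
both alleles with the standard code to the first stop, and reports the
category (frameshift, stop_gained, stop_lost, start_lost, splice
donor/acceptor, inframe indel, missense, synonymous, intronic, UTR,
intergenic), an impact tier (HIGH/MODERATE/LOW/MODIFIER via a fixed,
auditable map), the wild-type and mutant protein lengths, and the first
divergent residue. Indels are normalized two ways on purpose: leftmost
minimal representation for storage and panel matching; most-3' equivalent
placement on the transcript strand for c. reporting.

The cascade, in order, with a conservation-checked ledger
(`in = removed + kept` at every step):

1. **normalize** — left-align, deduplicate, count unsupported records
2. **panel** — drop variants with control-panel MAF strictly > 1 %
3. **recessive_high_impact** — keep hom-alt or het variants with a HIGH call
   under annotation source A
4. **compound_het** — hets survive only in genes with ≥ 2 qualifying hets
   forming a trans (or phase-unresolved) pair; cis-only pairs are dropped
5. **assembly_flags** — drop variants confined to assembly-flagged genes
6. **concordance** — require HIGH under annotation source B as well
7. **candidate_genes** — intersect with the disease gene list

## Worked example

No real data is required: the `simulate` subcommand writes a complete world
(reference FASTA, two GFF3 annotation sources, a 100-dog control-panel VCF,
a proband VCF with one planted causal insertion among structured decoys,
gene lists, and a ground-truth manifest).

```bash
varsieve simulate --seed 7 --out demo
varsieve run --vcf demo/proband.vcf --panel demo/panel.vcf \
    --fasta demo/reference.fa --gff-a demo/annotation_a.gff3 \
    --gff-b demo/annotation_b.gff3 --flags demo/flagged_genes.txt \
    --candidates demo/candidate_genes.txt --out demo/out
```

prints

```
Filtration cascade
==================================================================
step                          in   removed    kept   genes
normalize                    100         0     100       0
panel                        100        36      64       0
recessive_high_impact         64        27      37      25
compound_het                  37        24      13       7
assembly_flags                13         6       7       4
concordance                    7         6       1       1
candidate_genes                1         0       1       1

Final candidates (1):
  chr2:g.8010_8011insGGGGGCCG (c.19_20insCGGCCCCC) [G022] frameshift/HIGH, homozygous; protein 18 aa instead of 87 aa, divergence at residue 7
```

Reading the output: 100 proband variants enter; 36 panel-common decoys fall
at the MAF filter; 27 low-impact ones at the impact/zygosity partition; 24
unpaired or cis-configured hets at the compound-het step; 6 in
assembly-flagged genes; 6 whose HIGH impact the second annotation source
does not confirm; the survivor is the planted homozygous frameshift — a
minus-strand gene, so the genomic `insGGGGGCCG` is reported on the
transcript as `c.19_20insCGGCCCCC`, with the frame shifting after residue 6
and a premature stop truncating the protein (here 18 aa instead of 87 on the
synthetic transcript). Exit code 0 means candidates were found; 3 is the
documented "clean run, no candidate" code.

Single-variant interrogation:

```bash
varsieve consequence --fasta demo/reference.fa --gff demo/annotation_a.gff3 \
    --transcript gene022.t1 --hgvs-c "c.19_20insCGGCCCCC"
```

```
variant (left-aligned): chr2:8010:T:TGGGGGCCG
hgvs_g: chr2:g.8010_8011insGGGGGCCG
equivalent genomic placements: after any base from 8010 to 8026
-- transcript gene022.t1 (G022, strand -)
   category: frameshift  tier: HIGH
   hgvs_c: c.19_20insCGGCCCCC
   protein: 18 aa instead of 87 aa, first divergent residue 7
```

The same API is available from Python (`varsieve.run_cascade`,
`varsieve.classify`, `varsieve.generate_world`, ...); see `docs/methods.md`
for the model and the generator's assumptions.

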