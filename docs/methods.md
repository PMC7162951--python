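# Methods

## Problem and model

`varsieve` addresses single-proband prioritization of an autosomal-recessive
causal variant. The underlying genetic model is simple and explicit: the
disease allele is rare (absent or < 1 % minor-allele frequency in a control
panel), damaging at the protein level (HIGH-impact consequence), and present
in a recessive-compatible configuration — either homozygous, or as two
heterozygous damaging alleles of the same gene on opposite haplotypes
(compound heterozygosity). Everything else in the pipeline is bookkeeping to
apply that model reproducibly: coordinate projection between genomic and
coding frames, indel normalization, consequence prediction by direct CDS
editing and translation, and an audited sequence of set subtractions.

## Coordinate frames and normalization

Genomic coordinates are 1-based inclusive throughout (the native convention
of GFF3 and VCF); conversions happen only at I/O boundaries. Coding (c.)
positions cover the CDS only, 1 at the A of the start codon, counted in
transcription order; UTR and intronic positions are reported as designations
with offsets rather than negative/star coordinates, because the analysis
concerns coding variants.

Indels get **two** canonical forms, deliberately:

* *Left alignment* (storage, panel matching): shared suffix trimmed —
  extending leftward through the reference when the variant would lose its
  anchor — then the shared prefix beyond one anchor base. The operation is
  idempotent and haplotype-preserving (property-tested against a
  brute-force enumeration of all VCF representations, shortest-then-leftmost).
  Panel matching on left-aligned keys means an equivalent representation of
  a common indel cannot slip past the frequency filter.
* *HGVS 3' rule* (reporting): insertions and deletions are shifted to their
  most 3' equivalent placement on the transcript strand, with inserted
  sequence given in transcript orientation.

**Equivalent placements.** In repetitive sequence, one physical insertion
corresponds to a contiguous run of insertion points. Equivalence is
rotation-aware: sliding the insertion point by one base within a repeat
rotates the inserted string by one character, and two placements are
equivalent exactly when they rebuild the byte-identical alternate sequence.
With the literal same insert string the equivalent points of a tandem
repeat are spaced by the repeat period and do not form a run; only the
rotation-aware definition yields the contiguous interval that slippage
mutagenesis produces, and it is what `PlacementRange` reports. The run is
computed by bidirectional rotation shifting and verified in tests against
exhaustive enumeration over all insertion points and rotations.

## Consequence engine

A variant's effect on a transcript is decided by *doing the edit*: the
spliced CDS is modified in transcript orientation (REF bases outside the
CDS clipped), both alleles are translated with the standard genetic code to
the first stop codon (codons containing N translate to X; trailing partial
codons are ignored), and the category follows from what actually happened
to the protein — so any equivalent placement of the same indel receives the
same call, which is asserted as an invariant.

Category assignment: out-of-frame CDS indel → frameshift; in-frame indel →
inframe insertion/deletion; substitutions → start_lost (start codon hit and
residue 1 diverges from M; reported product length 0), stop_lost (stop codon
hit and translation reads through), stop_gained (premature stop), missense,
or synonymous. Splice donor/acceptor sites are the 2 intronic bases at each
junction of a CDS-interrupting intron; variants spanning several contexts
take the most severe applicable category. If an edited CDS never reaches a
stop codon the translated length is reported with a no-stop flag rather
than guessed.

The category→tier map (HIGH = frameshift, stop_gained, stop_lost,
start_lost, splice_donor, splice_acceptor; MODERATE = missense and in-frame
indels; LOW = synonymous; MODIFIER = non-coding) is a fixed table in
`consequence.IMPACT_BY_CATEGORY`, chosen to match the convention of the
standard annotators; keeping it explicit makes the downstream "high impact"
filter auditable.

## The cascade

Filter order is fixed (normalize → panel → impact/zygosity partition →
compound-het grouping → assembly flags → dual-source concordance →
candidate genes); the candidate step can be disabled to obtain the
genome-wide view, and assembly-flag exclusion and concordance commute
(tested). Parameters that matter:

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.01 | panel sites with MAF **strictly** above are removed; a site at exactly 1 % survives |
| `impact_floor` | HIGH | minimum tier to count as damaging, per source |
| phase handling | — | trans requires same phase set, alt alleles on opposite haplotypes; unconnected pairs are kept but flagged `phase-unresolved`, never promoted to trans |
| gene assignment | — | union of gene ids over a variant's consequence calls; a variant is removed by the assembly filter only if *every* such gene is flagged |

"Unique to the proband" is implemented as strict-MAF subtraction rather
than presence/absence: the two readings conflict for very rare panel
alleles, and the numeric rule is the reproducible one. Half-calls are
treated as missing genotypes (counted, excluded from zygosity partitioning);
symbolic/SV records are skipped with a count. The ledger enforces
`variants_in = variants_removed + variants_kept` at every step and chains
each step's kept set into the next; gene counts are reported alongside
variant counts because the two bases differ whenever a variant touches more
than one gene.

## The synthetic world

The generator emulates the motivating case's inputs at desk scale: 2 contigs × 40 kb,
36 genes (1–3 exons, GT..AG introns, both strands, stop-free ORFs built by
codon-level rejection sampling), a control panel of 100 diploid individuals
(MAF strata 0.005/0.01/0.02/0.05/0.25, including sites at exactly the
threshold), 11 candidate genes and 3 assembly-flagged genes, and a proband
callset of ~120 variants: one causal variant plus six decoy classes, each
built so that exactly one filter removes it (panel-common highs, private
low-impact, singleton het highs, cis het pairs, flagged-gene homs, and
annotation-discordant homs). All randomness flows from one seeded
generator; identical configurations are byte-identical on disk.

Design choices worth recording:

* **Causal allele.** The default planted variant reproduces the motivating
  allele exactly: an 8-nt CGGCCCCC insertion after c.19, homozygous, in a
  candidate gene. The causal gene's CDS begins `ATG` + `CGGCCCCC`×2 with
  base 20 ≠ C — the unique 5' context implied by the printed facts (an
  insertion at c.19_20 equivalently placeable after bases 3–19). This
  context also pins the anatomy: wild-type codon 7 starts with C but cannot
  be proline (base 20 ≠ C), while the mutant codon 7 is CCG = proline, so
  divergence at residue 7 is guaranteed, not probabilistic.
* **Annotation discordance.** Source B is a second GFF3 in which a few
  genes carry a CDS start shifted +3 into a second in-frame ATG. Both
  sources' models remain valid ORFs on the same sequence (a perturbed CDS
  *end* cannot be: any valid stop for one source is an internal stop for
  the other), and a start-codon SNV is then HIGH (start_lost) under A but
  5'-UTR MODIFIER under B — exercising the concordance filter exactly.
* **What is not emulated.** Read-level errors, genotype-quality noise,
  linkage structure, realistic genome composition, and the real 6-million
  variant scale. Passing the recovery tests therefore demonstrates the
  correctness of the filtering logic under the stated model, not robustness
  to calling artifacts; on real data the same cascade inherits whatever
  error modes the upstream caller has.

## Numerical and degenerate-input choices

Transcript models failing CDS invariants (length not a multiple of 3, no
ATG, missing terminal stop, internal stop) are flagged, warned about, and
retained rather than dropped; stop-exclusive GFF3 dialects are normalized to
stop-inclusive by codon inspection. Ties between overlapping contexts are
broken by a fixed severity order. Deterministic output ordering everywhere
is (contig, pos, alt). Problem sizes in the test suite (20 recovery seeds,
20 negative-control seeds, 500-case translation oracle, 1,000-case
normalization and compound-het oracles, ≤ 50 bp exhaustive placement
contexts) were chosen so the whole suite exercises every property at
comfortable desk scale.

## Known limitations

No structural variants, CNVs, breakends, gVCF, or liftover; no UTR/promoter
annotation or alternative genetic codes; recessive mode only (no dominant,
X-linked, or de novo logic, no trio support); no protein-domain annotation
or NMD prediction — the engine reports truncation, not mechanism. Compound
heterozygosity without phase information can only be flagged, not proven:
`phase-unresolved` survivors need orthogonal phasing before any causal
claim. Verification of the package against the real dog *IDUA* transcript
(655-aa wild type, 108-aa truncated mutant, chr3 projection) requires that
transcript as an external input; the corresponding test states how to
supply it.
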