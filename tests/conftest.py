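"""Shared fixtures: a seeded synthetic world and hand-built toy transcripts."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pytest

from varsieve.genome import ReferenceGenome, TranscriptModel, read_fasta, read_gff3
from varsieve.prioritize import PanelSite, read_panel
from varsieve.simulate import ScenarioConfig, generate_world
from varsieve.variants import Callset, read_vcf


@dataclass
class World:
    paths: object
    truth: object
    genome: ReferenceGenome
    transcripts_a: list[TranscriptModel]
    transcripts_b: list[TranscriptModel]
    callset: Callset
    panel: dict[str, PanelSite]
    flagged: set[str]
    candidates: set[str]


def load_world(paths, truth) -> World:
    genome = read_fasta(str(paths.fasta))
    return World(
        paths=paths,
        truth=truth,
        genome=genome,
        transcripts_a=read_gff3(str(paths.gff_a), genome),
        transcripts_b=read_gff3(str(paths.gff_b), genome),
        callset=read_vcf(str(paths.proband_vcf)),
        panel=read_panel(str(paths.panel_vcf)),
        flagged=set(paths.flags.read_text().split()),
        candidates=set(paths.candidates.read_text().split()),
    )


@pytest.fixture(scope="session")
def world7(tmp_path_factory) -> World:
    """The default scenario, seed 7: one planted homozygous frameshift."""
    out = tmp_path_factory.mktemp("world7")
    paths, truth = generate_world(ScenarioConfig(seed=7), out)
    return load_world(paths, truth)


def make_transcript(
    cds: str,
    strand: str = "+",
    contig: str = "chrT",
    cds_offset: int = 100,
    flank: int = 120,
    gene_id: str = "geneT",
    symbol: str = "GT",
    rng=None,
) -> tuple[ReferenceGenome, TranscriptModel]:
    """Single-exon transcript whose CDS is ``cds`` (transcript orientation),
    embedded in random-free flanking A/C/G/T filler."""
    import numpy as np

    rng = rng or np.random.default_rng(0)
    bases = "ACGT"
    filler = lambda n: "".join(bases[i] for i in rng.integers(0, 4, size=n))
    genomic_cds = cds
    if strand == "-":
        from varsieve.genome import reverse_complement

        genomic_cds = reverse_complement(cds)
    left = filler(cds_offset - 1)
    right = filler(flank)
    seq = left + genomic_cds + right
    genome = ReferenceGenome({contig: seq})
    cds_start = cds_offset
    cds_end = cds_offset + len(cds) - 1
    t = TranscriptModel(
        transcript_id="tT",
        gene_id=gene_id,
        gene_symbol=symbol,
        contig=contig,
        strand=strand,
        exons=((max(1, cds_start - 20), min(len(seq), cds_end + 20)),),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    return genome, t


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no varsieve internals)
# ---------------------------------------------------------------------------

ORACLE_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(seq: str) -> tuple[str, bool]:
    """Codon-by-codon lookup translation to the first stop."""
    protein = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            protein.append("X")
            continue
        aa = ORACLE_CODON_TABLE[codon]
        if aa == "*":
            return "".join(protein), True
        protein.append(aa)
    return "".join(protein), False


def oracle_normalize(chrom: str, seq: str, alt_hap: str):
    """Leftmost-minimal VCF representation by brute force: enumerate every
    (pos, ref, alt) whose substitution into ``seq`` rebuilds ``alt_hap``,
    then take the shortest, leftmost one."""
    best = None
    L = len(seq)
    for pos in range(1, L + 1):
        for ref_len in range(1, L - pos + 2):
            alt_len = len(alt_hap) - (L - ref_len)
            if alt_len < 1:
                continue
            ref = seq[pos - 1 : pos - 1 + ref_len]
            alt = alt_hap[pos - 1 : pos - 1 + alt_len]
            if ref == alt:
                continue
            if seq[: pos - 1] + alt + seq[pos - 1 + ref_len :] != alt_hap:
                continue
            cand = (ref_len + alt_len, pos)
            if best is None or cand < best[0]:
                best = (cand, ref, alt)
    (_, pos), ref, alt = best
    return chrom, pos, ref, alt


def oracle_placements(context: str, insert: str, alt: str) -> set[int]:
    """All positions after which an insertion event can reproduce ``alt``,
    by brute force over every insertion point and every rotation of the
    inserted sequence (the same physical duplication written at a different
    offset of a repeat carries a rotated allele)."""
    rotations = {insert[i:] + insert[:i] for i in range(len(insert))}
    return {
        p
        for p in range(len(context) + 1)
        for rot in rotations
        if context[:p] + rot + context[p:] == alt
    }


def oracle_compound_het(genes: dict[str, list[dict]]) -> dict[str, list[tuple]]:
    """Brute-force pairwise enumeration of qualifying het pairs per gene.

    Each variant dict: {key, phased, ps, hap} where hap is 0/1 for the
    haplotype carrying the alt allele (None when unphased).
    """
    out = {}
    for gene, variants in genes.items():
        pairs = []
        for i in range(len(variants)):
            for j in range(i + 1, len(variants)):
                v1, v2 = variants[i], variants[j]
                k1, k2 = sorted([v1["key"], v2["key"]])
                if (
                    v1["phased"]
                    and v2["phased"]
                    and v1["ps"] is not None
                    and v1["ps"] == v2["ps"]
                ):
                    if v1["hap"] != v2["hap"]:
                        pairs.append((k1, k2, "trans"))
                    # same haplotype: proven cis, excluded
                else:
                    pairs.append((k1, k2, "phase-unresolved"))
        if pairs:
            out[gene] = pairs
    return out
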