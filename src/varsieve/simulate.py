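"""Self-contained synthetic test worlds for the prioritization cascade.

A world is a reference FASTA, two GFF3 annotation sources, a control-panel
sites VCF, a single-proband VCF, candidate/flagged gene lists, and a JSON
ground-truth manifest.  The proband callset contains one planted causal
variant (by default a homozygous out-of-frame insertion mimicking an
8-nt CGGCCCCC insertion after coding position 19 of a candidate gene)
surrounded by decoy classes, each constructed to be removed by exactly one
filter of the cascade:

* ``common_high``       — high-impact but present in the panel at MAF > 1%
* ``private_low``       — absent from the panel but synonymous/intronic
* ``singleton_het_high``— heterozygous high-impact, alone in its gene
* ``cis_het_pair``      — two phased high-impact hets on the same haplotype
* ``flagged_gene``      — homozygous high-impact in an assembly-flagged gene
* ``source_discordant`` — high-impact under annotation source A only

The control panel spans MAF strata including sites at exactly the 1%
threshold (kept by the strict > rule).  Identical seeds give byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from Bio.Data import CodonTable

from .genome import ReferenceGenome, TranscriptModel, reverse_complement, translate
from .variants import (
    Callset,
    GenotypeCall,
    HgvsC,
    Variant,
    VariantCall,
    hgvs_c_to_variant,
    left_align,
    write_vcf,
)

__all__ = [
    "DecoyMix",
    "ScenarioConfig",
    "GroundTruth",
    "WorldPaths",
    "generate_world",
    "plant_frameshift",
    "build_panel",
    "CAUSAL_INSERT",
    "CAUSAL_MOTIF",
]

_STOPS = set(CodonTable.standard_dna_table.stop_codons)
_CODONS = [c for c in CodonTable.standard_dna_table.forward_table]
_FWD = CodonTable.standard_dna_table.forward_table
_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CAUSAL_INSERT = "CGGCCCCC"
# 5' CDS context of the emulated causal gene.  The reported anatomy of the
# canine MPS I allele (an 8-nt CGGCCCCC insertion at c.19_20 whose
# equivalent placements extend after bases 3-19) forces CDS bases 4-19 to be
# two tandem copies of the insert, with base 20 not C.
CAUSAL_MOTIF = "ATG" + CAUSAL_INSERT * 2


@dataclass
class DecoyMix:
    """Fractions of the proband callset assigned to each decoy class."""

    common_high: float = 0.30
    private_low: float = 0.25
    singleton_het_high: float = 0.10
    cis_het_pair: float = 0.10
    flagged_gene: float = 0.05
    source_discordant: float = 0.05

    def total(self) -> float:
        return sum(dataclasses.asdict(self).values())


@dataclass
class ScenarioConfig:
    seed: int = 7
    n_contigs: int = 2
    contig_length: int = 40_000
    n_genes: int = 36
    n_candidate_genes: int = 11
    n_flagged_genes: int = 3
    panel_samples: int = 100
    n_proband_variants: int = 120
    decoy_mix: DecoyMix = field(default_factory=DecoyMix)
    causal_mode: str = "hom_frameshift"  # 'hom_frameshift' | 'compound_het_trans' | 'none'
    causal_insert: str = CAUSAL_INSERT
    causal_c_anchor: int = 19

    def __post_init__(self):
        if self.decoy_mix.total() > 1.0 + 1e-9:
            raise ValueError("decoy fractions sum to more than 1")
        if self.causal_mode not in {"hom_frameshift", "compound_het_trans", "none"}:
            raise ValueError(f"unknown causal mode {self.causal_mode!r}")


@dataclass
class GroundTruth:
    causal_keys: list[str]
    causal_gene: str | None
    causal_gene_symbol: str | None
    expected_final: list[str]
    classes: dict[str, list[str]]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class WorldPaths:
    root: Path
    fasta: Path
    gff_a: Path
    gff_b: Path
    panel_vcf: Path
    proband_vcf: Path
    flags: Path
    candidates: Path
    ground_truth: Path
    scenario: Path


@dataclass
class _Gene:
    gene_id: str
    symbol: str
    contig: str
    strand: str
    start: int  # genomic 1-based start of the gene region
    sense_seq: str  # gene region in transcript orientation
    segments: list[tuple[str, int, int]]  # (kind, sense_start, sense_end) 1-based
    utr5: int
    cds_len: int
    role: str = "neutral"
    used_sense: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.sense_seq)

    def sense_to_genomic(self, i: int) -> int:
        if self.strand == "+":
            return self.start + i - 1
        return self.start + self.length - i

    def mrna_to_sense(self, m: int) -> int:
        """mRNA coordinate (introns removed) -> gene-sense coordinate."""
        consumed = 0
        for kind, s, e in self.segments:
            if kind != "exon":
                continue
            seg_len = e - s + 1
            if m <= consumed + seg_len:
                return s + (m - consumed - 1)
            consumed += seg_len
        raise ValueError(f"mRNA coordinate {m} beyond transcript")

    def cds_index_to_genomic(self, c: int) -> int:
        return self.sense_to_genomic(self.mrna_to_sense(self.utr5 + c))

    def exon_genomic_intervals(self) -> list[tuple[int, int]]:
        out = []
        for kind, s, e in self.segments:
            if kind != "exon":
                continue
            g1, g2 = self.sense_to_genomic(s), self.sense_to_genomic(e)
            out.append((min(g1, g2), max(g1, g2)))
        return sorted(out)

    def cds_genomic_bounds(self, mrna_start: int | None = None) -> tuple[int, int]:
        m1 = mrna_start if mrna_start is not None else self.utr5 + 1
        m2 = self.utr5 + self.cds_len
        g1 = self.sense_to_genomic(self.mrna_to_sense(m1))
        g2 = self.sense_to_genomic(self.mrna_to_sense(m2))
        return min(g1, g2), max(g1, g2)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    symbol: str,
    contig: str,
    start: int,
    role: str,
) -> _Gene:
    strand = "+" if rng.random() < 0.5 else "-"
    n_codons = int(rng.integers(70, 140))
    utr5 = int(rng.integers(10, 31))
    utr3 = int(rng.integers(10, 31))

    if role == "causal":
        # 5' context implied by the reference allele's reported anatomy
        head = CAUSAL_MOTIF  # bases 1..19 of the CDS
        b20 = "AGT"[int(rng.integers(0, 3))]  # base 20 must not extend the repeat
        b21 = _BASES[int(rng.integers(0, 4))]
        body = _random_codons(rng, n_codons - 8)
        cds = head + b20 + b21 + body
    elif role == "discordant":
        # second in-frame ATG lets source B annotate a start 3 bases in,
        # leaving the true first codon untranslated under source B
        cds = "ATG" + "ATG" + _random_codons(rng, n_codons - 3)
    else:
        cds = "ATG" + _random_codons(rng, n_codons - 2)
    cds += ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]
    cds_len = len(cds)

    mrna = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
    n_introns = int(rng.integers(0, 3))
    # keep the first 40 CDS bases intron-free so planted 5' variants sit in
    # one exon; introns land further into the CDS
    points = sorted(
        int(p)
        for p in rng.integers(utr5 + 40, utr5 + cds_len - 10, size=n_introns)
    )
    points = [p for i, p in enumerate(points) if i == 0 or p - points[i - 1] > 20]

    segments: list[tuple[str, int, int]] = []
    sense_parts: list[str] = []
    cursor_m = 0  # mRNA bases consumed
    cursor_s = 0  # sense bases emitted
    for p in points:
        exon_seq = mrna[cursor_m:p]
        segments.append(("exon", cursor_s + 1, cursor_s + len(exon_seq)))
        sense_parts.append(exon_seq)
        cursor_s += len(exon_seq)
        intron = "GT" + _random_seq(rng, int(rng.integers(46, 100))) + "AG"
        segments.append(("intron", cursor_s + 1, cursor_s + len(intron)))
        sense_parts.append(intron)
        cursor_s += len(intron)
        cursor_m = p
    exon_seq = mrna[cursor_m:]
    segments.append(("exon", cursor_s + 1, cursor_s + len(exon_seq)))
    sense_parts.append(exon_seq)

    return _Gene(
        gene_id=gene_id,
        symbol=symbol,
        contig=contig,
        strand=strand,
        start=start,
        sense_seq="".join(sense_parts),
        segments=segments,
        utr5=utr5,
        cds_len=cds_len,
        role=role,
    )


def _gene_to_model(g: _Gene, source_b: bool = False) -> TranscriptModel:
    shift = 3 if (source_b and g.role == "discordant") else 0
    cds_lo, cds_hi = g.cds_genomic_bounds(g.utr5 + 1 + shift)
    return TranscriptModel(
        transcript_id=f"{g.gene_id}.t1",
        gene_id=g.gene_id,
        gene_symbol=g.symbol,
        contig=g.contig,
        strand=g.strand,
        exons=tuple(g.exon_genomic_intervals()),
        cds_start=cds_lo,
        cds_end=cds_hi,
    )


def _gff_lines(g: _Gene, source_b: bool = False) -> list[str]:
    model = _gene_to_model(g, source_b)
    lo, hi = model.span
    tid = model.transcript_id
    lines = [
        f"{g.contig}\tvarsieve\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id};Name={g.symbol}",
        f"{g.contig}\tvarsieve\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}",
    ]
    for i, (s, e) in enumerate(model.exons, 1):
        lines.append(
            f"{g.contig}\tvarsieve\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={tid}.exon{i};Parent={tid}"
        )
    cds_parts = []
    for i, (s, e) in enumerate(model.exons, 1):
        cs, ce = max(s, model.cds_start), min(e, model.cds_end)
        if cs <= ce:
            cds_parts.append((i, cs, ce))
    if g.strand == "-":
        cds_parts = cds_parts[::-1]
    consumed = 0
    phased = []
    for i, cs, ce in cds_parts:
        phase = (3 - consumed % 3) % 3
        phased.append((i, cs, ce, phase))
        consumed += ce - cs + 1
    for i, cs, ce, phase in sorted(phased):
        lines.append(
            f"{g.contig}\tvarsieve\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t{phase}\tID={tid}.cds{i};Parent={tid}"
        )
    return lines


def plant_frameshift(
    transcript: TranscriptModel,
    genome: ReferenceGenome,
    ins_length: int = 8,
    c_anchor: int = 19,
    insert: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Variant, int]:
    """Plant an out-of-frame insertion after coding position ``c_anchor``.

    Returns the left-aligned genomic Variant and the expected first
    divergent residue (the codon containing the first inserted base:
    ``c_anchor // 3 + 1``, i.e. 7 for the default 19).  The default insert
    emulates the canine MPS I allele CGGCCCCC.
    """
    if ins_length % 3 == 0:
        raise ValueError(f"insertion length {ins_length} is in frame; no frameshift")
    if insert is None:
        if ins_length == len(CAUSAL_INSERT):
            insert = CAUSAL_INSERT
        else:
            if rng is None:
                raise ValueError("random insert requested but no rng supplied")
            insert = _random_seq(rng, ins_length)
    if len(insert) != ins_length:
        raise ValueError("insert length does not match ins_length")
    cds_len = len(transcript.cds_positions())
    if cds_len <= c_anchor + 3:
        raise ValueError(f"CDS length {cds_len} too short for anchor {c_anchor}")
    h = HgvsC("ins", c_anchor, c_anchor + 1, alt=insert)
    variant = hgvs_c_to_variant(h, transcript, genome)
    return variant, c_anchor // 3 + 1


def _stop_gain_site(g: _Gene, rng: np.random.Generator) -> tuple[int, str] | None:
    """A (CDS sense index, new sense base) turning one codon into a stop."""
    n_cod = g.cds_len // 3
    order = list(rng.permutation(np.arange(8, n_cod - 4)))
    cds = _gene_cds(g)
    for k in order:
        codon = cds[3 * k : 3 * k + 3]
        for j in range(3):
            for b in _BASES:
                if b == codon[j]:
                    continue
                mutant = codon[:j] + b + codon[j + 1 :]
                if mutant in _STOPS:
                    c_index = 3 * k + j + 1
                    if _site_free(g, c_index):
                        return c_index, b
    return None


def _synonymous_site(g: _Gene, rng: np.random.Generator) -> tuple[int, str] | None:
    n_cod = g.cds_len // 3
    order = list(rng.permutation(np.arange(5, n_cod - 2)))
    cds = _gene_cds(g)
    for k in order:
        codon = cds[3 * k : 3 * k + 3]
        aa = _FWD.get(codon)
        for b in _BASES:
            if b == codon[2]:
                continue
            mutant = codon[:2] + b
            if mutant not in _STOPS and _FWD.get(mutant) == aa:
                c_index = 3 * k + 3
                if _site_free(g, c_index):
                    return c_index, b
    return None


def _gene_cds(g: _Gene) -> str:
    chars = []
    for c in range(1, g.cds_len + 1):
        chars.append(g.sense_seq[g.mrna_to_sense(g.utr5 + c) - 1])
    return "".join(chars)


def _site_free(g: _Gene, c_index: int, margin: int = 14) -> bool:
    return all(abs(c_index - u) > margin for u in g.used_sense)


def _reserve(g: _Gene, c_index: int) -> None:
    g.used_sense.add(c_index)


def _exonic_cds_snv(g: _Gene, c_index: int, new_sense_base: str, genome: ReferenceGenome) -> Variant:
    gpos = g.cds_index_to_genomic(c_index)
    ref = genome.fetch(g.contig, gpos, gpos)
    alt = new_sense_base if g.strand == "+" else _COMPLEMENT[new_sense_base]
    return Variant(g.contig, gpos, ref, alt)


def _frameshift_del(g: _Gene, rng: np.random.Generator, genome: ReferenceGenome) -> Variant | None:
    n_cod = g.cds_len // 3
    order = list(rng.permutation(np.arange(8, n_cod - 4)))
    for k in order:
        c_index = 3 * k + 1
        if not _site_free(g, c_index):
            continue
        # require the base and both neighbours in the same exon
        g0 = g.cds_index_to_genomic(c_index - 1)
        g1 = g.cds_index_to_genomic(c_index)
        g2 = g.cds_index_to_genomic(c_index + 1)
        if abs(g1 - g0) != 1 or abs(g2 - g1) != 1:
            continue
        _reserve(g, c_index)
        lo = min(g0, g1, g2) - 1
        anchor = genome.fetch(g.contig, lo, lo)
        deleted = genome.fetch(g.contig, lo + 1, lo + 1)
        return left_align(Variant(g.contig, lo, anchor + deleted, anchor), genome)
    return None


def _intronic_snv(g: _Gene, rng: np.random.Generator, genome: ReferenceGenome) -> Variant | None:
    introns = [(s, e) for kind, s, e in g.segments if kind == "intron"]
    rng.shuffle(introns)
    for s, e in introns:
        if e - s < 12:
            continue
        i = int(rng.integers(s + 5, e - 4))
        gpos = g.sense_to_genomic(i)
        ref = genome.fetch(g.contig, gpos, gpos)
        alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        if alt == ref:
            alt = _BASES[(_BASES.index(ref) + 1) % 4]
        return Variant(g.contig, gpos, ref, alt)
    return None


def build_panel(
    cfg: ScenarioConfig,
    site_pool: list[tuple[Variant, float]],
) -> list[tuple[Variant, int, int]]:
    """Assign allele counts over 2×panel_samples chromosomes.

    Returns (variant, AC, AN) per site; MAF = AC/AN spans the configured
    strata, including sites at exactly the filtering threshold.
    """
    an = 2 * cfg.panel_samples
    out = []
    for variant, maf in site_pool:
        ac = int(round(maf * an))
        out.append((variant, ac, an))
    return out


def _write_fasta(path: Path, contigs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_panel_vcf(path: Path, sites: list[tuple[Variant, int, int]], contig_lengths: dict[str, int]) -> None:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("AC", "A", "Integer", "Alternate allele count in the control panel")
    header.info.add("AN", 1, "Integer", "Total alleles genotyped in the control panel")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v, ac, an in sorted(sites, key=lambda s: (s[0].contig, s[0].pos, s[0].alt)):
            rec = out.new_record(contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt))
            rec.info["AC"] = (ac,)
            rec.info["AN"] = an
            out.write(rec)


def generate_world(cfg: ScenarioConfig, out_dir: str | Path) -> tuple[WorldPaths, GroundTruth]:
    """Generate a complete, self-consistent world under ``out_dir``."""
    rng = np.random.default_rng(cfg.seed)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    mix = cfg.decoy_mix
    n = cfg.n_proband_variants
    n_common = int(round(mix.common_high * n))
    n_private = int(round(mix.private_low * n))
    n_singleton = int(round(mix.singleton_het_high * n))
    n_cis_pairs = int(round(mix.cis_het_pair * n)) // 2
    n_flagged_var = int(round(mix.flagged_gene * n))
    n_discordant = int(round(mix.source_discordant * n))

    n_discordant_genes = max(1, (n_discordant + 1) // 2) if n_discordant else 0
    n_flag_genes = cfg.n_flagged_genes
    needed = (
        1  # causal
        + (cfg.n_candidate_genes - 1)
        + n_flag_genes
        + n_discordant_genes
        + n_singleton
        + n_cis_pairs
    )
    if needed > cfg.n_genes:
        raise ValueError(
            f"infeasible config: {needed} dedicated genes required but only "
            f"{cfg.n_genes} genes configured"
        )

    # ---- contigs and genes -------------------------------------------------
    contig_names = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    contigs = {name: list(_random_seq(rng, cfg.contig_length)) for name in contig_names}

    roles = (
        ["causal"]
        + ["candidate"] * (cfg.n_candidate_genes - 1)
        + ["flagged"] * n_flag_genes
        + ["discordant"] * n_discordant_genes
        + ["singleton"] * n_singleton
        + ["cis"] * n_cis_pairs
    )
    roles += ["neutral"] * (cfg.n_genes - len(roles))
    order = rng.permutation(len(roles))
    roles = [roles[i] for i in order]

    genes: list[_Gene] = []
    cursors = {name: 1 for name in contig_names}
    for gi, role in enumerate(roles):
        contig = contig_names[gi % cfg.n_contigs]
        start = cursors[contig] + int(rng.integers(200, 500))
        gene = _build_gene(rng, f"gene{gi + 1:03d}", f"G{gi + 1:03d}", contig, start, role)
        end = start + gene.length - 1
        if end > cfg.contig_length - 200:
            raise ValueError(
                f"infeasible config: gene {gene.gene_id} does not fit on {contig} "
                f"(needs {end}, contig length {cfg.contig_length})"
            )
        frag = gene.sense_seq if gene.strand == "+" else reverse_complement(gene.sense_seq)
        contigs[contig][start - 1 : end] = list(frag)
        cursors[contig] = end + 1
        genes.append(gene)

    genome = ReferenceGenome({k: "".join(v) for k, v in contigs.items()})
    models_a = [_gene_to_model(g) for g in genes]
    by_role: dict[str, list[_Gene]] = {}
    for g in genes:
        by_role.setdefault(g.role, []).append(g)

    # sanity: every source-A model satisfies the ORF invariants
    from .genome import spliced_cds

    for g, model in zip(genes, models_a):
        cds = spliced_cds(model, genome)
        assert len(cds) % 3 == 0 and cds.startswith("ATG") and cds[-3:] in _STOPS, (
            g.gene_id,
            cds[:12],
        )
        body = translate(cds)
        assert body.found_stop and len(body.protein) == len(cds) // 3 - 1, g.gene_id

    # ---- variants ----------------------------------------------------------
    model_by_gene = {g.gene_id: m for g, m in zip(genes, models_a)}
    calls: list[VariantCall] = []
    classes: dict[str, list[str]] = {
        "causal": [],
        "common_high": [],
        "private_low": [],
        "singleton_het_high": [],
        "cis_het_pair": [],
        "flagged_gene": [],
        "source_discordant": [],
    }
    panel_pool: list[tuple[Variant, float]] = []
    common_mafs = [0.02, 0.05, 0.25]

    def add_call(v: Variant, gt: tuple[int, int], phased=False, ps=None, cls=""):
        v = left_align(v, genome)
        calls.append(
            VariantCall(
                v,
                {"proband": GenotypeCall("proband", gt, phased=phased, phase_set=ps)},
            )
        )
        classes[cls].append(v.key)
        return v

    # causal
    causal_gene = by_role["causal"][0]
    causal_model = model_by_gene[causal_gene.gene_id]
    if cfg.causal_mode == "hom_frameshift":
        v, _ = plant_frameshift(
            causal_model,
            genome,
            ins_length=len(cfg.causal_insert),
            c_anchor=cfg.causal_c_anchor,
            insert=cfg.causal_insert,
        )
        _reserve(causal_gene, cfg.causal_c_anchor)
        add_call(v, (1, 1), cls="causal")
    elif cfg.causal_mode == "compound_het_trans":
        v1, _ = plant_frameshift(
            causal_model,
            genome,
            ins_length=len(cfg.causal_insert),
            c_anchor=cfg.causal_c_anchor,
            insert=cfg.causal_insert,
        )
        _reserve(causal_gene, cfg.causal_c_anchor)
        site = _stop_gain_site(causal_gene, rng)
        assert site is not None, "no stop-gain site available in causal gene"
        c_index, base = site
        _reserve(causal_gene, c_index)
        v2 = _exonic_cds_snv(causal_gene, c_index, base, genome)
        ps = causal_gene.start
        add_call(v1, (0, 1), phased=True, ps=ps, cls="causal")
        add_call(v2, (1, 0), phased=True, ps=ps, cls="causal")

    # common high-impact decoys, hom/het alternating, placed in candidate and
    # neutral genes (their removal never depends on the gene)
    host_pool = by_role.get("candidate", []) + by_role.get("neutral", [])
    for i in range(n_common):
        host = host_pool[i % len(host_pool)]
        site = _stop_gain_site(host, rng)
        if site is None:
            continue
        c_index, base = site
        _reserve(host, c_index)
        v = _exonic_cds_snv(host, c_index, base, genome)
        v = add_call(v, (1, 1) if i % 2 == 0 else (0, 1), cls="common_high")
        panel_pool.append((v, common_mafs[i % len(common_mafs)]))

    # private low-impact decoys: synonymous or intronic, never in the panel
    # above threshold (a few sit in the panel at or below 1%)
    boundary_mafs = [0.005, 0.01]
    for i in range(n_private):
        host = host_pool[(i * 3 + 1) % len(host_pool)]
        v = None
        if i % 2 == 0:
            site = _synonymous_site(host, rng)
            if site is not None:
                c_index, base = site
                _reserve(host, c_index)
                v = _exonic_cds_snv(host, c_index, base, genome)
        if v is None:
            v = _intronic_snv(host, rng, genome)
        if v is None:
            continue
        v = add_call(v, (1, 1) if i % 3 == 0 else (0, 1), cls="private_low")
        if i < 4:  # boundary panel sites: kept by the strict > rule
            panel_pool.append((v, boundary_mafs[i % 2]))

    # singleton heterozygous high-impact decoys: one per dedicated gene
    for i, host in enumerate(by_role.get("singleton", [])[:n_singleton]):
        site = _stop_gain_site(host, rng)
        if site is None:
            v = _frameshift_del(host, rng, genome)
            if v is None:
                continue
        else:
            c_index, base = site
            _reserve(host, c_index)
            v = _exonic_cds_snv(host, c_index, base, genome)
        add_call(v, (0, 1), cls="singleton_het_high")

    # cis het pairs: two highs on the same haplotype of one gene
    for host in by_role.get("cis", [])[:n_cis_pairs]:
        ps = host.start
        planted = 0
        for _ in range(2):
            site = _stop_gain_site(host, rng)
            if site is None:
                break
            c_index, base = site
            _reserve(host, c_index)
            v = _exonic_cds_snv(host, c_index, base, genome)
            add_call(v, (0, 1), phased=True, ps=ps, cls="cis_het_pair")
            planted += 1
        assert planted in (0, 2), "cis pair must be complete"

    # flagged-gene decoys: homozygous highs confined to flagged genes
    flag_hosts = by_role.get("flagged", [])
    for i in range(n_flagged_var):
        host = flag_hosts[i % len(flag_hosts)]
        site = _stop_gain_site(host, rng)
        if site is None:
            continue
        c_index, base = site
        _reserve(host, c_index)
        v = _exonic_cds_snv(host, c_index, base, genome)
        add_call(v, (1, 1), cls="flagged_gene")

    # source-discordant decoys: start-lost under A, 5' UTR under B
    disc_hosts = by_role.get("discordant", [])
    start_positions = [1, 3]  # skip c.2: keeps source B's ATG at c.1..3 intact
    for i in range(n_discordant):
        host = disc_hosts[i % len(disc_hosts)]
        c_index = start_positions[(i // len(disc_hosts)) % len(start_positions)]
        if c_index in host.used_sense:
            continue
        wt = _gene_cds(host)[c_index - 1]
        alt = {"A": "C", "T": "A", "G": "T", "C": "A"}[wt]
        _reserve(host, c_index)
        v = _exonic_cds_snv(host, c_index, alt, genome)
        add_call(v, (1, 1), cls="source_discordant")

    # panel-only sites across the MAF spectrum, in intergenic space
    strata = [0.005, 0.01, 0.02, 0.05, 0.25]
    for i in range(30):
        contig = contig_names[i % cfg.n_contigs]
        pos = cfg.contig_length - 150 - 3 * i
        ref = genome.fetch(contig, pos, pos)
        alt = _BASES[(_BASES.index(ref) + 1) % 4]
        panel_pool.append((Variant(contig, pos, ref, alt), strata[i % len(strata)]))

    panel_sites = build_panel(cfg, panel_pool)

    # ---- ground truth ------------------------------------------------------
    final_expected = list(classes["causal"]) if cfg.causal_mode != "none" else []
    truth = GroundTruth(
        causal_keys=list(classes["causal"]),
        causal_gene=causal_gene.gene_id if cfg.causal_mode != "none" else None,
        causal_gene_symbol=causal_gene.symbol if cfg.causal_mode != "none" else None,
        expected_final=final_expected,
        classes=classes,
    )

    # ---- write files -------------------------------------------------------
    paths = WorldPaths(
        root=root,
        fasta=root / "reference.fa",
        gff_a=root / "annotation_a.gff3",
        gff_b=root / "annotation_b.gff3",
        panel_vcf=root / "panel.vcf",
        proband_vcf=root / "proband.vcf",
        flags=root / "flagged_genes.txt",
        candidates=root / "candidate_genes.txt",
        ground_truth=root / "ground_truth.json",
        scenario=root / "scenario.json",
    )
    _write_fasta(paths.fasta, genome.contigs)
    contig_lengths = {k: len(v) for k, v in genome.contigs.items()}
    for path, source_b in ((paths.gff_a, False), (paths.gff_b, True)):
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, length in contig_lengths.items():
                fh.write(f"##sequence-region {name} 1 {length}\n")
            for g in genes:
                fh.write("\n".join(_gff_lines(g, source_b)) + "\n")
    _write_panel_vcf(paths.panel_vcf, panel_sites, contig_lengths)
    write_vcf(str(paths.proband_vcf), Callset(samples=["proband"], calls=calls), contig_lengths)
    with open(paths.flags, "w") as fh:
        for g in sorted(flag_hosts, key=lambda g: g.gene_id):
            fh.write(g.gene_id + "\n")
    with open(paths.candidates, "w") as fh:
        for g in sorted(
            by_role.get("causal", []) + by_role.get("candidate", []),
            key=lambda g: g.gene_id,
        ):
            fh.write(g.symbol + "\n")
    with open(paths.ground_truth, "w") as fh:
        fh.write(truth.to_json() + "\n")
    with open(paths.scenario, "w") as fh:
        cfg_dict = dataclasses.asdict(cfg)
        fh.write(json.dumps(cfg_dict, indent=2, sort_keys=True) + "\n")
    return paths, truth
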