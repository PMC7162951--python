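"""Reference sequences, transcript models, and coding-coordinate projection.

The coordinate conventions follow the input formats everywhere: genomic
positions are 1-based and intervals are inclusive (GFF3/VCF style).  Coding
(c.) positions number the spliced CDS from 1 at the A of the start codon,
in transcription order, and cover the CDS only — UTR and intronic positions
are reported as non-coding designations, not as negative/star offsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "ReferenceGenome",
    "TranscriptModel",
    "CodingCoordinate",
    "NoncodingPosition",
    "Translation",
    "GenomeError",
    "FastaError",
    "Gff3Error",
    "read_fasta",
    "read_gff3",
    "spliced_cds",
    "translate",
    "genomic_to_c",
    "c_to_genomic",
    "reverse_complement",
]

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset(CodonTable.standard_dna_table.stop_codons)
_CODON_TABLE = CodonTable.standard_dna_table.forward_table

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Base class for reference/annotation errors."""


class FastaError(GenomeError):
    pass


class Gff3Error(GenomeError):
    pass


@dataclass
class ReferenceGenome:
    """In-memory reference: contig name -> uppercase DNA over {A,C,G,T,N}."""

    contigs: dict[str, str]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """1-based inclusive slice [start, end]."""
        if contig not in self.contigs:
            raise GenomeError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 1 or end > len(seq) or start > end + 1:
            raise GenomeError(
                f"coordinates {contig}:{start}-{end} outside contig (length {len(seq)})"
            )
        return seq[start - 1 : end]


@dataclass
class TranscriptModel:
    """One mRNA: exon structure plus a single CDS interval on a strand.

    ``exons`` are (start, end) genomic intervals, 1-based inclusive, sorted
    by genomic start regardless of strand.  ``cds_start``/``cds_end`` bound
    the CDS in genomic coordinates (stop codon included).  Models that fail
    CDS invariants carry ``valid=False`` with the reasons in
    ``validation_errors`` instead of being dropped.
    """

    transcript_id: str
    gene_id: str
    gene_symbol: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    valid: bool = True
    validation_errors: tuple[str, ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of each intron, in genomic order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((e1 + 1, s2 - 1))
        return out

    def cds_positions(self) -> list[int]:
        """Genomic positions of the spliced CDS in transcription order."""
        pos = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                pos.extend(range(lo, hi + 1))
        if self.strand == "-":
            pos.reverse()
        return pos

    def exonic_positions(self) -> list[int]:
        pos = []
        for s, e in self.exons:
            pos.extend(range(s, e + 1))
        if self.strand == "-":
            pos.reverse()
        return pos


class CodingCoordinate(NamedTuple):
    transcript_id: str
    c_pos: int  # 1 = the A of the start codon


@dataclass(frozen=True)
class NoncodingPosition:
    """Designation for positions outside the CDS of a transcript."""

    region: str  # 'intronic' | 'utr' | 'intergenic'
    nearest_c: int | None = None  # nearest coding position, if any
    offset: int | None = None  # signed distance, transcription direction


class Translation(NamedTuple):
    protein: str
    found_stop: bool


def read_fasta(path: str) -> ReferenceGenome:
    """Load a multi-record FASTA into memory, uppercased and validated.

    IUPAC ambiguity codes other than N are rejected; duplicate record
    names are an error.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        name = record.id
        if name in contigs:
            raise FastaError(
                f"duplicate FASTA record {name!r} (line {_find_header_line(path, name, 2)})"
            )
        seq = str(record.seq).upper()
        if not seq:
            raise FastaError(f"empty sequence for record {name!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaError(
                f"record {name!r} contains invalid characters {sorted(bad)} "
                f"(line {_find_bad_line(path, name, bad)}); only A/C/G/T/N accepted"
            )
        contigs[name] = seq
    if not contigs:
        raise FastaError(f"no FASTA records found in {path}")
    return ReferenceGenome(contigs)


def _find_header_line(path: str, name: str, occurrence: int) -> int:
    seen = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[0] == name:
                seen += 1
                if seen == occurrence:
                    return lineno
    return -1


def _find_bad_line(path: str, name: str, bad: set[str]) -> int:
    current = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                current = line[1:].split()[0] if line[1:].split() else ""
            elif current == name and set(line.strip().upper()) & bad:
                return lineno
    return -1


def read_gff3(path: str, genome: ReferenceGenome) -> list[TranscriptModel]:
    """Assemble TranscriptModels from a GFF3 of gene/mRNA/exon/CDS features.

    Models that violate CDS invariants (length not a multiple of 3, no ATG,
    no terminal stop, internal stop) are returned with ``valid=False``
    rather than dropped.  Orphan CDS features and features beyond contig
    ends raise :class:`Gff3Error`.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    for feat in db.all_features():
        if feat.featuretype == "CDS" and "Parent" not in feat.attributes:
            raise Gff3Error(f"orphan CDS at {feat.seqid}:{feat.start}-{feat.end} (no Parent)")
        if feat.seqid in genome and feat.end > genome.length(feat.seqid):
            raise Gff3Error(
                f"feature {feat.id or feat.featuretype} ends at {feat.end}, beyond "
                f"contig {feat.seqid} (length {genome.length(feat.seqid)})"
            )

    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_parts = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not exons or not cds_parts:
            continue
        gene_id, gene_symbol = mrna.id, mrna.id
        parents = list(db.parents(mrna, featuretype="gene"))
        if parents:
            gene_id = parents[0].id
            gene_symbol = parents[0].attributes.get("Name", [gene_id])[0]
        model = TranscriptModel(
            transcript_id=mrna.id,
            gene_id=gene_id,
            gene_symbol=gene_symbol,
            contig=mrna.seqid,
            strand=mrna.strand,
            exons=tuple(exons),
            cds_start=cds_parts[0][0],
            cds_end=cds_parts[-1][1],
        )
        models.append(_finalize_model(model, genome))
    return models


def _finalize_model(t: TranscriptModel, genome: ReferenceGenome) -> TranscriptModel:
    """Validate CDS invariants; normalize the CDS to include the stop codon."""
    errors: list[str] = []
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        if s2 <= e1:
            errors.append(f"overlapping exons {s1}-{e1} and {s2}-{e2}")
    covered = set()
    for s, e in t.exons:
        covered.update(range(s, e + 1))
    if t.cds_start not in covered or t.cds_end not in covered:
        errors.append("CDS bounds not contained in exon union")
    if errors:
        return _flagged(t, errors)

    cds = spliced_cds(t, genome)
    if cds[-3:] not in STOP_CODONS:
        extended = _try_stop_extension(t, genome)
        if extended is not None:
            t = extended
            cds = spliced_cds(t, genome)
    if len(cds) % 3 != 0:
        errors.append(f"CDS length {len(cds)} not a multiple of 3")
    else:
        if not cds.startswith("ATG"):
            errors.append("CDS does not begin with ATG")
        if cds[-3:] not in STOP_CODONS:
            errors.append("CDS does not end with a stop codon")
        body = translate(cds).protein
        if len(body) < len(cds) // 3 - 1:
            errors.append("internal stop codon in CDS")
    if errors:
        return _flagged(t, errors)
    return t


def _flagged(t: TranscriptModel, errors: list[str]) -> TranscriptModel:
    warnings.warn(
        f"transcript {t.transcript_id}: {'; '.join(errors)}", stacklevel=3
    )
    t.valid = False
    t.validation_errors = tuple(errors)
    return t


def _try_stop_extension(t: TranscriptModel, genome: ReferenceGenome) -> TranscriptModel | None:
    """GFF3 dialects differ on whether CDS includes the stop codon; if the
    3 exonic bases just past the CDS end form a stop, adopt them."""
    exonic = t.exonic_positions()
    cds_pos = t.cds_positions()
    if not cds_pos:
        return None
    try:
        idx = exonic.index(cds_pos[-1])
    except ValueError:
        return None
    ext = exonic[idx + 1 : idx + 4]
    if len(ext) != 3:
        return None
    codon = "".join(genome.fetch(t.contig, p, p) for p in ext)
    if t.strand == "-":
        codon = "".join(reverse_complement(genome.fetch(t.contig, p, p)) for p in ext)
    if codon not in STOP_CODONS:
        return None
    new_bound = ext[-1]
    if t.strand == "+":
        t.cds_end = max(t.cds_end, new_bound)
    else:
        t.cds_start = min(t.cds_start, new_bound)
    return t


def spliced_cds(t: TranscriptModel, genome: ReferenceGenome) -> str:
    """CDS-overlapping exon segments joined in transcription order
    (reverse-complemented for strand '-')."""
    parts = []
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if lo <= hi:
            parts.append(genome.fetch(t.contig, lo, hi))
    seq = "".join(parts)
    return reverse_complement(seq) if t.strand == "-" else seq


def translate(cds: str) -> Translation:
    """Translate with the standard genetic code from position 1, stopping at
    (and excluding) the first stop codon.

    A trailing partial codon is ignored.  Any codon containing N yields 'X'.
    Returns the protein and whether a stop codon was encountered.
    """
    if not cds:
        raise ValueError("cannot translate an empty sequence")
    if len(cds) < 3:
        raise ValueError(f"sequence of length {len(cds)} has no complete codon")
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            protein.append("X")
            continue
        if codon in STOP_CODONS:
            return Translation("".join(protein), True)
        protein.append(_CODON_TABLE[codon])
    return Translation("".join(protein), False)


def genomic_to_c(t: TranscriptModel, gpos: int) -> CodingCoordinate | NoncodingPosition:
    """Project a genomic position into the c. frame of ``t``.

    Positions outside the CDS come back as :class:`NoncodingPosition` with
    the region (intronic/utr/intergenic) and, where meaningful, the nearest
    coding position and a signed offset in transcription direction.
    """
    cds_pos = t.cds_positions()
    index = {g: i + 1 for i, g in enumerate(cds_pos)}
    if gpos in index:
        return CodingCoordinate(t.transcript_id, index[gpos])
    lo, hi = t.span
    if not lo <= gpos <= hi:
        return NoncodingPosition("intergenic")
    in_exon = any(s <= gpos <= e for s, e in t.exons)
    region = "utr" if in_exon else "intronic"
    nearest = min(cds_pos, key=lambda g: abs(g - gpos))
    dist = gpos - nearest
    if t.strand == "-":
        dist = -dist
    return NoncodingPosition(region, nearest_c=index[nearest], offset=dist)


def c_to_genomic(t: TranscriptModel, c: CodingCoordinate | int) -> int:
    """Inverse of :func:`genomic_to_c` on coding positions."""
    c_pos = c.c_pos if isinstance(c, CodingCoordinate) else int(c)
    cds_pos = t.cds_positions()
    if not 1 <= c_pos <= len(cds_pos):
        raise GenomeError(
            f"c.{c_pos} outside CDS of {t.transcript_id} (length {len(cds_pos)})"
        )
    return cds_pos[c_pos - 1]
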