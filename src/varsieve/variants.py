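"""Variants, genotypes, VCF I/O, indel normalization and HGVS rendering.

Two normalization conventions deliberately coexist:

* **Left alignment** (VCF convention) — the leftmost genomic representation
  with a single anchor base — is used for storage and for matching against
  the control panel, so equivalent representations of the same indel cannot
  slip past a frequency filter.
* **The HGVS 3' rule** — the most 3' equivalent placement *on the transcript
  strand* — is used when rendering c. descriptions.  In repetitive sequence
  the same physical insertion has a whole run of equivalent placements, and
  the two conventions pick opposite ends of it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pysam

from .genome import (
    GenomeError,
    ReferenceGenome,
    TranscriptModel,
    c_to_genomic,
    genomic_to_c,
    CodingCoordinate,
    reverse_complement,
)

__all__ = [
    "Variant",
    "GenotypeCall",
    "VariantCall",
    "Callset",
    "PlacementRange",
    "VcfError",
    "ReferenceMismatchError",
    "HgvsError",
    "read_vcf",
    "write_vcf",
    "left_align",
    "enumerate_equivalent_placements",
    "insertion_placements",
    "to_hgvs_c",
    "to_hgvs_g",
    "parse_hgvs_c",
    "hgvs_c_to_variant",
]


class VcfError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    """REF allele does not match the reference genome: wrong build."""


class HgvsError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Variant:
    """A REF/ALT substitution at a 1-based genomic position (VCF convention:
    for indels, ``pos`` is the shared anchor base)."""

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def end(self) -> int:
        """Genomic position of the last REF base."""
        return self.pos + len(self.ref) - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def is_insertion(self) -> bool:
        return len(self.ref) == 1 < len(self.alt) and self.alt[0] == self.ref

    @property
    def is_deletion(self) -> bool:
        return len(self.alt) == 1 < len(self.ref) and self.ref[0] == self.alt

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class GenotypeCall:
    sample: str
    alleles: tuple[int | None, int | None]
    phased: bool = False
    phase_set: int | None = None

    @property
    def zygosity(self) -> str:
        a, b = self.alleles
        if a is None or b is None:
            return "missing"
        if a == b:
            return "hom_alt" if a == 1 else "hom_ref"
        return "het"

    @property
    def alt_haplotype(self) -> int | None:
        """For a phased het: 0 if the alt allele is on the first haplotype,
        1 if on the second; None otherwise."""
        if not self.phased or self.zygosity != "het":
            return None
        return 0 if self.alleles[0] == 1 else 1


@dataclass
class VariantCall:
    variant: Variant
    genotypes: dict[str, GenotypeCall]
    info: dict = field(default_factory=dict)

    def genotype(self, sample: str | None = None) -> GenotypeCall:
        if sample is None:
            sample = next(iter(self.genotypes))
        return self.genotypes[sample]


@dataclass
class Callset:
    samples: list[str]
    calls: list[VariantCall]
    skipped_records: int = 0  # symbolic / SV / breakend records
    half_calls: int = 0

    def __iter__(self):
        return iter(self.calls)

    def __len__(self):
        return len(self.calls)


@dataclass(frozen=True)
class PlacementRange:
    """All coordinates after which an inserted sequence can be equivalently
    placed; applying the insertion at any of them yields the identical
    alternate sequence.  ``frame`` records the coordinate system ('g' or 'c')."""

    insert: str
    frame: str
    first: int
    last: int

    @property
    def positions(self) -> range:
        return range(self.first, self.last + 1)


_SYMBOLIC = re.compile(r"[<>\[\]]")


def read_vcf(path: str) -> Callset:
    """Read a VCF 4.2 into a callset of bi-allelic variants.

    Multi-allelic records are split; genotype indices are remapped so each
    split record is 0/1-coded (other alt alleles count as reference).
    Symbolic/SV alleles are skipped and counted; half-calls are preserved
    as missing and counted.
    """
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfError(f"cannot read VCF {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise VcfError(f"{path}: GT FORMAT field missing from header")
        samples = list(vf.header.samples)
        calls: list[VariantCall] = []
        skipped = half = 0
        for rec in vf:
            alts = rec.alts or ()
            if not alts or any(a is None or _SYMBOLIC.search(a) or a == "*" for a in alts):
                skipped += 1
                continue
            info = dict(rec.info)
            for ai, alt in enumerate(alts, start=1):
                try:
                    variant = Variant(rec.contig, rec.pos, rec.ref.upper(), alt.upper())
                except ValueError as exc:
                    raise VcfError(
                        f"{path}: malformed record at {rec.contig}:{rec.pos}: {exc}"
                    ) from exc
                genotypes = {}
                for sample in samples:
                    sdata = rec.samples[sample]
                    gt = sdata.get("GT")
                    if gt is None or len(gt) != 2:
                        raise VcfError(
                            f"{path}: missing or non-diploid GT at {rec.contig}:{rec.pos}"
                        )
                    mapped = tuple(
                        None if a is None else (1 if a == ai else 0) for a in gt
                    )
                    if None in mapped:
                        half += 1
                    ps = sdata.get("PS") if "PS" in vf.header.formats else None
                    genotypes[sample] = GenotypeCall(
                        sample=sample,
                        alleles=mapped,
                        phased=bool(sdata.phased),
                        phase_set=ps,
                    )
                calls.append(VariantCall(variant, genotypes, info))
    return Callset(samples=samples, calls=calls, skipped_records=skipped, half_calls=half)


def write_vcf(
    path: str,
    callset: Callset,
    contig_lengths: dict[str, int],
    info_fields: dict[str, tuple[str, str]] | None = None,
) -> None:
    """Write a callset to a plain-text VCF 4.2 with GT and PS."""
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set")
    for key, (number, vtype) in (info_fields or {}).items():
        header.info.add(key, number, vtype, key)
    for sample in callset.samples:
        header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(callset.calls, key=lambda c: (c.variant.contig, c.variant.pos, c.variant.alt)):
            v = call.variant
            rec = out.new_record(
                contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            for key, value in call.info.items():
                if key in header.info:
                    rec.info[key] = value
            for sample in callset.samples:
                g = call.genotypes[sample]
                rec.samples[sample]["GT"] = g.alleles
                rec.samples[sample].phased = g.phased
                if g.phase_set is not None:
                    rec.samples[sample]["PS"] = g.phase_set
            out.write(rec)


def _check_ref(v: Variant, genome: ReferenceGenome) -> None:
    actual = genome.fetch(v.contig, v.pos, v.end)
    if actual != v.ref:
        raise ReferenceMismatchError(
            f"{v.key}: REF {v.ref!r} does not match reference {actual!r} "
            "(wrong reference build?)"
        )


def left_align(v: Variant, genome: ReferenceGenome) -> Variant:
    """Normalize to the leftmost minimal representation (VCF convention).

    Shared suffix is trimmed (extending leftward through the reference when
    needed), then the shared prefix beyond a single indel anchor base.
    Idempotent; preserves the alternate haplotype.
    """
    _check_ref(v, genome)
    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) == 1 or len(alt) == 1:
                if pos == 1:
                    break
                prev = genome.fetch(v.contig, pos - 1, pos - 1)
                ref = prev + ref[:-1]
                alt = prev + alt[:-1]
                pos -= 1
            else:
                ref = ref[:-1]
                alt = alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return Variant(v.contig, pos, ref, alt)


def insertion_placements(context: str, after: int, insert: str, frame: str = "g") -> PlacementRange:
    """Every position of ``context`` (1-based) after which ``insert`` can be
    equivalently placed, given it is inserted after position ``after``.

    Equivalent means the resulting alternate sequence is byte-identical.
    The run is contiguous: sliding an insertion by one position is possible
    exactly when the flanking base matches the appropriate end of the
    (rotated) inserted sequence.
    """
    if not 0 <= after <= len(context):
        raise ValueError(f"insertion point {after} outside context of length {len(context)}")
    if not insert:
        raise ValueError("insert must be non-empty")
    # shift left: inserting I after p equals inserting rot_right(I) after p-1
    # iff context[p] (1-based) == I[-1]
    p, ins = after, insert
    while p > 0 and context[p - 1] == ins[-1]:
        ins = ins[-1] + ins[:-1]
        p -= 1
    first = p
    # shift right: inserting I after p equals inserting rot_left(I) after p+1
    # iff context[p+1] (1-based) == I[0]
    p, ins = after, insert
    while p < len(context) and context[p] == ins[0]:
        ins = ins[1:] + ins[0]
        p += 1
    return PlacementRange(insert=insert, frame=frame, first=first, last=p)


def enumerate_equivalent_placements(
    v: Variant, genome: ReferenceGenome, flank: int = 1000
) -> PlacementRange:
    """Genomic-frame equivalent placements of a pure insertion.

    ``positions`` are genomic coordinates after which the inserted sequence
    can be placed: the "after any base pair from a to b" run.
    """
    if not v.is_insertion:
        raise ValueError(f"{v.key} is not a pure insertion")
    _check_ref(v, genome)
    lo = max(1, v.pos - flank)
    hi = min(genome.length(v.contig), v.pos + flank)
    context = genome.fetch(v.contig, lo, hi)
    local = insertion_placements(context, v.pos - lo + 1, v.alt[1:], frame="g")
    return PlacementRange(
        insert=v.alt[1:], frame="g", first=local.first + lo - 1, last=local.last + lo - 1
    )


def _require_coding(t: TranscriptModel, gpos: int) -> int:
    c = genomic_to_c(t, gpos)
    if not isinstance(c, CodingCoordinate):
        raise GenomeError(
            f"position {t.contig}:{gpos} is {c.region} for {t.transcript_id}; "
            "no c. coordinate"
        )
    return c.c_pos


def _transcript_edit(
    v: Variant, t: TranscriptModel, genome: ReferenceGenome
) -> tuple[str, int, str, str]:
    """Express a genomic variant as an edit of the spliced CDS.

    Returns (kind, c position, ref-in-transcript-frame, alt-in-transcript-frame)
    where for 'ins' the c position is the base *after which* the sequence goes,
    and for 'del'/'delins' it is the first deleted base.
    """
    from .genome import spliced_cds  # local to avoid cycle at import time

    minus = t.strand == "-"
    if v.is_snv:
        c = _require_coding(t, v.pos)
        ref_t, alt_t = (reverse_complement(v.ref), reverse_complement(v.alt)) if minus else (v.ref, v.alt)
        return "snv", c, ref_t, alt_t
    if v.is_insertion:
        ins = v.alt[1:]
        left, right = v.pos, v.pos + 1
        if minus:
            c_after = _require_coding(t, right)
            return "ins", c_after, "", reverse_complement(ins)
        c_after = _require_coding(t, left)
        return "ins", c_after, "", ins
    # deletion or delins: REF span beyond the anchor base is replaced
    del_start, del_end = v.pos + 1, v.end
    deleted = v.ref[1:]
    inserted = v.alt[1:]
    if len(v.ref) == 1:  # anchorless substitution (MNV-style)
        del_start, deleted, inserted = v.pos, v.ref, v.alt
    c1 = _require_coding(t, del_start)
    c2 = _require_coding(t, del_end)
    if minus:
        c1, c2 = c2, c1
        deleted = reverse_complement(deleted)
        inserted = reverse_complement(inserted)
    kind = "del" if not inserted else "delins"
    return kind, c1, deleted, inserted


def to_hgvs_c(v: Variant, t: TranscriptModel, genome: ReferenceGenome) -> str:
    """Render a variant in c. notation on transcript ``t``.

    Insertions and deletions are shifted to their most 3' equivalent
    placement on the transcript strand (HGVS rule); inserted sequence is
    reported in transcript orientation.
    """
    from .genome import spliced_cds

    cds = spliced_cds(t, genome)
    kind, c, ref_t, alt_t = _transcript_edit(v, t, genome)
    if kind == "snv":
        return f"c.{c}{ref_t}>{alt_t}"
    if kind == "ins":
        run = insertion_placements(cds, c, alt_t, frame="c")
        p = run.last
        shift = p - run.first
        orig_shift = c - run.first
        seq = alt_t
        # re-rotate the inserted sequence to its 3'-most phase
        for _ in range((shift - orig_shift) % len(alt_t) if len(alt_t) else 0):
            seq = seq[1:] + seq[0]
        return f"c.{p}_{p + 1}ins{seq}"
    if kind == "del":
        start, end = c, c + len(ref_t) - 1
        # 3' shift: deleting [i..j] equals deleting [i+1..j+1] iff cds[i-1]==cds[j]
        while end < len(cds) and cds[start - 1] == cds[end]:
            start += 1
            end += 1
        if start == end:
            return f"c.{start}del"
        return f"c.{start}_{end}del"
    start, end = c, c + len(ref_t) - 1
    return f"c.{start}_{end}delins{alt_t}"


def to_hgvs_g(v: Variant) -> str:
    """Genomic (g.) description of a normalized variant, rendered as-is."""
    if v.is_snv:
        return f"{v.contig}:g.{v.pos}{v.ref}>{v.alt}"
    if v.is_insertion:
        return f"{v.contig}:g.{v.pos}_{v.pos + 1}ins{v.alt[1:]}"
    if v.is_deletion:
        start, end = v.pos + 1, v.end
        if start == end:
            return f"{v.contig}:g.{start}del"
        return f"{v.contig}:g.{start}_{end}del"
    start, end = v.pos + 1, v.end
    return f"{v.contig}:g.{start}_{end}delins{v.alt[1:]}"


@dataclass(frozen=True)
class HgvsC:
    """A parsed c. description (CDS coordinates only)."""

    kind: str  # 'snv' | 'ins' | 'del' | 'delins'
    start: int
    end: int
    ref: str = ""
    alt: str = ""


_HGVS_PATTERNS = [
    ("snv", re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")),
    ("ins", re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")),
    ("delins", re.compile(r"^c\.(\d+)(?:_(\d+))?delins([ACGT]+)$")),
    ("del", re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")),
]


def parse_hgvs_c(text: str) -> HgvsC:
    """Parse c. SNV/ins/del/delins descriptions, e.g. ``c.19_20insCGGCCCCC``."""
    text = text.strip()
    for kind, pattern in _HGVS_PATTERNS:
        m = pattern.match(text)
        if not m:
            continue
        if kind == "snv":
            pos = int(m.group(1))
            return HgvsC("snv", pos, pos, ref=m.group(2), alt=m.group(3))
        if kind == "ins":
            start, end = int(m.group(1)), int(m.group(2))
            if end != start + 1:
                raise HgvsError(
                    f"insertion interval {start}_{end} must be adjacent positions"
                )
            return HgvsC("ins", start, end, alt=m.group(3))
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if end < start:
            raise HgvsError(f"interval end {end} precedes start {start}")
        if kind == "delins":
            return HgvsC("delins", start, end, alt=m.group(3))
        return HgvsC("del", start, end, ref=m.group(3))
    token = text.split(".", 1)[-1]
    raise HgvsError(f"cannot parse HGVS c. description {text!r} (offending token: {token!r})")


def hgvs_c_to_variant(h: HgvsC, t: TranscriptModel, genome: ReferenceGenome) -> Variant:
    """Project a c. description onto the genome as a left-aligned Variant."""
    minus = t.strand == "-"
    if h.kind == "snv":
        g = c_to_genomic(t, h.start)
        ref = reverse_complement(h.ref) if minus else h.ref
        alt = reverse_complement(h.alt) if minus else h.alt
        actual = genome.fetch(t.contig, g, g)
        if actual != ref:
            raise HgvsError(
                f"c.{h.start}{h.ref}> : reference has {actual!r} at {t.contig}:{g}"
            )
        return left_align(Variant(t.contig, g, ref, alt), genome)
    if h.kind == "ins":
        ins_t = h.alt
        if minus:
            g_anchor = c_to_genomic(t, h.end)  # transcript 'after start' = genomic after (g(end))
            ins_g = reverse_complement(ins_t)
        else:
            g_anchor = c_to_genomic(t, h.start)
            ins_g = ins_t
        anchor_base = genome.fetch(t.contig, g_anchor, g_anchor)
        return left_align(Variant(t.contig, g_anchor, anchor_base, anchor_base + ins_g), genome)
    # del / delins over c interval [start, end]
    g1 = c_to_genomic(t, h.start)
    g2 = c_to_genomic(t, h.end)
    lo, hi = min(g1, g2), max(g1, g2)
    if hi - lo != h.end - h.start:
        raise HgvsError(
            f"c.{h.start}_{h.end} spans a splice junction; genomic projection is not contiguous"
        )
    deleted = genome.fetch(t.contig, lo, hi)
    inserted = ""
    if h.kind == "delins":
        inserted = reverse_complement(h.alt) if minus else h.alt
    if lo == 1:
        raise HgvsError("deletion at contig start unsupported")
    anchor = genome.fetch(t.contig, lo - 1, lo - 1)
    return left_align(
        Variant(t.contig, lo - 1, anchor + deleted, anchor + inserted), genome
    )
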