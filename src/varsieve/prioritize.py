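"""The recessive-disease filtration cascade with a full audit ledger.

Order of filters (each recorded in the ledger):

1. normalize — left-align, drop unsupported records (counted, not silent)
2. panel — remove variants seen in the control panel at MAF strictly above
   the threshold (default 1%): the "common in the population" exclusion
3. recessive_high_impact — keep homozygous-alt or heterozygous variants with
   at least one HIGH-tier consequence under the primary annotation source
4. compound_het — heterozygous variants survive only in genes with at least
   two qualifying hets forming a trans (or phase-unresolved) pair
5. assembly_flags — remove variants confined to genes flagged for possible
   reference-assembly errors
6. concordance — require HIGH impact under the second annotation source too
7. candidate_genes — intersect with the disease candidate gene list

Every step satisfies variants_in = variants_removed + variants_kept, and the
kept set of one step is exactly the input of the next.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable

import pysam

from .consequence import (
    HIGH,
    TIER_RANK,
    ConsequenceCall,
    annotate_callset,
    genes_of_variant,
)
from .genome import ReferenceGenome, TranscriptModel
from .variants import (
    Callset,
    GenotypeCall,
    Variant,
    VariantCall,
    left_align,
    to_hgvs_g,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PanelSite",
    "FilterLedger",
    "LedgerStep",
    "CascadeConfig",
    "CascadeResult",
    "CandidateRecord",
    "read_panel",
    "panel_subtract",
    "recessive_partition",
    "compound_het_genes",
    "exclude_assembly_errors",
    "concordance_filter",
    "candidate_gene_filter",
    "run_cascade",
]


@dataclass(frozen=True)
class PanelSite:
    """Control-population allele frequency at one variant key (left-aligned)."""

    key: str
    allele_count: int
    allele_number: int

    @property
    def maf(self) -> float:
        if self.allele_number == 0:
            return 0.0
        af = self.allele_count / self.allele_number
        return min(af, 1.0 - af)


@dataclass
class LedgerStep:
    name: str
    variants_in: int
    variants_removed: int
    variants_kept: int
    genes_in: int
    genes_kept: int
    detail: dict = field(default_factory=dict)


class FilterLedger:
    """Ordered audit of the cascade; enforces count conservation."""

    def __init__(self) -> None:
        self.steps: list[LedgerStep] = []

    def add(self, step: LedgerStep) -> None:
        if step.variants_in != step.variants_removed + step.variants_kept:
            raise ValueError(
                f"ledger step {step.name}: {step.variants_in} != "
                f"{step.variants_removed} + {step.variants_kept}"
            )
        if self.steps and step.variants_in != self.steps[-1].variants_kept:
            raise ValueError(
                f"ledger step {step.name}: input {step.variants_in} does not "
                f"match previous kept {self.steps[-1].variants_kept}"
            )
        self.steps.append(step)
        logger.info(
            "%s: %d in, %d removed, %d kept (%d -> %d genes)",
            step.name,
            step.variants_in,
            step.variants_removed,
            step.variants_kept,
            step.genes_in,
            step.genes_kept,
        )

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "name": s.name,
                    "variants_in": s.variants_in,
                    "variants_removed": s.variants_removed,
                    "variants_kept": s.variants_kept,
                    "genes_in": s.genes_in,
                    "genes_kept": s.genes_kept,
                    "detail": s.detail,
                }
                for s in self.steps
            ]
        }


@dataclass
class CascadeConfig:
    maf_threshold: float = 0.01
    impact_floor: str = HIGH
    use_assembly_filter: bool = True
    use_concordance: bool = True
    use_candidate_filter: bool = True
    proband: str | None = None  # sample name; default: first sample


@dataclass
class CandidateRecord:
    variant: Variant
    zygosity: str
    mode: str  # 'homozygous' | 'compound_het'
    genes: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    phase_note: str = ""
    hgvs_g: str = ""
    best_call: ConsequenceCall | None = None


@dataclass
class CascadeResult:
    candidates: list[CandidateRecord]
    ledger: FilterLedger
    consequences: dict[str, list[ConsequenceCall]]
    compound_het: dict[str, list[tuple[str, str, str]]]


def read_panel(path: str) -> dict[str, PanelSite]:
    """Load a control panel from a sites VCF (INFO AC/AN) or a TSV with
    columns contig, pos, ref, alt, ac, an."""
    sites: dict[str, PanelSite] = {}
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                for ai, alt in enumerate(rec.alts or ()):
                    ac = rec.info.get("AC")
                    an = rec.info.get("AN", 0)
                    count = ac[ai] if isinstance(ac, tuple) else (ac or 0)
                    key = f"{rec.contig}:{rec.pos}:{rec.ref.upper()}:{alt.upper()}"
                    sites[key] = PanelSite(key, int(count), int(an))
    else:
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or row[0].startswith("#"):
                    continue
                contig, pos, ref, alt, ac, an = row[:6]
                key = f"{contig}:{int(pos)}:{ref.upper()}:{alt.upper()}"
                sites[key] = PanelSite(key, int(ac), int(an))
    return sites


def panel_subtract(
    calls: list[VariantCall],
    panel: dict[str, PanelSite],
    maf_threshold: float = 0.01,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Remove variants whose left-aligned key matches a panel site with
    MAF strictly above the threshold."""
    if not 0.0 <= maf_threshold <= 0.5:
        raise ValueError(f"MAF threshold {maf_threshold} outside [0, 0.5]")
    kept, removed = [], []
    for call in calls:
        site = panel.get(call.variant.key)
        if site is not None and site.maf > maf_threshold:
            removed.append(call)
        else:
            kept.append(call)
    return kept, removed


def recessive_partition(
    calls: list[VariantCall],
    consequences: list[ConsequenceCall],
    impact_floor: str = HIGH,
    proband: str | None = None,
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Split into (hom_candidates, het_pool, discarded) by zygosity and
    impact under the given source's consequences."""
    floor = TIER_RANK[impact_floor]
    qualifying = {
        c.variant_key
        for c in consequences
        if TIER_RANK[c.impact_tier] >= floor
    }
    hom, het, discarded = [], [], []
    for call in calls:
        g = call.genotype(proband)
        if call.variant.key in qualifying and g.zygosity == "hom_alt":
            hom.append(call)
        elif call.variant.key in qualifying and g.zygosity == "het":
            het.append(call)
        else:
            discarded.append(call)
    return hom, het, discarded


def compound_het_genes(
    het_pool: list[VariantCall],
    consequences: list[ConsequenceCall],
    impact_floor: str = HIGH,
    proband: str | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Genes with at least two qualifying heterozygous variants that can sit
    on opposite haplotypes.

    A pair is **trans** when both variants are phased in the same phase set
    with the alt alleles on different haplotypes; **phase-unresolved** when
    phase does not connect them (different phase sets or unphased); pairs
    proven cis are excluded.  Returns gene -> list of
    (key1, key2, 'trans'|'phase-unresolved').
    """
    floor = TIER_RANK[impact_floor]
    gene_calls: dict[str, dict[str, ConsequenceCall]] = {}
    for c in consequences:
        if c.gene_id is None or TIER_RANK[c.impact_tier] < floor:
            continue
        gene_calls.setdefault(c.gene_id, {})[c.variant_key] = c
    by_key = {call.variant.key: call for call in het_pool}
    result: dict[str, list[tuple[str, str, str]]] = {}
    for gene, keyed in gene_calls.items():
        members = sorted(k for k in keyed if k in by_key)
        if len(members) < 2:
            continue
        pairs = []
        for i, k1 in enumerate(members):
            for k2 in members[i + 1 :]:
                config = _pair_configuration(
                    by_key[k1].genotype(proband), by_key[k2].genotype(proband)
                )
                if config is not None:
                    pairs.append((k1, k2, config))
        if pairs:
            result[gene] = pairs
    return result


def _pair_configuration(g1: GenotypeCall, g2: GenotypeCall) -> str | None:
    """'trans', 'phase-unresolved', or None for a proven-cis pair."""
    h1, h2 = g1.alt_haplotype, g2.alt_haplotype
    if (
        h1 is not None
        and h2 is not None
        and g1.phase_set is not None
        and g1.phase_set == g2.phase_set
    ):
        return "trans" if h1 != h2 else None
    return "phase-unresolved"


def exclude_assembly_errors(
    calls: list[VariantCall],
    genes_by_key: dict[str, set[str]],
    flagged: set[str],
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Remove variants whose every gene assignment is flagged for possible
    assembly errors; variants also touching an unflagged gene stay."""
    kept, removed = [], []
    for call in calls:
        genes = genes_by_key.get(call.variant.key, set())
        if genes and genes <= flagged:
            removed.append(call)
        else:
            kept.append(call)
    return kept, removed


def concordance_filter(
    calls: list[VariantCall],
    calls_source_a: list[ConsequenceCall],
    calls_source_b: list[ConsequenceCall],
    impact_floor: str = HIGH,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Keep variants at or above the impact floor under BOTH annotation
    sources (any transcript each)."""
    if calls_source_a is None:
        raise ValueError("missing consequence calls for source A")
    if calls_source_b is None:
        raise ValueError("missing consequence calls for source B")
    floor = TIER_RANK[impact_floor]

    def qualifying(conseqs: list[ConsequenceCall]) -> set[str]:
        return {
            c.variant_key for c in conseqs if TIER_RANK[c.impact_tier] >= floor
        }

    ok = qualifying(calls_source_a) & qualifying(calls_source_b)
    kept = [c for c in calls if c.variant.key in ok]
    removed = [c for c in calls if c.variant.key not in ok]
    return kept, removed


def candidate_gene_filter(
    calls: list[VariantCall],
    genes_by_key: dict[str, set[str]],
    symbols_by_key: dict[str, set[str]],
    candidates: set[str],
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Keep variants in candidate genes; match by gene id first, then by
    symbol, case-insensitively."""
    if not candidates:
        raise ValueError("candidate gene set is empty but candidate filtering is enabled")
    wanted = {c.lower() for c in candidates}
    kept, removed = [], []
    for call in calls:
        ids = {g.lower() for g in genes_by_key.get(call.variant.key, set())}
        syms = {s.lower() for s in symbols_by_key.get(call.variant.key, set())}
        if ids & wanted or syms & wanted:
            kept.append(call)
        else:
            removed.append(call)
    return kept, removed


def _gene_count(calls: Iterable[VariantCall], genes_by_key: dict[str, set[str]]) -> int:
    genes: set[str] = set()
    for call in calls:
        genes |= genes_by_key.get(call.variant.key, set())
    return len(genes)


def _log_removed(step: str, removed: list[VariantCall]) -> None:
    for call in removed:
        logger.debug("%s removed %s", step, call.variant.key)


def run_cascade(
    config: CascadeConfig,
    callset: Callset,
    genome: ReferenceGenome,
    transcripts_a: list[TranscriptModel],
    transcripts_b: list[TranscriptModel],
    panel: dict[str, PanelSite],
    flagged_genes: set[str],
    candidate_genes: set[str],
) -> CascadeResult:
    """Execute the full filtration cascade; deterministic given its inputs."""
    ledger = FilterLedger()
    proband = config.proband

    # 1. normalize: left-align and deduplicate
    normalized: dict[str, VariantCall] = {}
    for call in callset:
        v = left_align(call.variant, genome)
        normalized.setdefault(v.key, VariantCall(v, call.genotypes, call.info))
    calls = sorted(
        normalized.values(), key=lambda c: (c.variant.contig, c.variant.pos, c.variant.alt)
    )
    dropped = len(callset.calls) - len(calls)
    ledger.add(
        LedgerStep(
            "normalize",
            variants_in=len(callset.calls),
            variants_removed=dropped,
            variants_kept=len(calls),
            genes_in=0,
            genes_kept=0,
            detail={
                "skipped_records": callset.skipped_records,
                "half_calls": callset.half_calls,
                "duplicates_merged": dropped,
            },
        )
    )

    # 2. control-panel subtraction
    kept, removed = panel_subtract(calls, panel, config.maf_threshold)
    _log_removed("panel", removed)
    ledger.add(
        LedgerStep(
            "panel",
            variants_in=len(calls),
            variants_removed=len(removed),
            variants_kept=len(kept),
            genes_in=0,
            genes_kept=0,
            detail={"maf_threshold": config.maf_threshold},
        )
    )
    calls = kept

    # 3. annotate under both sources, then recessive/high-impact partition
    conseq_a = annotate_callset(calls, transcripts_a, genome, "sourceA")
    conseq_b = annotate_callset(calls, transcripts_b, genome, "sourceB")
    genes_a = genes_of_variant(conseq_a)
    symbols_a: dict[str, set[str]] = {}
    for c in conseq_a:
        symbols_a.setdefault(c.variant_key, set())
        if c.gene_symbol:
            symbols_a[c.variant_key].add(c.gene_symbol)

    hom, het, discarded = recessive_partition(
        calls, conseq_a, config.impact_floor, proband
    )
    _log_removed("recessive_high_impact", discarded)
    ledger.add(
        LedgerStep(
            "recessive_high_impact",
            variants_in=len(calls),
            variants_removed=len(discarded),
            variants_kept=len(hom) + len(het),
            genes_in=_gene_count(calls, genes_a),
            genes_kept=_gene_count(hom + het, genes_a),
            detail={
                "homozygous": len(hom),
                "heterozygous": len(het),
                "impact_floor": config.impact_floor,
            },
        )
    )

    # 4. compound-het grouping of the het pool
    comphet = compound_het_genes(het, conseq_a, config.impact_floor, proband)
    paired_keys = {k for pairs in comphet.values() for pair in pairs for k in pair[:2]}
    het_kept = [c for c in het if c.variant.key in paired_keys]
    het_removed = [c for c in het if c.variant.key not in paired_keys]
    _log_removed("compound_het", het_removed)
    calls = hom + het_kept
    ledger.add(
        LedgerStep(
            "compound_het",
            variants_in=len(hom) + len(het),
            variants_removed=len(het_removed),
            variants_kept=len(calls),
            genes_in=_gene_count(hom + het, genes_a),
            genes_kept=_gene_count(calls, genes_a),
            detail={
                "genes_with_pairs": len(comphet),
                "trans_pairs": sum(
                    1 for pairs in comphet.values() for p in pairs if p[2] == "trans"
                ),
                "unresolved_pairs": sum(
                    1
                    for pairs in comphet.values()
                    for p in pairs
                    if p[2] == "phase-unresolved"
                ),
            },
        )
    )

    # 5. assembly-error gene exclusion
    if config.use_assembly_filter:
        kept, removed = exclude_assembly_errors(calls, genes_a, flagged_genes)
        _log_removed("assembly_flags", removed)
        ledger.add(
            LedgerStep(
                "assembly_flags",
                variants_in=len(calls),
                variants_removed=len(removed),
                variants_kept=len(kept),
                genes_in=_gene_count(calls, genes_a),
                genes_kept=_gene_count(kept, genes_a),
                detail={"flagged_genes": len(flagged_genes)},
            )
        )
        calls = kept

    # 6. dual-source concordance
    if config.use_concordance:
        kept, removed = concordance_filter(calls, conseq_a, conseq_b, config.impact_floor)
        _log_removed("concordance", removed)
        ledger.add(
            LedgerStep(
                "concordance",
                variants_in=len(calls),
                variants_removed=len(removed),
                variants_kept=len(kept),
                genes_in=_gene_count(calls, genes_a),
                genes_kept=_gene_count(kept, genes_a),
                detail={},
            )
        )
        calls = kept

    # 7. candidate-gene intersection
    if config.use_candidate_filter:
        sym_map = symbols_a
        kept, removed = candidate_gene_filter(calls, genes_a, sym_map, candidate_genes)
        _log_removed("candidate_genes", removed)
        ledger.add(
            LedgerStep(
                "candidate_genes",
                variants_in=len(calls),
                variants_removed=len(removed),
                variants_kept=len(kept),
                genes_in=_gene_count(calls, genes_a),
                genes_kept=_gene_count(kept, genes_a),
                detail={"candidate_genes": len(candidate_genes)},
            )
        )
        calls = kept

    hom_keys = {c.variant.key for c in hom}
    best_by_key: dict[str, ConsequenceCall] = {}
    for c in conseq_a:
        prev = best_by_key.get(c.variant_key)
        if prev is None or TIER_RANK[c.impact_tier] > TIER_RANK[prev.impact_tier]:
            best_by_key[c.variant_key] = c
    records = []
    for call in sorted(calls, key=lambda c: (c.variant.contig, c.variant.pos, c.variant.alt)):
        key = call.variant.key
        mode = "homozygous" if key in hom_keys else "compound_het"
        phase_note = ""
        if mode == "compound_het":
            notes = {
                p[2]
                for pairs in comphet.values()
                for p in pairs
                if key in p[:2]
            }
            phase_note = "trans" if "trans" in notes else "phase-unresolved"
        genes = tuple(sorted(genes_a.get(key, set())))
        syms = tuple(sorted(symbols_a.get(key, set())))
        records.append(
            CandidateRecord(
                variant=call.variant,
                zygosity=call.genotype(proband).zygosity,
                mode=mode,
                genes=genes,
                gene_symbols=syms,
                phase_note=phase_note,
                hgvs_g=to_hgvs_g(call.variant),
                best_call=best_by_key.get(key),
            )
        )
    return CascadeResult(
        candidates=records,
        ledger=ledger,
        consequences={"sourceA": conseq_a, "sourceB": conseq_b},
        compound_het=comphet,
    )
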