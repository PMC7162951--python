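"""Deterministic human-readable and machine-readable cascade reports."""

from __future__ import annotations

import json
from importlib import resources

from .prioritize import CascadeResult

__all__ = ["render_report", "report_schema"]


def report_schema() -> dict:
    """The shipped JSON schema for the machine-readable report."""
    text = resources.files("varsieve").joinpath("schemas/report.schema.json").read_text()
    return json.loads(text)


def render_report(result: CascadeResult) -> tuple[str, dict]:
    """Render the ledger and final candidates as (text, JSON-ready dict).

    Ordering is deterministic: ledger steps in cascade order, candidates by
    (contig, pos, alt).  Repeated runs on the same inputs are byte-identical.
    """
    ledger = result.ledger.to_dict()
    candidates = []
    for rec in result.candidates:
        best = rec.best_call
        candidates.append(
            {
                "key": rec.variant.key,
                "contig": rec.variant.contig,
                "pos": rec.variant.pos,
                "ref": rec.variant.ref,
                "alt": rec.variant.alt,
                "zygosity": rec.zygosity,
                "mode": rec.mode,
                "phase": rec.phase_note,
                "genes": list(rec.genes),
                "gene_symbols": list(rec.gene_symbols),
                "hgvs_g": rec.hgvs_g,
                "hgvs_c": best.hgvs_c if best else None,
                "category": best.category if best else None,
                "impact_tier": best.impact_tier if best else None,
                "wt_protein_length": best.wt_protein_length if best else 0,
                "mut_protein_length": best.mut_protein_length if best else 0,
                "first_divergent_residue": best.first_divergent_residue if best else 0,
            }
        )
    doc = {
        "ledger": ledger,
        "candidates": candidates,
        "summary": {
            "n_candidates": len(candidates),
            "candidate_genes": sorted({g for c in candidates for g in c["genes"]}),
            "compound_het_genes": sorted(result.compound_het),
        },
    }

    lines = ["Filtration cascade", "=" * 66]
    lines.append(f"{'step':<24}{'in':>8}{'removed':>10}{'kept':>8}{'genes':>8}")
    for step in ledger["steps"]:
        lines.append(
            f"{step['name']:<24}{step['variants_in']:>8}"
            f"{step['variants_removed']:>10}{step['variants_kept']:>8}"
            f"{step['genes_kept']:>8}"
        )
    lines.append("")
    if not candidates:
        lines.append("No candidate variant survives the cascade (explicit negative finding).")
    else:
        lines.append(f"Final candidates ({len(candidates)}):")
        for c in candidates:
            protein = ""
            if c["wt_protein_length"]:
                protein = (
                    f"; protein {c['mut_protein_length']} aa instead of "
                    f"{c['wt_protein_length']} aa, divergence at residue "
                    f"{c['first_divergent_residue']}"
                )
            lines.append(
                f"  {c['hgvs_g']} ({c['hgvs_c'] or 'n/a'}) "
                f"[{','.join(c['gene_symbols']) or ','.join(c['genes'])}] "
                f"{c['category']}/{c['impact_tier']}, {c['mode']}"
                + (f" ({c['phase']})" if c["phase"] else "")
                + protein
            )
    return "\n".join(lines) + "\n", doc
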