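"""Filtration cascade: each filter, the ledger, and cascade properties."""

import numpy as np
import pytest

from conftest import oracle_compound_het

from varsieve.consequence import ConsequenceCall
from varsieve.prioritize import (
    CascadeConfig,
    FilterLedger,
    LedgerStep,
    PanelSite,
    candidate_gene_filter,
    compound_het_genes,
    concordance_filter,
    exclude_assembly_errors,
    panel_subtract,
    recessive_partition,
    run_cascade,
)
from varsieve.variants import GenotypeCall, Variant, VariantCall


def _vc(key_pos, gt=(0, 1), phased=False, ps=None, contig="c"):
    v = Variant(contig, key_pos, "A", "T")
    return VariantCall(v, {"p": GenotypeCall("p", gt, phased=phased, phase_set=ps)})


def _cons(call, tier="HIGH", gene="g1", category="stop_gained", source="sourceA"):
    return ConsequenceCall(
        variant_key=call.variant.key,
        transcript_id=f"{gene}.t1",
        gene_id=gene,
        gene_symbol=gene.upper(),
        category=category,
        impact_tier=tier,
        annotation_source=source,
    )


class TestPanelSubtract:
    def test_common_removed_unknown_kept_boundary_kept(self):
        calls = [_vc(100), _vc(200), _vc(300)]
        panel = {
            calls[0].variant.key: PanelSite(calls[0].variant.key, 10, 200),  # 5%
            calls[2].variant.key: PanelSite(calls[2].variant.key, 2, 200),  # exactly 1%
        }
        kept, removed = panel_subtract(calls, panel, 0.01)
        assert [c.variant.pos for c in removed] == [100]
        assert [c.variant.pos for c in kept] == [200, 300]  # absent + boundary

    def test_maf_folding(self):
        site = PanelSite("k", 198, 200)  # major allele is the alt
        assert site.maf == pytest.approx(0.01)

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            panel_subtract([], {}, 0.7)

    def test_generator_bookkeeping(self, world7):
        """Panel subtraction removes exactly the planted common decoys."""
        calls = [c for c in world7.callset]
        kept, removed = panel_subtract(calls, world7.panel, 0.01)
        assert {c.variant.key for c in removed} == set(
            world7.truth.classes["common_high"]
        )


class TestRecessivePartition:
    def test_partition_by_zygosity_and_impact(self):
        hom_fs = _vc(100, gt=(1, 1))
        het_sg = _vc(200, gt=(0, 1))
        hom_syn = _vc(300, gt=(1, 1))
        cons = [
            _cons(hom_fs, "HIGH", category="frameshift"),
            _cons(het_sg, "HIGH"),
            _cons(hom_syn, "LOW", category="synonymous"),
        ]
        hom, het, discarded = recessive_partition([hom_fs, het_sg, hom_syn], cons)
        assert hom == [hom_fs] and het == [het_sg] and discarded == [hom_syn]


class TestCompoundHet:
    def test_trans_pair_retained(self):
        a = _vc(100, gt=(0, 1), phased=True, ps=1)
        b = _vc(200, gt=(1, 0), phased=True, ps=1)
        out = compound_het_genes([a, b], [_cons(a), _cons(b)])
        assert out == {"g1": [(a.variant.key, b.variant.key, "trans")]}

    def test_cis_pair_excluded(self):
        a = _vc(100, gt=(0, 1), phased=True, ps=1)
        b = _vc(200, gt=(0, 1), phased=True, ps=1)
        assert compound_het_genes([a, b], [_cons(a), _cons(b)]) == {}

    def test_unphased_pair_flagged_not_promoted(self):
        a = _vc(100, gt=(0, 1))
        b = _vc(200, gt=(0, 1))
        out = compound_het_genes([a, b], [_cons(a), _cons(b)])
        assert out["g1"][0][2] == "phase-unresolved"

    def test_single_het_gene_dropped(self):
        a = _vc(100, gt=(0, 1))
        assert compound_het_genes([a], [_cons(a)]) == {}

    def test_matches_bruteforce_enumeration_on_random_fixtures(self):
        """Random phase assignments over 50 synthetic genes equal the
        brute-force pairwise enumeration, repeatedly."""
        rng = np.random.default_rng(2024)
        for trial in range(20):
            calls, cons, oracle_input = [], [], {}
            pos = 100
            for gi in range(50):
                gene = f"g{gi}"
                n = int(rng.integers(0, 5))
                oracle_input[gene] = []
                for _ in range(n):
                    phased = bool(rng.random() < 0.6)
                    ps = int(rng.integers(1, 3)) if phased else None
                    hap = int(rng.integers(0, 2))
                    gt = (1, 0) if hap == 0 else (0, 1)
                    call = _vc(pos, gt=gt if phased else (0, 1), phased=phased, ps=ps)
                    pos += 10
                    calls.append(call)
                    cons.append(_cons(call, gene=gene))
                    oracle_input[gene].append(
                        {
                            "key": call.variant.key,
                            "phased": phased,
                            "ps": ps,
                            "hap": call.genotypes["p"].alt_haplotype,
                        }
                    )
            ours = compound_het_genes(calls, cons)
            theirs = oracle_compound_het(oracle_input)
            norm = lambda d: {
                g: sorted((min(a, b), max(a, b), c) for a, b, c in pairs)
                for g, pairs in d.items()
            }
            assert norm(ours) == norm(theirs)


class TestAssemblyAndConcordance:
    def test_flag_exclusion_and_mixed_gene_kept(self):
        a, b, c = _vc(100), _vc(200), _vc(300)
        genes = {a.variant.key: {"bad"}, b.variant.key: {"bad", "ok"}, c.variant.key: {"ok"}}
        kept, removed = exclude_assembly_errors([a, b, c], genes, {"bad"})
        assert removed == [a] and kept == [b, c]

    def test_empty_flag_set_is_identity(self):
        calls = [_vc(100), _vc(200)]
        kept, removed = exclude_assembly_errors(calls, {}, set())
        assert kept == calls and removed == []

    def test_flagged_removal_equals_set_intersection(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(20)]
        flagged = set(genes[:5])
        calls, gmap = [], {}
        for i in range(60):
            call = _vc(100 + i * 10)
            gmap[call.variant.key] = {genes[int(rng.integers(0, 20))]}
            calls.append(call)
        kept, removed = exclude_assembly_errors(calls, gmap, flagged)
        expected_removed = {c.variant.key for c in calls if gmap[c.variant.key] <= flagged}
        assert {c.variant.key for c in removed} == expected_removed

    def test_concordance_requires_high_in_both(self):
        calls = [_vc(100 + 10 * i) for i in range(12)]
        cons_a = [_cons(c, "HIGH") for c in calls]
        cons_b = [
            _cons(c, "MODIFIER" if i < 3 else "HIGH", source="sourceB")
            for i, c in enumerate(calls)
        ]
        kept, removed = concordance_filter(calls, cons_a, cons_b)
        assert len(kept) == 9 and len(removed) == 3

    def test_missing_source_named_in_error(self):
        with pytest.raises(ValueError, match="source B"):
            concordance_filter([], [], None)


class TestCandidateFilter:
    def test_symbol_fallback_case_insensitive(self):
        a, b = _vc(100), _vc(200)
        genes = {a.variant.key: {"gene001"}, b.variant.key: {"gene002"}}
        syms = {a.variant.key: {"Idua"}, b.variant.key: {"OTHER"}}
        kept, removed = candidate_gene_filter([a, b], genes, syms, {"IDUA"})
        assert kept == [a] and removed == [b]

    def test_empty_candidate_set_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            candidate_gene_filter([], {}, {}, set())


class TestLedger:
    def test_conservation_enforced(self):
        ledger = FilterLedger()
        ledger.add(LedgerStep("a", 10, 4, 6, 0, 0))
        with pytest.raises(ValueError, match="!="):
            ledger.add(LedgerStep("b", 6, 2, 5, 0, 0))
        with pytest.raises(ValueError, match="does not match previous"):
            ledger.add(LedgerStep("c", 5, 1, 4, 0, 0))

    def test_cascade_ledger_invariants(self, world7):
        result = run_cascade(
            CascadeConfig(),
            world7.callset,
            world7.genome,
            world7.transcripts_a,
            world7.transcripts_b,
            world7.panel,
            world7.flagged,
            world7.candidates,
        )
        steps = result.ledger.steps
        kept = [s.variants_kept for s in steps]
        assert kept == sorted(kept, reverse=True)  # monotone non-increasing
        for prev, nxt in zip(steps, steps[1:]):
            assert nxt.variants_in == prev.variants_kept
        names = [s.name for s in steps]
        assert names == [
            "normalize",
            "panel",
            "recessive_high_impact",
            "compound_het",
            "assembly_flags",
            "concordance",
            "candidate_genes",
        ]


class TestCascade:
    def test_filter_order_exchange(self, world7):
        """Assembly-error exclusion and concordance commute: disabling each
        in turn and applying it afterwards gives the same final set."""
        base = run_cascade(
            CascadeConfig(),
            world7.callset,
            world7.genome,
            world7.transcripts_a,
            world7.transcripts_b,
            world7.panel,
            world7.flagged,
            world7.candidates,
        )
        # run with assembly OFF, then apply assembly to the survivors
        alt = run_cascade(
            CascadeConfig(use_assembly_filter=False),
            world7.callset,
            world7.genome,
            world7.transcripts_a,
            world7.transcripts_b,
            world7.panel,
            world7.flagged,
            world7.candidates,
        )
        from varsieve.consequence import genes_of_variant

        genes = genes_of_variant(alt.consequences["sourceA"])
        survivors = [
            type("C", (), {"variant": r.variant, "genotypes": {}})
            for r in alt.candidates
        ]
        kept, _ = exclude_assembly_errors(survivors, genes, world7.flagged)
        assert {c.variant.key for c in kept} == {
            r.variant.key for r in base.candidates
        }

    def test_causal_in_panel_yields_no_candidates(self, world7):
        """Sensitivity: if the causal variant were common (panel MAF 2%),
        the cascade would return an empty set."""
        (key,) = world7.truth.causal_keys
        panel = dict(world7.panel)
        panel[key] = PanelSite(key, 4, 200)
        result = run_cascade(
            CascadeConfig(),
            world7.callset,
            world7.genome,
            world7.transcripts_a,
            world7.transcripts_b,
            panel,
            world7.flagged,
            world7.candidates,
        )
        assert result.candidates == []
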