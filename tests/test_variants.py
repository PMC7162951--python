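"""VCF I/O, indel normalization, equivalent placements, HGVS."""

import numpy as np
import pytest

from conftest import make_transcript, oracle_normalize

from varsieve.genome import ReferenceGenome, reverse_complement
from varsieve.variants import (
    Callset,
    GenotypeCall,
    HgvsError,
    ReferenceMismatchError,
    Variant,
    VariantCall,
    enumerate_equivalent_placements,
    hgvs_c_to_variant,
    insertion_placements,
    left_align,
    parse_hgvs_c,
    read_vcf,
    to_hgvs_c,
    to_hgvs_g,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tdog1\n"
)


def _vcf(tmp_path, body):
    p = tmp_path / "x.vcf"
    p.write_text(VCF_HEADER + body)
    return str(p)


class TestReadVcf:
    def test_simple_het(self, tmp_path):
        cs = read_vcf(_vcf(tmp_path, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/1\n"))
        (call,) = cs.calls
        assert call.variant == Variant("chr1", 100, "A", "T")
        g = call.genotype()
        assert g.zygosity == "het" and not g.phased

    def test_multiallelic_split_matches_manual(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tT,G\t.\t.\t.\tGT\t1/2\n"
            "chr1\t200\t.\tC\tCA,CAA\t.\t.\t.\tGT\t0/2\n"
            "chr1\t300\t.\tG\tA\t.\t.\t.\tGT\t1/1\n"
            "chr1\t400\t.\tT\tC\t.\t.\t.\tGT\t0/0\n"
            "chr1\t500\t.\tAC\tA\t.\t.\t.\tGT\t0/1\n"
        )
        cs = read_vcf(_vcf(tmp_path, body))
        # manual split of the 5-record toy VCF: 7 bi-allelic variants
        expected = [
            (Variant("chr1", 100, "A", "T"), "het"),
            (Variant("chr1", 100, "A", "G"), "het"),
            (Variant("chr1", 200, "C", "CA"), "hom_ref"),
            (Variant("chr1", 200, "C", "CAA"), "het"),
            (Variant("chr1", 300, "G", "A"), "hom_alt"),
            (Variant("chr1", 400, "T", "C"), "hom_ref"),
            (Variant("chr1", 500, "AC", "A"), "het"),
        ]
        got = [(c.variant, c.genotype().zygosity) for c in cs.calls]
        assert got == expected

    def test_phase_and_phase_set_preserved(self, tmp_path):
        cs = read_vcf(_vcf(tmp_path, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT:PS\t0|1:100\n"))
        g = cs.calls[0].genotype()
        assert g.phased and g.phase_set == 100 and g.alt_haplotype == 1

    def test_half_calls_counted_as_missing(self, tmp_path):
        cs = read_vcf(_vcf(tmp_path, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t./1\n"))
        assert cs.half_calls == 1
        assert cs.calls[0].genotype().zygosity == "missing"

    def test_symbolic_alleles_skipped_with_count(self, tmp_path):
        body = "chr1\t100\t.\tA\t<DEL>\t.\t.\t.\tGT\t0/1\nchr1\t200\t.\tA\tT\t.\t.\t.\tGT\t0/1\n"
        cs = read_vcf(_vcf(tmp_path, body))
        assert cs.skipped_records == 1 and len(cs) == 1

    def test_round_trip_preserves_variants_genotypes_phase(self, tmp_path):
        calls = [
            VariantCall(
                Variant("chr1", 100, "A", "AT"),
                {"dog1": GenotypeCall("dog1", (0, 1), phased=True, phase_set=100)},
            ),
            VariantCall(
                Variant("chr1", 300, "G", "C"),
                {"dog1": GenotypeCall("dog1", (1, 1))},
            ),
        ]
        out = tmp_path / "rt.vcf"
        write_vcf(str(out), Callset(["dog1"], calls), {"chr1": 1000})
        back = read_vcf(str(out))
        assert [c.variant for c in back.calls] == [c.variant for c in calls]
        assert [c.genotype() for c in back.calls] == [c.genotype() for c in calls]


class TestLeftAlign:
    def test_homopolymer_insertion_shifts_to_run_start(self):
        genome = ReferenceGenome({"c": "CAAAG"})
        # insertion of A after position 4 == insertion after the C at 1
        v = left_align(Variant("c", 4, "A", "AA"), genome)
        assert v == Variant("c", 1, "C", "CA")

    def test_snv_unchanged(self):
        genome = ReferenceGenome({"c": "CAAAG"})
        assert left_align(Variant("c", 3, "A", "T"), genome) == Variant("c", 3, "A", "T")

    def test_ref_mismatch_signals_wrong_build(self):
        genome = ReferenceGenome({"c": "CAAAG"})
        with pytest.raises(ReferenceMismatchError):
            left_align(Variant("c", 3, "G", "T"), genome)

    def test_idempotent_and_matches_haplotype_diff_oracle(self):
        """1000 random indels: left_align is idempotent, equals the
        suffix-then-prefix haplotype-diff oracle, and preserves the
        alternate haplotype."""
        rng = np.random.default_rng(12345)
        bases = "ACGT"
        checked = 0
        while checked < 1000:
            n = int(rng.integers(20, 60))
            seq = "".join(bases[i] for i in rng.integers(0, 4, size=n))
            # bias toward repeats so shifting actually happens
            if rng.random() < 0.5:
                unit = "".join(bases[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
                mid = n // 2
                seq = seq[:mid] + unit * int(rng.integers(2, 6)) + seq[mid:]
            genome = ReferenceGenome({"c": seq})
            pos = int(rng.integers(2, len(seq) - 6))
            if rng.random() < 0.5:  # insertion
                ins = "".join(bases[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 5))))
                v = Variant("c", pos, seq[pos - 1], seq[pos - 1] + ins)
                alt_hap = seq[:pos] + ins + seq[pos:]
            else:  # deletion
                dlen = int(rng.integers(1, 4))
                v = Variant("c", pos, seq[pos - 1 : pos + dlen], seq[pos - 1])
                alt_hap = seq[:pos] + seq[pos + dlen :]
            norm = left_align(v, genome)
            assert left_align(norm, genome) == norm  # idempotent
            expected = oracle_normalize("c", seq, alt_hap)
            assert ("c", norm.pos, norm.ref, norm.alt) == expected
            # the normalized variant still produces the same haplotype
            rebuilt = seq[: norm.pos - 1] + norm.alt + seq[norm.end :]
            assert rebuilt == alt_hap
            checked += 1


class TestPlacements:
    def test_homopolymer_run(self):
        run = insertion_placements("CAAAG", 4, "A")
        assert list(run.positions) == [1, 2, 3, 4]

    def test_non_insertion_rejected(self):
        genome = ReferenceGenome({"c": "CAAAG"})
        with pytest.raises(ValueError, match="not a pure insertion"):
            enumerate_equivalent_placements(Variant("c", 2, "AA", "A"), genome)

    def test_members_yield_identical_alternate_sequence(self):
        context = "ATGCGGCCCCCCGGCCCCCA"
        original_alt = context[:19] + "CGGCCCCC" + context[19:]
        run = insertion_placements(context, 19, "CGGCCCCC")
        for p in run.positions:
            # the appropriately rotated insert at p rebuilds the same alt
            assert any(
                context[:p] + rot + context[p:] == original_alt
                for rot in _rotations("CGGCCCCC")
            )

    def test_equals_exhaustive_enumeration_on_random_contexts(self):
        """Random contexts ≤50 bp: the placement run equals the set of
        insertion points that brute-force produce the identical alternate."""
        rng = np.random.default_rng(99)
        bases = "ACGT"
        for _ in range(300):
            n = int(rng.integers(5, 51))
            context = "".join(bases[i] for i in rng.integers(0, 4, size=n))
            ins = "".join(bases[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 6))))
            after = int(rng.integers(0, n + 1))
            alt = context[:after] + ins + context[after:]
            expected = {
                p
                for p in range(n + 1)
                for rot in _rotations(ins)
                if context[:p] + rot + context[p:] == alt
            }
            run = insertion_placements(context, after, ins)
            assert set(run.positions) == expected
            # contiguity is part of the contract
            assert sorted(expected) == list(range(min(expected), max(expected) + 1))


def _rotations(s):
    return {s[i:] + s[:i] for i in range(len(s))}


CAUSAL_CDS = "ATG" + "CGGCCCCC" * 2 + "GA" + "GCTTGGAAGCTT" * 20 + "TGA"


class TestHgvs:
    def test_minus_strand_genomic_insertion_renders_transcript_insert(self):
        """A genomic GGGGGCCG insertion on a minus-strand gene is reported as
        c.19_20insCGGCCCCC: reverse complement plus the 3' rule."""
        genome, t = make_transcript(CAUSAL_CDS, strand="-")
        v = hgvs_c_to_variant(parse_hgvs_c("c.19_20insCGGCCCCC"), t, genome)
        assert "GGGGGCCG" in v.alt[1:] + v.alt[1:]  # some rotation of the rc insert
        assert to_hgvs_c(v, t, genome) == "c.19_20insCGGCCCCC"

    def test_plus_strand_snv(self):
        genome, t = make_transcript("ATG" + "AAA" * 10 + "TAA", strand="+", cds_offset=101)
        v = Variant("chrT", 105, "A", "G")
        assert to_hgvs_c(v, t, genome) == "c.5A>G"

    def test_three_prime_shift_in_homopolymer(self):
        """An insertion into a c. homopolymer run is anchored at the run's 3'
        end, matching the brute-force most-3' equivalent placement."""
        cds = "ATGCCCTTT" + "AAAAA" + "GGGCCCTAA"  # run at c.10-14
        genome, t = make_transcript(cds, strand="+")
        # insert an A after c.10 (leftmost representation)
        g = 100 + 9  # genomic of c.10 with cds_offset 100
        v = Variant("chrT", g, genome.fetch("chrT", g, g), genome.fetch("chrT", g, g) + "A")
        assert to_hgvs_c(v, t, genome) == "c.14_15insA"

    def test_hgvs_g_forms(self):
        assert to_hgvs_g(Variant("chr3", 91534556, "T", "TGGGGGCCG")) == (
            "chr3:g.91534556_91534557insGGGGGCCG"
        )
        assert to_hgvs_g(Variant("chr1", 100, "A", "T")) == "chr1:g.100A>T"
        assert to_hgvs_g(Variant("chr1", 49, "CAT", "C")) == "chr1:g.50_51del"

    @pytest.mark.parametrize(
        "text,kind,start,end,alt",
        [
            ("c.19_20insCGGCCCCC", "ins", 19, 20, "CGGCCCCC"),
            ("c.5A>G", "snv", 5, 5, "G"),
            ("c.7_9del", "del", 7, 9, ""),
            ("c.7_9delinsAT", "delins", 7, 9, "AT"),
        ],
    )
    def test_parse_hgvs_c(self, text, kind, start, end, alt):
        h = parse_hgvs_c(text)
        assert (h.kind, h.start, h.end, h.alt) == (kind, start, end, alt)

    @pytest.mark.parametrize("bad", ["c.19insX", "c.19_21insAC", "g.100A>T", "c.9_7del"])
    def test_parse_errors_name_the_token(self, bad):
        with pytest.raises(HgvsError):
            parse_hgvs_c(bad)

    def test_round_trip_through_genome_projection(self):
        """parse -> genomic variant -> re-render recovers the 3'-anchored
        description for both strands."""
        for strand in "+-":
            genome, t = make_transcript(CAUSAL_CDS, strand=strand)
            v = hgvs_c_to_variant(parse_hgvs_c("c.19_20insCGGCCCCC"), t, genome)
            assert to_hgvs_c(v, t, genome) == "c.19_20insCGGCCCCC"


# hypothesis property checks ------------------------------------------------

from hypothesis import given, settings, strategies as st

_DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestPlacementProperties:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(context=_DNA, ins=st.text(alphabet="ACGT", min_size=1, max_size=6), data=st.data())
    def test_run_contains_origin_and_is_contiguous(self, context, ins, data):
        """Any placement run contains the originating insertion point, and
        shrinking/extending by one position leaves the run (contiguity)."""
        after = data.draw(st.integers(min_value=0, max_value=len(context)))
        run = insertion_placements(context, after, ins)
        assert run.first <= after <= run.last
        positions = list(run.positions)
        assert positions == list(range(run.first, run.last + 1))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=8, max_size=50), data=st.data())
    def test_left_align_never_moves_right(self, seq, data):
        genome = ReferenceGenome({"c": seq})
        pos = data.draw(st.integers(min_value=1, max_value=len(seq) - 5))
        ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
        v = Variant("c", pos, seq[pos - 1], seq[pos - 1] + ins)
        assert left_align(v, genome).pos <= pos
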