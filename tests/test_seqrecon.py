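import numpy as np
import pytest

from apricolor import seqrecon as sr
from apricolor.locus import PrimerPair, revcomp
from apricolor.synthetic_data import AlleleSpec, simulate_allele_sequence

F = "GATTACACCTGAAGGATCCT"  # 20-mer forward primer for constructed templates
R = "CTTGAACGGTAGGTACCAGT"  # 20-mer reverse primer
PAIR = PrimerPair("toy", F, R, 45)


def pcr_oracle(template, primers, max_product=5000):
    """Exhaustive placement oracle: scan every (i, j) primer placement."""
    products = []
    n = len(template)
    for strand, seq in (("+", template), ("-", revcomp(template))):
        rr = revcomp(primers.reverse)
        for i in range(n - len(primers.forward) + 1):
            if seq[i : i + len(primers.forward)] != primers.forward:
                continue
            for j in range(i + len(primers.forward), n - len(rr) + 1):
                if seq[j : j + len(rr)] != rr:
                    continue
                end = j + len(rr)
                if end - i > max_product:
                    continue
                if strand == "+":
                    products.append((i, end, "+"))
                else:
                    products.append((n - end, n - i, "-"))
    return sorted(products)


class TestInsilicoPcr:
    def test_constructed_product(self):
        template = "AAAA" + F + "AAAAA" + revcomp(R) + "GGGG"
        products = sr.insilico_pcr(template, PAIR)
        assert len(products) == 1
        assert products[0].length == 45
        assert products[0].sequence == F + "AAAAA" + revcomp(R)
        assert (products[0].start, products[0].end) == (4, 49)

    def test_no_reverse_site_gives_empty_list(self):
        template = "AAAA" + F + "AAAAA"
        assert sr.insilico_pcr(template, PAIR) == []

    def test_two_reverse_sites_give_two_products(self):
        template = F + "AA" + revcomp(R) + "CC" + revcomp(R)
        products = sr.insilico_pcr(template, PAIR)
        assert [p.length for p in products] == [42, 64]
        assert [(p.start, p.end, p.strand) for p in products] == pcr_oracle(template, PAIR)

    def test_matches_exhaustive_oracle_on_random_templates(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(50):
            template = "".join(rng.choice(bases, size=1000))
            # implant sites to make products likely
            i, j = sorted(rng.integers(0, 900, size=2))
            template = template[:i] + F + template[i + 20 : j] + revcomp(R) + template[j + 20 :]
            got = [(p.start, p.end, p.strand) for p in sr.insilico_pcr(template, PAIR)]
            assert got == pcr_oracle(template, PAIR)

    def test_product_lengths_invariant_under_template_revcomp(self):
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        template = F + "".join(rng.choice(bases, size=300)) + revcomp(R)
        fwd = sorted(p.length for p in sr.insilico_pcr(template, PAIR))
        rev = sorted(p.length for p in sr.insilico_pcr(revcomp(template), PAIR))
        assert fwd == rev and fwd

    def test_max_product_cap(self):
        template = F + "A" * 200 + revcomp(R)
        assert sr.insilico_pcr(template, PAIR, max_product=100) == []


class TestTandemRepeat:
    def test_simple_run(self):
        tract = sr.find_tandem_repeat("TTAGCAGCAGCAGCAGCGG", "AGC")
        assert (tract.start, tract.repeat_count) == (2, 5)
        assert tract.span_bp == 15

    def test_longest_of_several_runs(self):
        seq = "TT" + "AGC" * 3 + "TTTT" + "AGC" * 6 + "TT"
        tract = sr.find_tandem_repeat(seq, "AGC")
        assert (tract.start, tract.repeat_count) == (2 + 9 + 4, 6)

    def test_absent_motif(self):
        assert sr.find_tandem_repeat("TTTTTT", "AGC") is None

    def test_phase_detection(self):
        # GCA-phase run embedded without a pure AGC start
        seq = "TTGCAGCAGCATT"
        tract = sr.find_tandem_repeat(seq, "AGC")
        assert tract.repeat_count == 3
        assert tract.motif in ("GCA", "AGC", "CAG")

    def test_leftmost_on_ties(self):
        seq = "AGCAGC" + "TTTT" + "AGCAGC"
        tract = sr.find_tandem_repeat(seq, "AGC")
        assert tract.start == 0


class TestSnpExtraction:
    def test_reference_returns_reference_states(self, reference):
        result = sr.extract_snp_states(reference.template)
        assert result.states == ("C", "G", "A", "A")
        assert not result.novel

    def test_expanded_tract_with_substitutions(self, named_loci):
        # SSR +2 units with SNP1 C→T, SNP2 G→T, SNP4 A→G is Allele 3
        result = sr.extract_snp_states(named_loci["Allele 3"].template)
        assert result.states == ("T", "T", "A", "G")

    def test_flank_deletion_rejected(self, reference):
        broken = reference.template[:50] + reference.template[53:]
        with pytest.raises(sr.AlignmentAmbiguityError):
            sr.extract_snp_states(broken)

    def test_flank_point_mismatch_rejected(self, reference):
        t = reference.template
        pos = 400
        while pos in {s.offset for s in sr.SNP_DEFINITIONS}:
            pos += 1
        base = "A" if t[pos] != "A" else "G"
        with pytest.raises(sr.AlignmentAmbiguityError):
            sr.extract_snp_states(t[:pos] + base + t[pos + 1 :])

    def test_novel_state_flagged_not_fatal(self, reference):
        snp3 = next(s for s in sr.SNP_DEFINITIONS if s.short_name == "SNP3")
        t = reference.template
        mutated = t[: snp3.offset] + "C" + t[snp3.offset + 1 :]
        result = sr.extract_snp_states(mutated)
        assert result.states[2] == "C"
        assert result.novel == {"SNP3": "C"}


class TestHaplotypeAssembly:
    @pytest.mark.parametrize(
        "size, states, name",
        [
            (108, ("C", "G", "A", "A"), "Allele 1"),
            (111, ("C", "G", "G", "G"), "Allele 2"),
            (114, ("T", "T", "A", "G"), "Allele 3"),
            (120, ("C", "G", "A", "G"), "Allele 4"),
        ],
    )
    def test_named_alleles(self, size, states, name):
        assert sr.assemble_haplotype(size, states).allele_name == name

    def test_unlisted_combination_is_novel(self):
        call = sr.assemble_haplotype(108, ("T", "T", "A", "G"))
        assert call.is_novel
        assert call.ssr_amplicon_size == 108
        assert call.snp_states == ("T", "T", "A", "G")


class TestRoundTrip:
    def test_named_alleles_recovered_exactly(self, named_specs):
        sizes = {}
        for name, spec in named_specs.items():
            loc = simulate_allele_sequence(spec)
            products = sr.insilico_pcr(loc.template, sr.COL1_PRIMERS)
            assert len(products) == 1
            tract = sr.find_tandem_repeat(products[0].sequence)
            assert tract.repeat_count == spec.repeat_count
            states = sr.extract_snp_states(loc.template).states
            call = sr.assemble_haplotype(products[0].length, states)
            assert call.allele_name == name
            sizes[name] = products[0].length
        assert sorted(sizes.values()) == [108, 111, 114, 120]

    def test_amplicon_size_is_linear_in_repeat_count(self):
        def size(n):
            loc = simulate_allele_sequence(AlleleSpec(n, ("C", "G", "A", "A")))
            (product,) = sr.insilico_pcr(loc.template, sr.COL1_PRIMERS)
            return product.length

        sizes = {n: size(n) for n in (2, 4, 5, 6, 8, 12)}
        for n in sizes:
            for m in sizes:
                assert sizes[n] - sizes[m] == 3 * (n - m)

    def test_arbitrary_specs_round_trip(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(2, 15))
            states = tuple(rng.choice(list("ACGT")) for _ in range(4))
            loc = simulate_allele_sequence(AlleleSpec(n, states))
            (product,) = sr.insilico_pcr(loc.template, sr.COL1_PRIMERS)
            assert product.length == 96 + 3 * n
            assert sr.find_tandem_repeat(loc.template).repeat_count == n
            assert sr.extract_snp_states(loc.template).states == states

    def test_full_reconstruction_helper(self, named_loci):
        for name, loc in named_loci.items():
            assert sr.reconstruct_allele(loc.template).allele_name == name
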