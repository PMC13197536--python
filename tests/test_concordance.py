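import itertools

import pytest

from apricolor import concordance as cc
from apricolor.colorimetry import HueClass, PhenotypeRecord
from apricolor.io_tables import fixture_phenotype_records


def _pheno(ind, hue_class, hue=70.0):
    return PhenotypeRecord(ind, hue, 1.0, 6, HueClass(hue_class))


@pytest.fixture(scope="module")
def snp1():
    return cc.get_marker("S3_22924169")


@pytest.fixture(scope="module")
def col1():
    return cc.get_marker("col1")


class TestParseGenotype:
    def test_snp_call(self, snp1):
        rec = cc.parse_genotype("C/T", snp1, "x")
        assert (rec.allele_1, rec.allele_2, rec.missing) == ("C", "T", False)

    def test_missing_code(self, snp1):
        assert cc.parse_genotype("X/X", snp1).missing

    def test_order_invariance(self, snp1):
        assert cc.parse_genotype("T/C", snp1) == cc.parse_genotype("C/T", snp1)

    @pytest.mark.parametrize("call", ["C", "C/T/G", "C/", "A/G"])
    def test_malformed_or_foreign_alleles(self, call, snp1):
        with pytest.raises(cc.GenotypeParseError):
            cc.parse_genotype(call, snp1)

    def test_ssr_sizes_pass_through(self, col1):
        rec = cc.parse_genotype("114/108", col1)
        assert (rec.allele_1, rec.allele_2) == ("108", "114")


class TestPredict:
    @pytest.mark.parametrize(
        "call, expected",
        [("C/C", "yellow"), ("C/T", "orange"), ("T/T", "orange")],
    )
    def test_snp1_rule(self, call, expected, snp1):
        rec = cc.parse_genotype(call, snp1)
        assert cc.predict_phenotype(rec, snp1) == expected

    @pytest.mark.parametrize(
        "call, expected",
        [("A/A", "yellow"), ("A/G", "orange"), ("G/G", "orange")],
    )
    def test_snp4_rule(self, call, expected):
        snp4 = cc.get_marker("snp4")
        rec = cc.parse_genotype(call, snp4)
        assert cc.predict_phenotype(rec, snp4) == expected

    @pytest.mark.parametrize(
        "call, expected",
        [
            ("108/108", "yellow"),
            ("108/114", "orange"),  # orange-dominant heterozygote
            ("111/120", "orange"),
        ],
    )
    def test_ssr_orange_dominant(self, call, expected, col1):
        rec = cc.parse_genotype(call, col1)
        assert cc.predict_phenotype(rec, col1) == expected

    def test_missing_not_scorable(self, snp1):
        with pytest.raises(cc.NotScorableError):
            cc.predict_phenotype(cc.parse_genotype("X/X", snp1), snp1)

    def test_unknown_ssr_allele(self, col1):
        with pytest.raises(cc.UnknownGenotypeError):
            cc.predict_phenotype(cc.parse_genotype("108/999", col1), col1)


class TestScoring:
    @pytest.mark.parametrize(
        "predicted, observed, expected",
        [
            ("orange", "light_orange", True),  # transitional class scores orange
            ("yellow", "yellow", True),
            ("orange", "yellow", False),
            ("yellow", "light_orange", False),
        ],
    )
    def test_collapse(self, predicted, observed, expected):
        assert cc.score_concordance(predicted, observed) is expected

    def test_collapse_rule_uniquely_reproduces_panel(self, table2, snp1):
        """Of the two admissible binary collapses of light orange, only
        light_orange→orange gives 51/57 on the cultivar panel."""
        rows = list(table2.table.itertuples(index=False))
        outcomes = {}
        for lo_group in ("orange", "yellow"):
            correct = 0
            for r in rows:
                pred = cc.predict_phenotype(cc.parse_genotype(r.genotype, snp1), snp1)
                observed = r.hue_class
                group = lo_group if observed == "light_orange" else observed
                correct += pred == group
            outcomes[lo_group] = correct
        assert outcomes["orange"] == 51
        assert outcomes["yellow"] != 51


class TestEfficiency:
    def _records(self, spec, marker):
        """spec: list of (call, observed class) tuples."""
        return [
            (cc.parse_genotype(call, marker, f"i{k}"), _pheno(f"i{k}", obs))
            for k, (call, obs) in enumerate(spec)
        ]

    def test_equal_class_sizes_make_weighted_equal_unweighted(self, snp1):
        spec = [("C/C", "yellow"), ("C/C", "yellow"),
                ("C/T", "orange"), ("C/C", "orange")]
        report = cc.efficiency(self._records(spec, snp1), snp1)
        assert report.unweighted_efficiency == 75.0
        assert report.weighted_efficiency == 75.0
        assert report.misclassified_ids == ("i3",)

    def test_weighted_invariant_under_class_duplication(self, snp1):
        spec = [("C/C", "yellow"), ("C/T", "orange"),
                ("C/C", "orange"), ("C/T", "orange")]
        base = cc.efficiency(self._records(spec, snp1), snp1)
        doubled = cc.efficiency(self._records(spec + [("C/C", "yellow")] * 1, snp1), snp1)
        assert base.weighted_fraction == pytest.approx(doubled.weighted_fraction)
        assert base.unweighted_fraction != doubled.unweighted_fraction

    def test_missing_excluded_from_both_terms(self, snp1):
        spec = [("C/C", "yellow"), ("X/X", "orange"), ("C/T", "orange")]
        report = cc.efficiency(self._records(spec, snp1), snp1)
        assert (report.n_total, report.n_scored, report.n_correct) == (3, 2, 2)
        assert report.excluded_ids == ("i1",)
        assert report.unweighted_efficiency == 100.0

    def test_empty_weighted_class_is_an_error(self, snp1):
        spec = [("C/T", "orange"), ("C/T", "orange")]
        with pytest.raises(cc.WeightingError):
            cc.efficiency(self._records(spec, snp1), snp1)

    def test_perfect_iff_no_misclassifications(self, snp1):
        spec = [("C/C", "yellow"), ("C/T", "orange")]
        report = cc.efficiency(self._records(spec, snp1), snp1)
        assert report.unweighted_efficiency == 100.0
        assert report.weighted_efficiency == 100.0
        assert report.misclassified_ids == ()

    def test_weights_must_sum_to_one(self, snp1):
        spec = [("C/C", "yellow"), ("C/T", "orange")]
        with pytest.raises(cc.WeightingError):
            cc.efficiency(self._records(spec, snp1), snp1, weights={"orange": 0.7, "yellow": 0.5})


class TestPanels:
    def test_seedling_population_is_fully_concordant(self, table1, snp1):
        recs = fixture_phenotype_records(table1)
        pairs = [
            (cc.parse_genotype(r.genotype, snp1, r.individual_id), p)
            for r, p in zip(table1.table.itertuples(index=False), recs)
        ]
        report = cc.efficiency(pairs, snp1)
        assert report.n_scored == 40
        assert report.unweighted_efficiency == 100.0

    def test_cultivar_panel_efficiencies(self, table2, snp1):
        recs = fixture_phenotype_records(table2)
        pairs = [
            (cc.parse_genotype(r.genotype, snp1, r.individual_id), p)
            for r, p in zip(table2.table.itertuples(index=False), recs)
        ]
        report = cc.efficiency(pairs, snp1)
        assert (report.n_scored, report.n_correct) == (57, 51)
        assert report.unweighted_efficiency == 89.5
        # recomputation of the 0.5-weighted statistic: 0.5*(10/10) + 0.5*(41/47)
        assert report.weighted_fraction == pytest.approx(0.5 + 0.5 * 41 / 47)
        assert report.weighted_efficiency == 93.6

    def test_rounding_is_half_up_to_one_decimal(self):
        assert cc.round_percent(51 / 57) == 89.5  # 89.47...
        assert cc.round_percent(0.8944) == 89.4
        assert cc.round_percent(0.5) == 50.0
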