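"""Phenotype translation, recommendation lookup and the change report."""

import itertools

import pytest

from pgxrev.call_model import parse_diplotype
from pgxrev.errors import CoverageError, UnknownDrugError, UnknownGeneError
from pgxrev.phenotype_engine import (
    allele_function,
    diplotype_to_phenotype,
    format_percent_one_decimal,
    lookup_recommendation,
    phenotype_change_report,
)
from pgxrev.revision_engine import AlleleClass, Criterion, RevisionRecord

GENE = "SLCO1B1"

GENERIC = "Prescribe desired starting dose and adjust doses based on disease-specific guidelines"

# frozen guideline texts (decreased-function column)
DECREASED_TEXTS = {
    "simvastatin": (
        "Prescribe an alternative statin depending on the desired potency. "
        "If simvastatin therapy is warranted, limit dose to < 20 mg/day"
    ),
    "rosuvastatin": (
        "Prescribe desired starting dose and adjust doses of rosuvastatin based on "
        "disease-specific and specific population guidelines. Prescriber should be "
        "aware of possible increased risk for myopathy especially for doses > 20 mg"
    ),
    "lovastatin": (
        "Prescribe an alternative statin depending on the desired potency. "
        "If lovastatin therapy is warranted, limit dose to ≤ 20 mg/day"
    ),
    "pravastatin": (
        "Prescribe desired starting dose and adjust doses of pravastatin based on "
        "disease-specific guidelines. Prescriber should be aware of possible "
        "increased risk for myopathy with pravastatin especially with doses > 40 mg per day"
    ),
    "atorvastatin": (
        "Prescribe ≤ 40 mg as a starting dose and adjust doses of atorvastatin "
        "based on disease-specific guidelines. Prescriber should be aware of possible "
        "increased risk for myopathy especially for 40 mg dose. If dose > 40 mg needed "
        "for desired efficacy, consider combination therapy (i.e., atorvastatin plus "
        "non-statin guideline directed medical therapy)"
    ),
    "fluvastatin": (
        "Prescribe desired starting dose and adjust doses of fluvastatin based on "
        "disease-specific guidelines. Prescriber should be aware of possible increased "
        "risk for myopathy especially for doses > 40 mg per day"
    ),
    "pitavastatin": (
        "Prescribe ≤ 2 mg as a starting dose and adjust doses of pitavastatin "
        "based on disease-specific guidelines. Prescriber should be aware of possible "
        "increased risk for myopathy especially for doses > 1 mg. If dose > 2 mg "
        "needed for desired efficacy, consider an alternative statin or combination "
        "therapy (i.e., pitavastatin plus non-statin guideline directed medical therapy)"
    ),
}

NORMAL_TEXTS = {
    "simvastatin": GENERIC,
    "rosuvastatin": (
        "Prescribe desired starting dose and adjust doses of rosuvastatin "
        "based on disease-specific and specific population guidelines"
    ),
    "lovastatin": GENERIC,
    "pravastatin": GENERIC,
    "atorvastatin": GENERIC,
    "fluvastatin": (
        "Prescribe desired starting dose and adjust doses of fluvastatin "
        "based on disease-specific guidelines"
    ),
    "pitavastatin": GENERIC,
}


class TestAlleleFunction:
    def test_wildtype_is_normal_function(self, default_function_table):
        assert allele_function(default_function_table, GENE, "*1") == "normal function"

    def test_unknown_allele_is_indeterminate(self, default_function_table):
        assert allele_function(default_function_table, GENE, "*999") == "indeterminate"

    def test_undeclared_gene_rejected(self, default_function_table):
        with pytest.raises(UnknownGeneError):
            allele_function(default_function_table, "NOPE", "*1")


class TestDiplotypeToPhenotype:
    def test_wildtype_pair_is_normal_function(self, default_function_table):
        d = parse_diplotype("*1/*1")
        assert diplotype_to_phenotype(default_function_table, GENE, d) == "Normal function"

    def test_no_function_with_normal_is_decreased(self, default_function_table):
        d = parse_diplotype("*31/*37")
        assert diplotype_to_phenotype(default_function_table, GENE, d) == "Decreased function"

    def test_unknown_allele_propagates_indeterminate(self, default_function_table):
        d = parse_diplotype("*1/*999")
        assert diplotype_to_phenotype(default_function_table, GENE, d) == "Indeterminate"

    def test_order_insensitive_for_all_declared_pairs(self, default_function_table):
        alleles = sorted(default_function_table.functions[GENE])
        for a, b in itertools.combinations(alleles, 2):
            pa = diplotype_to_phenotype(default_function_table, GENE, parse_diplotype(f"{a}/{b}"))
            pb = diplotype_to_phenotype(default_function_table, GENE, parse_diplotype(f"{b}/{a}"))
            assert pa == pb


class TestRecommendations:
    @pytest.mark.parametrize("drug", sorted(NORMAL_TEXTS))
    def test_normal_function_texts_verbatim(self, statin_table, drug):
        text = lookup_recommendation(statin_table, drug, {GENE: "Normal function"})
        assert text == NORMAL_TEXTS[drug]

    @pytest.mark.parametrize("drug", sorted(DECREASED_TEXTS))
    def test_decreased_function_texts_verbatim(self, statin_table, drug):
        text = lookup_recommendation(statin_table, drug, {GENE: "Decreased function"})
        assert text == DECREASED_TEXTS[drug]

    def test_defaults_fill_missing_genes(self, statin_table):
        # rosuvastatin rules require ABCG2; the default profile supplies it
        text = lookup_recommendation(statin_table, "rosuvastatin", {GENE: "Decreased function"})
        assert text == DECREASED_TEXTS["rosuvastatin"]
        explicit = lookup_recommendation(
            statin_table,
            "rosuvastatin",
            {GENE: "Decreased function", "ABCG2": "Normal Metabolizer"},
        )
        assert explicit == text

    def test_lookup_total_over_shipped_phenotypes(self, statin_table):
        for drug in statin_table.drugs():
            for phenotype in ("Normal function", "Decreased function", "Poor function"):
                assert lookup_recommendation(statin_table, drug, {GENE: phenotype})

    def test_unknown_drug_rejected(self, statin_table):
        with pytest.raises(UnknownDrugError):
            lookup_recommendation(statin_table, "aspirin", {GENE: "Normal function"})

    def test_uncovered_profile_rejected(self, statin_table):
        with pytest.raises(CoverageError):
            lookup_recommendation(statin_table, "simvastatin", {GENE: "Hyperactive"})


def record(sample, original, revised, criterion=Criterion.NONE):
    o, r = parse_diplotype(original), parse_diplotype(revised)
    cls = (
        AlleleClass.CONCORDANT,
        AlleleClass.CONCORDANT if o == r else AlleleClass.DISCORDANT,
    )
    return RevisionRecord(sample, GENE, o, r, criterion, cls)


class TestPhenotypeChangeReport:
    def test_three_of_seventy_is_4_3_percent(self, default_function_table):
        records = [record(f"S{i}", "*1/*1", "*1/*1") for i in range(67)]
        records += [
            record(f"A{i}", "*1/*1", "*31/*37", Criterion.C1) for i in range(3)
        ]
        report = phenotype_change_report(records, default_function_table)
        assert report.pct_altered_by_gene[GENE] == "4.3"
        assert sum(r.altered for r in report.rows) == 3

    def test_no_alterations_is_zero(self, default_function_table):
        records = [record(f"S{i}", "*1/*1", "*1/*1") for i in range(10)]
        report = phenotype_change_report(records, default_function_table)
        assert report.pct_altered_by_gene[GENE] == "0.0"

    def test_indeterminate_transitions_not_counted(self, default_function_table):
        # unknown allele -> Normal function: excluded from the altered count
        records = [record("S1", "*1/*999", "*1/*1", Criterion.C4)]
        report = phenotype_change_report(records, default_function_table)
        assert report.pct_altered_by_gene[GENE] == "0.0"
        assert report.rows[0].old_phenotype == "Indeterminate"

    def test_one_decimal_half_up(self):
        assert format_percent_one_decimal(3, 70) == "4.3"
        assert format_percent_one_decimal(1, 16) == "6.3"
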