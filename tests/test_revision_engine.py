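"""Revision criteria, allele classification and dataset-level summaries."""

import pytest

from pgxrev.allele_db import DatabaseVersion, StarAllele, Variant
from pgxrev.call_model import (
    NO_CALL,
    CallMatrix,
    TruthCell,
    format_diplotype,
    parse_diplotype,
)
from pgxrev.revision_engine import (
    AlleleClass,
    Criterion,
    ToolDbRegistry,
    apply_revision_criteria,
    consensus_call,
    majority_diplotype,
    revise_dataset,
    revision_rows,
)

GENE = "SLCO1B1"


def build_db():
    """*5 extends *2; *46 is recent; *9X exists nowhere (obsolete)."""
    v = lambda i: Variant("chr12", 21000000 + i, "G", "A")
    names = {
        "*1": frozenset(),
        "*2": frozenset({v(1)}),
        "*5": frozenset({v(1), v(2)}),
        "*15": frozenset({v(3)}),
        "*31": frozenset({v(4)}),
        "*37": frozenset({v(5)}),
        "*46": frozenset({v(6)}),
    }
    return DatabaseVersion(
        "6.2",
        alleles={GENE: {n: StarAllele(GENE, n, vs) for n, vs in names.items()}},
    )


def registry(names=("*1", "*2", "*5", "*15", "*31", "*37", "*46")):
    known = frozenset(names)
    return ToolDbRegistry(known={t: {GENE: known} for t in ("aldy", "pypgx", "stellarpgx")})


def calls(a, p, s):
    parse = lambda x: NO_CALL if x is None else parse_diplotype(x)
    return {"aldy": parse(a), "pypgx": parse(p), "stellarpgx": parse(s)}


def apply(truth, cell_calls, *, tentative=False, evidence=(), recent=(), db=None,
          reg=None, verified=(), rename_map=None):
    return apply_revision_criteria(
        "S1",
        GENE,
        TruthCell(parse_diplotype(truth), tentative, tuple(evidence)),
        cell_calls,
        db or build_db(),
        reg or registry(),
        recent,
        verified_alleles=verified,
        rename_map=rename_map,
    )


class TestVoting:
    def test_unanimous_consensus(self):
        assert format_diplotype(
            consensus_call(calls("*31/*37", "*31/*37", "*31/*37"))
        ) == "*31/*37"

    def test_not_unanimous(self):
        assert consensus_call(calls("*1/*2", "*1/*5", "*1/*2")) is None

    def test_consensus_ignores_no_calls(self):
        assert format_diplotype(consensus_call(calls(None, "*5/*15", "*5/*15"))) == "*5/*15"

    def test_single_caller_is_not_a_consensus(self):
        assert consensus_call(calls(None, "*5/*15", None)) is None

    def test_all_no_call_is_none(self):
        assert consensus_call(calls(None, None, None)) is None

    def test_majority_two_of_three(self):
        assert format_diplotype(majority_diplotype(calls("*1/*2", "*1/*2", "*1/*5"))) == "*1/*2"

    def test_three_way_split_has_no_majority(self):
        assert majority_diplotype(calls("*1/*2", "*1/*5", "*1/*15")) is None

    def test_single_call_is_a_majority_of_callers(self):
        assert format_diplotype(majority_diplotype(calls("*1/*2", None, None))) == "*1/*2"


class TestCriteria:
    def test_c1_unanimous_consensus_replaces_original(self):
        rec = apply("*1/*1", calls("*31/*37", "*31/*37", "*31/*37"))
        assert rec.criterion == Criterion.C1
        assert format_diplotype(rec.revised) == "*31/*37"
        assert rec.allele_classes == (AlleleClass.DISCORDANT, AlleleClass.DISCORDANT)

    def test_tentative_call_confirmed(self):
        rec = apply("*5/*15", calls("*5/*15", "*5/*15", "*5/*15"), tentative=True)
        assert rec.criterion == Criterion.NONE
        assert format_diplotype(rec.revised) == "*5/*15"
        assert rec.allele_classes == (AlleleClass.CONFIRMED, AlleleClass.CONFIRMED)

    def test_c2_verified_majority(self):
        rec = apply(
            "*1/*2",
            calls("*1/*15", "*1/*15", "*1/*2"),
            verified={(GENE, "*15")},
        )
        assert rec.criterion == Criterion.C2
        assert format_diplotype(rec.revised) == "*1/*15"

    def test_unverified_majority_does_not_fire_c2(self):
        rec = apply("*1/*2", calls("*1/*15", "*1/*15", "*1/*2"))
        assert rec.criterion not in (Criterion.C1, Criterion.C2, Criterion.C3)
        assert rec.revised == rec.original

    def test_c3_extension_substitution(self):
        rec = apply("*1/*2", calls("*1/*5", "*1/*5", "*1/*2"))
        assert rec.criterion == Criterion.C3
        assert format_diplotype(rec.revised) == "*1/*5"
        assert rec.allele_classes == (AlleleClass.CONCORDANT, AlleleClass.DISCORDANT)

    def test_c3_wt_recent_allele_replaces_wildtype(self):
        rec = apply("*1/*1", calls("*1/*46", "*1/*1", "*1/*1"), recent={"*46"})
        assert rec.criterion == Criterion.C3_WT
        assert format_diplotype(rec.revised) == "*1/*46"
        assert rec.allele_classes == (AlleleClass.CONCORDANT, AlleleClass.DISCORDANT)

    def test_c3_wt_needs_recent_membership(self):
        rec = apply("*1/*1", calls("*1/*46", "*1/*1", "*1/*1"), recent=())
        assert rec.criterion != Criterion.C3_WT
        assert rec.revised == rec.original

    def test_c3_wt_rejected_when_third_tool_disagrees(self):
        rec = apply("*1/*1", calls("*1/*46", "*1/*15", "*1/*1"), recent={"*46"})
        assert rec.criterion != Criterion.C3_WT

    def test_c4_obsolete_without_majority_falls_back_to_wildtype(self):
        rec = apply("*1/*9X", calls("*1/*2", "*1/*5", None))
        assert rec.criterion == Criterion.C4
        assert format_diplotype(rec.revised) == "*1/*1"
        assert "obsolete" in rec.notes
        assert AlleleClass.LEGACY in rec.allele_classes

    def test_c4_obsolete_replaced_by_majority(self):
        # majority (not consensus: one dissenter) supplies the replacement
        rec = apply("*1/*9X", calls("*1/*2", "*1/*2", "*1/*5"))
        assert rec.criterion == Criterion.C4
        assert format_diplotype(rec.revised) == "*1/*2"
        assert rec.allele_classes == (AlleleClass.CONCORDANT, AlleleClass.LEGACY)

    def test_c5_ambiguous_calls_retain_original(self):
        rec = apply("*1/*2", calls("*1/*15", "*1/*31", "*1/*37"))
        assert rec.criterion == Criterion.C5
        assert rec.revised == rec.original
        assert rec.allele_classes == (AlleleClass.CONCORDANT, AlleleClass.ORIGINAL)

    def test_unresolvable_when_tool_db_lacks_original(self):
        reg = registry()
        reg.known["aldy"] = {GENE: frozenset({"*1"})}  # aldy does not know *2
        rec = apply("*1/*2", calls("*1/*15", "*1/*31", "*1/*37"), reg=reg)
        assert rec.criterion == Criterion.NONE
        assert rec.revised == rec.original
        assert "unresolvable" in rec.notes

    def test_precedence_c1_beats_c3(self):
        # all tools unanimously call the extension: C1 wins over C3
        rec = apply("*1/*2", calls("*1/*5", "*1/*5", "*1/*5"))
        assert rec.criterion == Criterion.C1
        assert format_diplotype(rec.revised) == "*1/*5"


class TestClassification:
    def test_renamed_allele_is_legacy_even_under_c1(self):
        rec = apply(
            "*1/*2",
            calls("*1/*5", "*1/*5", "*1/*5"),
            rename_map={(GENE, "*2"): "*5"},
        )
        assert rec.criterion == Criterion.C1
        assert rec.allele_classes == (AlleleClass.CONCORDANT, AlleleClass.LEGACY)

    def test_unreproduced_unchanged_allele_is_original(self):
        rec = apply("*2/*15", calls("*1/*31", "*1/*37", None))
        assert rec.revised == rec.original
        assert rec.allele_classes == (AlleleClass.ORIGINAL, AlleleClass.ORIGINAL)


def tiny_matrix(diplotype="*1/*2", n_samples=3):
    samples = [f"S{i}" for i in range(1, n_samples + 1)]
    d = parse_diplotype(diplotype)
    matrix = CallMatrix(samples=samples, genes=[GENE], tools=["aldy", "pypgx", "stellarpgx"])
    for s in samples:
        matrix.truth[(s, GENE)] = TruthCell(d)
        for t in matrix.tools:
            matrix.tool_calls[(s, GENE, t)] = d
    return matrix


class TestReviseDataset:
    def test_no_discrepancies_means_no_updates(self):
        result = revise_dataset(tiny_matrix(), build_db(), registry(), frozenset())
        assert result.summary["n_updated"] == 0
        assert set(result.summary["class_totals"]) == {"concordant"}

    def test_class_counts_sum_to_two_per_cell(self):
        result = revise_dataset(tiny_matrix(n_samples=5), build_db(), registry(), frozenset())
        per_gene = result.summary["per_gene_class_counts"][GENE]
        assert sum(per_gene.values()) == 2 * 5

    def test_deterministic_output(self):
        run = lambda: revision_rows(
            revise_dataset(tiny_matrix(), build_db(), registry(), frozenset()).records
        )
        assert run() == run()

    def test_injected_c1_events_are_counted(self):
        matrix = tiny_matrix(n_samples=4)
        other = parse_diplotype("*31/*37")
        for s in ("S1", "S3"):  # two cells where all tools disagree with truth
            for t in matrix.tools:
                matrix.tool_calls[(s, GENE, t)] = other
        result = revise_dataset(matrix, build_db(), registry(), frozenset())
        assert result.summary["n_updated"] == 2
        assert result.summary["criterion_counts"]["C1"] == 2
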