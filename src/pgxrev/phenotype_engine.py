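"""Diplotype -> phenotype translation and drug recommendation lookup.

Phenotype prediction is a two-stage table lookup: each allele maps to a
function category (normal / decreased / no function, ...), and the
unordered pair of categories maps to a phenotype label.  The mapping ships
as editable data rather than activity-score arithmetic, so local guideline
revisions can be applied without code changes.  Unknown alleles yield the
function category ``indeterminate`` and the phenotype ``Indeterminate``,
which downstream reports exclude from change counts.

Recommendation lookup matches a drug plus a per-gene phenotype profile
against guideline rows (CPIC-style statin/SLCO1B1 tables); genes missing
from the query profile are filled from configured defaults (e.g. CYP2C9
and ABCG2 assumed normal metabolizers for fluvastatin and rosuvastatin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence, TextIO

from .call_model import Diplotype
from .errors import (
    CoverageError,
    ParseError,
    PgxRevError,
    UnknownDrugError,
    UnknownGeneError,
)
from .revision_engine import RevisionRecord

INDETERMINATE_FUNCTION = "indeterminate"
INDETERMINATE_PHENOTYPE = "Indeterminate"


@dataclass(slots=True)
class FunctionTable:
    """Allele -> function and function-pair -> phenotype rules, per gene."""

    functions: dict[str, dict[str, str]] = field(default_factory=dict)
    rules: dict[str, dict[tuple[str, str], str]] = field(default_factory=dict)

    def declared_genes(self) -> list[str]:
        return sorted(self.functions)


def _iter_rows(stream: TextIO | Iterable[str], required: tuple[str, ...]):
    header = None
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            missing = set(required) - set(header)
            if missing:
                raise ParseError(f"missing columns: {sorted(missing)}", line_no)
            continue
        yield line_no, dict(zip(header, fields))


def load_function_table(
    functions_stream: TextIO | Iterable[str],
    rules_stream: TextIO | Iterable[str],
) -> FunctionTable:
    """Load allele-function TSV (gene, allele, function) and phenotype-rule
    TSV (gene, function_a, function_b, phenotype)."""
    ft = FunctionTable()
    for _, row in _iter_rows(functions_stream, ("gene", "allele", "function")):
        ft.functions.setdefault(row["gene"].strip(), {})[row["allele"].strip()] = (
            row["function"].strip()
        )
    for _, row in _iter_rows(rules_stream, ("gene", "function_a", "function_b", "phenotype")):
        key = _pair_key(row["function_a"].strip(), row["function_b"].strip())
        ft.rules.setdefault(row["gene"].strip(), {})[key] = row["phenotype"].strip()
    return ft


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def allele_function(ft: FunctionTable, gene: str, allele_name: str) -> str:
    """Function category of an allele; unknown alleles are indeterminate."""
    if gene not in ft.functions:
        raise UnknownGeneError(f"gene {gene!r} not declared in the function table")
    return ft.functions[gene].get(allele_name, INDETERMINATE_FUNCTION)


def diplotype_to_phenotype(ft: FunctionTable, gene: str, d: Diplotype) -> str:
    """Phenotype label for a diplotype; order-insensitive by construction.

    Copy-number annotations do not alter the function lookup: the category
    is keyed on the core allele name.
    """
    f1 = allele_function(ft, gene, d.first.core_name)
    f2 = allele_function(ft, gene, d.second.core_name)
    if INDETERMINATE_FUNCTION in (f1, f2):
        return INDETERMINATE_PHENOTYPE
    key = _pair_key(f1, f2)
    rules = ft.rules.get(gene, {})
    if key not in rules:
        raise CoverageError(
            f"no phenotype rule for gene {gene!r} and function pair {key!r}"
        )
    return rules[key]


# ---------------------------------------------------------------------------
# recommendation lookup
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class RecommendationTable:
    """Guideline texts keyed by drug and per-gene phenotype profile.

    ``rules[drug]`` is a list of (profile, text) pairs; a profile is a
    gene -> phenotype mapping that must be satisfied by the (default-
    completed) query profile.  The most specific matching rule wins.
    """

    rules: dict[str, list[tuple[dict[str, str], str]]] = field(default_factory=dict)
    default_profiles: dict[str, str] = field(default_factory=dict)

    def drugs(self) -> list[str]:
        return sorted(self.rules)


def load_recommendation_table(
    stream: TextIO | Iterable[str],
    defaults_stream: TextIO | Iterable[str] | None = None,
) -> RecommendationTable:
    """Load recommendation TSV (drug, profile, recommendation) plus an
    optional defaults TSV (gene, phenotype).

    The profile column holds semicolon-separated ``GENE:Phenotype`` pairs.
    """
    rt = RecommendationTable()
    for line_no, row in _iter_rows(stream, ("drug", "profile", "recommendation")):
        profile: dict[str, str] = {}
        for pair in row["profile"].split(";"):
            pair = pair.strip()
            if not pair:
                continue
            if ":" not in pair:
                raise ParseError(f"profile entry {pair!r} is not GENE:Phenotype", line_no)
            gene, phenotype = pair.split(":", 1)
            profile[gene.strip()] = phenotype.strip()
        if not row["recommendation"].strip():
            raise ParseError("empty recommendation text", line_no)
        rt.rules.setdefault(row["drug"].strip(), []).append(
            (profile, row["recommendation"].strip())
        )
    if defaults_stream is not None:
        for _, row in _iter_rows(defaults_stream, ("gene", "phenotype")):
            rt.default_profiles[row["gene"].strip()] = row["phenotype"].strip()
    return rt


def lookup_recommendation(
    rt: RecommendationTable, drug: str, profile: Mapping[str, str]
) -> str:
    """Guideline text for a drug and phenotype profile.

    Genes configured in ``default_profiles`` but absent from the query are
    filled in before matching; the stored text is returned verbatim.
    """
    if drug not in rt.rules:
        raise UnknownDrugError(f"drug {drug!r} not declared in the recommendation table")
    completed = dict(rt.default_profiles)
    completed.update(profile)
    best: tuple[int, str] | None = None
    for rule_profile, text in rt.rules[drug]:
        if all(completed.get(g) == ph for g, ph in rule_profile.items()):
            if best is None or len(rule_profile) > best[0]:
                best = (len(rule_profile), text)
    if best is None:
        raise CoverageError(
            f"no recommendation rule for drug {drug!r} matches profile {dict(completed)!r}"
        )
    return best[1]


# ---------------------------------------------------------------------------
# phenotype change report
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class PhenotypeChange:
    sample: str
    gene: str
    old_phenotype: str
    new_phenotype: str
    altered: bool


@dataclass(slots=True)
class PhenotypeChangeReport:
    rows: list[PhenotypeChange]
    pct_altered_by_gene: dict[str, str]


def format_percent_one_decimal(count: int, total: int) -> str:
    """Percentage with one decimal, half-up (3/70 -> ``4.3``)."""
    if total <= 0:
        raise PgxRevError(f"total must be positive, got {total}")
    value = Decimal(count) * 100 / Decimal(total)
    return str(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def phenotype_change_report(
    records: Sequence[RevisionRecord], ft: FunctionTable
) -> PhenotypeChangeReport:
    """Old vs new phenotype per sample and gene, with per-gene altered rates.

    A sample counts as altered for a gene iff the phenotypes differ and
    neither is Indeterminate.  Only genes declared in the function table
    are reported.
    """
    rows: list[PhenotypeChange] = []
    altered: dict[str, int] = {}
    totals: dict[str, int] = {}
    for rec in records:
        if rec.gene not in ft.functions:
            continue
        old = diplotype_to_phenotype(ft, rec.gene, rec.original)
        new = diplotype_to_phenotype(ft, rec.gene, rec.revised)
        is_altered = (
            old != new
            and old != INDETERMINATE_PHENOTYPE
            and new != INDETERMINATE_PHENOTYPE
        )
        rows.append(PhenotypeChange(rec.sample, rec.gene, old, new, is_altered))
        totals[rec.gene] = totals.get(rec.gene, 0) + 1
        if is_altered:
            altered[rec.gene] = altered.get(rec.gene, 0) + 1
    pct = {
        gene: format_percent_one_decimal(altered.get(gene, 0), totals[gene])
        for gene in sorted(totals)
    }
    return PhenotypeChangeReport(rows=rows, pct_altered_by_gene=pct)
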