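"""Shipped lookup tables: SLCO1B1 function/phenotype rules and statin
recommendation texts (CPIC-style), plus the default phenotype profiles.

The per-allele function assignments and the "Poor function" recommendation
rows are synthetic fixture entries; see the comments inside each TSV.
"""

from __future__ import annotations

from importlib import resources

from ..phenotype_engine import (
    FunctionTable,
    RecommendationTable,
    load_function_table,
    load_recommendation_table,
)

_PKG = resources.files(__name__)


def _open(name: str):
    return (_PKG / name).open("r", encoding="utf-8")


def load_default_function_table() -> FunctionTable:
    """The shipped SLCO1B1 allele-function and phenotype-rule tables."""
    with _open("slco1b1_functions.tsv") as fn, _open("slco1b1_phenotype_rules.tsv") as rules:
        return load_function_table(fn, rules)


def load_statin_recommendations() -> RecommendationTable:
    """The shipped statin recommendation table with default profiles."""
    with _open("statin_recommendations.tsv") as rec, _open("default_profiles.tsv") as dflt:
        return load_recommendation_table(rec, dflt)
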