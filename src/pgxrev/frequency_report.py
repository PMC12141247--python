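"""Cohort allele frequencies and reporting of previously unreported alleles.

Each diplotype contributes two chromosome observations per gene, so with N
samples every gene's counts sum to 2N.  Copy-number calls are reported as
their own rows (``*1x2`` separate from ``*1``), each occupying exactly one
diplotype slot, which keeps the per-gene total at 2N.

Percentages are rendered with two decimals below 10% and one decimal at or
above 10%, with half-up rounding — the convention used in published
pharmacogene frequency tables (0.71, 1.43, ..., 15.0, 17.9).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .call_model import Diplotype
from .errors import CompletenessError, PgxRevError


@dataclass(frozen=True, slots=True)
class FrequencyRow:
    """One allele's occurrence count and formatted cohort frequency."""

    gene: str
    allele: str
    count: int
    percent: str


def format_percent(count: int, n_chromosomes: int) -> str:
    """Render ``count / n_chromosomes`` as a percentage string.

    Two decimals below 10%, one decimal at/above 10%, half-up rounding.
    """
    if n_chromosomes <= 0:
        raise PgxRevError(f"n_chromosomes must be positive, got {n_chromosomes}")
    if not 0 <= count <= n_chromosomes:
        raise PgxRevError(f"count {count} outside [0, {n_chromosomes}]")
    value = Decimal(count) * 100 / Decimal(n_chromosomes)
    quantum = Decimal("0.01") if value < 10 else Decimal("0.1")
    return str(value.quantize(quantum, rounding=ROUND_HALF_UP))


def allele_sort_key(label: str) -> tuple:
    """Numeric-first ordering for allele labels (``*2`` before ``*10``)."""
    m = re.match(r"\*(\d+)", label)
    return (int(m.group(1)) if m else 10**9, label)


def allele_frequencies(
    call_set: Mapping[tuple[str, str], Diplotype], gene: str
) -> list[FrequencyRow]:
    """Frequency rows for one gene over a ``(sample, gene) -> Diplotype`` map.

    Every sample present in the map must have a call for *gene*.
    """
    samples = sorted({s for s, _ in call_set})
    counts: dict[str, int] = {}
    for sample in samples:
        if (sample, gene) not in call_set:
            raise CompletenessError(f"sample {sample!r} has no call for gene {gene!r}")
        d = call_set[(sample, gene)]
        for allele in d.alleles:
            counts[allele.label] = counts.get(allele.label, 0) + 1
    n_chromosomes = 2 * len(samples)
    return [
        FrequencyRow(gene, label, counts[label], format_percent(counts[label], n_chromosomes))
        for label in sorted(counts, key=allele_sort_key)
    ]


def novel_allele_report(
    freqs: Iterable[FrequencyRow], baseline: Iterable[tuple[str, str]]
) -> list[FrequencyRow]:
    """Rows whose (gene, allele) was absent from the baseline call set.

    The baseline is the set of alleles previously reported by the reference
    material; copy-number labels compare as written (``*1x2`` is novel if
    only ``*1`` was reported).
    """
    baseline_set = frozenset(baseline)
    rows = [row for row in freqs if (row.gene, row.allele) not in baseline_set]
    return sorted(rows, key=lambda r: (r.gene, allele_sort_key(r.allele)))
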