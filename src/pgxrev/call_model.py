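"""Diplotype call parsing, canonicalisation and the cohort call matrix.

A diplotype is an unordered pair of allele calls, e.g. ``*31/*37``.  Each
allele call carries a core star-allele name plus an integer copy number
taken from an ``xN`` suffix (``*1x2`` = two tandem copies of ``*1``).
Sub-allele suffixes (``*5.001``) are stripped during parsing, matching how
core alleles are counted throughout the package.

Canonical ordering puts the allele with the smaller numeric part first
(``*2`` before ``*10``), breaking ties by full label and then copy number,
so order-insensitive equality coincides with textual equality of the
canonical form.

``NO_CALL`` is an explicit state distinct from a wild-type call: a caller
that produced no result is treated differently from one that called
``*1/*1``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO, Union

from .errors import CompletenessError, ParseError

logger = logging.getLogger(__name__)


class _NoCall:
    """Singleton sentinel for a tool that produced no call."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_CALL"

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


NO_CALL = _NoCall()

Call = Union["Diplotype", _NoCall]

# core = digits plus optional letter suffix ("*2A", "*9X"); ".sub" is the
# sub-allele component; lowercase "x<digits>" at the end is a copy number.
_ALLELE_RE = re.compile(r"^\*(\d+[A-Za-z]*?)(?:\.([0-9A-Za-z]+))?(?:x(\d+))?$")


@dataclass(frozen=True, slots=True)
class AlleleCall:
    """One called allele: core name plus copy number (default 1)."""

    core_name: str
    copy_number: int = 1

    def __post_init__(self) -> None:
        if not self.core_name.startswith("*"):
            raise ParseError(f"allele name must begin with '*', got {self.core_name!r}")
        if "." in self.core_name:
            raise ParseError(f"core allele name may not contain '.': {self.core_name!r}")
        if self.copy_number < 1:
            raise ParseError(f"copy number must be >= 1, got {self.copy_number}")

    @property
    def label(self) -> str:
        return self.core_name if self.copy_number == 1 else f"{self.core_name}x{self.copy_number}"

    def sort_key(self) -> tuple:
        m = re.match(r"\*(\d+)", self.core_name)
        numeric = int(m.group(1)) if m else 10**9
        return (numeric, self.core_name, self.copy_number)


def parse_allele_call(text: str) -> AlleleCall:
    """Parse one allele token, stripping any sub-allele suffix."""
    token = text.strip()
    if not token.startswith("*"):
        raise ParseError(f"allele token must begin with '*', got {token!r}")
    m = _ALLELE_RE.match(token)
    if not m:
        raise ParseError(f"malformed allele token {token!r}")
    core, _sub, cn = m.groups()
    copy_number = int(cn) if cn is not None else 1
    if copy_number < 1:
        raise ParseError(f"copy number must be >= 1 in {token!r}")
    return AlleleCall(core_name=f"*{core}", copy_number=copy_number)


@dataclass(frozen=True, slots=True)
class Diplotype:
    """An unordered pair of allele calls, stored in canonical order."""

    first: AlleleCall
    second: AlleleCall

    def __post_init__(self) -> None:
        if self.second.sort_key() < self.first.sort_key():
            first, second = self.second, self.first
            object.__setattr__(self, "first", first)
            object.__setattr__(self, "second", second)

    @property
    def alleles(self) -> tuple[AlleleCall, AlleleCall]:
        return (self.first, self.second)

    def core_names(self) -> frozenset[str]:
        return frozenset((self.first.core_name, self.second.core_name))

    def contains(self, allele: AlleleCall) -> bool:
        return allele == self.first or allele == self.second

    def __str__(self) -> str:
        return format_diplotype(self)


def parse_diplotype(text: str) -> Diplotype:
    """Parse ``"<allele>/<allele>"`` into a canonical :class:`Diplotype`.

    Some callers emit several candidate diplotypes separated by ``;``; the
    first candidate is taken and a warning logged.
    """
    s = text.strip()
    if ";" in s:
        first, rest = s.split(";", 1)
        logger.warning("multiple candidate diplotypes %r; taking first candidate %r", s, first)
        s = first.strip()
    if s.count("/") != 1:
        raise ParseError(f"diplotype must contain exactly one '/', got {text!r}")
    left, right = s.split("/")
    return Diplotype(parse_allele_call(left), parse_allele_call(right))


def format_diplotype(d: Diplotype) -> str:
    """Canonical text form; ``parse_diplotype(format_diplotype(d)) == d``."""
    return f"{d.first.label}/{d.second.label}"


def diplotypes_equal(a: Diplotype, b: Diplotype) -> bool:
    """Order-insensitive equality on (core name, copy number) multisets."""
    return a == b


@dataclass(frozen=True, slots=True)
class TruthCell:
    """One ground-truth/consensus cell: diplotype, tentative flag, evidence tags.

    Evidence tags are free-form tokens (e.g. ``benchmark:H``) carrying the
    "verified through other sources" signal that cannot be computed.
    """

    diplotype: Diplotype
    tentative: bool = False
    evidence: tuple[str, ...] = ()


@dataclass(slots=True)
class CallMatrix:
    """Truth plus per-tool diplotype calls for every sample x gene cell."""

    samples: list[str]
    genes: list[str]
    tools: list[str]
    truth: dict[tuple[str, str], TruthCell] = field(default_factory=dict)
    tool_calls: dict[tuple[str, str, str], Call] = field(default_factory=dict)

    def cell_calls(self, sample: str, gene: str) -> dict[str, Call]:
        return {
            tool: self.tool_calls.get((sample, gene, tool), NO_CALL) for tool in self.tools
        }

    def validate(self) -> None:
        for sample in self.samples:
            for gene in self.genes:
                if (sample, gene) not in self.truth:
                    raise CompletenessError(f"missing truth entry for ({sample}, {gene})")


# ---------------------------------------------------------------------------
# TSV I/O
#
# Truth TSV columns:  sample, gene, diplotype, tentative (T/F), evidence
# (comma-separated tags, optional).
# Tool TSV columns:   sample, gene, diplotype  ('.' or empty = NO_CALL).
# '#'-prefixed lines are comments.
# ---------------------------------------------------------------------------


def _read_rows(stream: TextIO | Iterable[str], required: tuple[str, ...]):
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


def load_call_matrix(
    truth_stream: TextIO | Iterable[str],
    tool_streams: Mapping[str, TextIO | Iterable[str]],
) -> CallMatrix:
    """Assemble a :class:`CallMatrix` from a truth table and per-tool tables.

    Absent tool rows become ``NO_CALL``; a tool row for a cell with no
    truth entry raises :class:`~pgxrev.errors.CompletenessError`.
    """
    truth: dict[tuple[str, str], TruthCell] = {}
    for line_no, row in _read_rows(truth_stream, ("sample", "gene", "diplotype")):
        sample, gene = row["sample"].strip(), row["gene"].strip()
        try:
            diplotype = parse_diplotype(row["diplotype"])
        except ParseError as exc:
            raise ParseError(f"truth cell ({sample}, {gene}): {exc}", line_no) from None
        tentative = row.get("tentative", "F").strip().upper() in ("T", "TRUE", "1")
        evidence = tuple(
            tag.strip() for tag in row.get("evidence", "").split(",") if tag.strip()
        )
        truth[(sample, gene)] = TruthCell(diplotype, tentative, evidence)

    tools = sorted(tool_streams)
    tool_calls: dict[tuple[str, str, str], Call] = {}
    for tool in tools:
        for line_no, row in _read_rows(tool_streams[tool], ("sample", "gene", "diplotype")):
            sample, gene = row["sample"].strip(), row["gene"].strip()
            if (sample, gene) not in truth:
                raise CompletenessError(
                    f"tool {tool!r} line {line_no}: no truth entry for ({sample}, {gene})"
                )
            text = row["diplotype"].strip()
            if not text or text == ".":
                tool_calls[(sample, gene, tool)] = NO_CALL
                continue
            try:
                tool_calls[(sample, gene, tool)] = parse_diplotype(text)
            except ParseError as exc:
                raise ParseError(
                    f"tool {tool!r} cell ({sample}, {gene}): {exc}", line_no
                ) from None

    samples = sorted({s for s, _ in truth})
    genes = sorted({g for _, g in truth})
    matrix = CallMatrix(samples=samples, genes=genes, tools=tools,
                        truth=truth, tool_calls=tool_calls)
    matrix.validate()
    return matrix
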