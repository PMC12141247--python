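"""Versioned star-allele definition databases.

A star allele is a named haplotype of a pharmacogene defined by a set of
*core variants*.  Nomenclature databases (PharmVar-style) publish these
definitions in versioned releases: alleles are added, renamed and retired
over time, and sub-alleles (``*2.001``) refine a core allele (``*2``) with
benign variation.  This module models one release (:class:`DatabaseVersion`)
and the operations the rest of the package needs: loading definition tables
with sub-allele collapsing, looking up core-variant sets, and the
"extends" relation between alleles (superset of core variants).

Variant coordinates are 1-based VCF-style tokens (``chrom:pos:ref:alt``)
and are compared token-exact; no normalisation or left-alignment is done,
because alleles are compared by definition identity, not variant semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

from .errors import (
    ConflictError,
    FormatError,
    ParseError,
    UnknownAlleleError,
    UnknownGeneError,
)

_BASES = re.compile(r"^[ACGT]+$")

DEFAULT_WILDTYPE = "*1"


@dataclass(frozen=True, slots=True)
class Variant:
    """A single defining variant in 1-based coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if not _BASES.match(self.ref) or not _BASES.match(self.alt):
            raise FormatError(
                f"ref/alt must be non-empty ACGT strings, got {self.ref!r}/{self.alt!r}"
            )
        if self.ref == self.alt:
            raise FormatError(f"ref equals alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def token(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def parse_variant_token(token: str, line: int | None = None) -> Variant:
    """Parse a ``chrom:pos:ref:alt`` token into a :class:`Variant`."""
    parts = token.strip().split(":")
    if len(parts) != 4:
        raise ParseError(f"expected chrom:pos:ref:alt, got {token!r}", line)
    chrom, pos_s, ref, alt = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise ParseError(f"non-integer position in variant token {token!r}", line) from None
    try:
        return Variant(chrom, pos, ref, alt)
    except FormatError as exc:
        raise ParseError(f"invalid variant token {token!r}: {exc}", line) from None


@dataclass(frozen=True, slots=True)
class StarAllele:
    """A core star allele: name, defining variant set and optional function.

    The designated wild-type allele of a gene has an empty variant set.
    Copy-number suffixes (``x2``) are not part of allele names here; they
    are call-level annotations handled by :mod:`pgxrev.call_model`.
    """

    gene: str
    name: str
    core_variants: frozenset[Variant] = frozenset()
    function: str | None = None

    def __post_init__(self) -> None:
        if not self.name.startswith("*"):
            raise FormatError(f"allele name must begin with '*', got {self.name!r}")
        if "." in self.name:
            raise FormatError(
                f"core allele name may not contain a sub-allele suffix: {self.name!r}"
            )


def strip_suballele(allele_name: str) -> str:
    """Collapse a sub-allele name onto its core allele (``*1.001`` -> ``*1``).

    Idempotent; names without a ``.`` component are returned unchanged.
    """
    if not allele_name.startswith("*"):
        raise FormatError(f"allele name must begin with '*', got {allele_name!r}")
    return allele_name.split(".", 1)[0]


def version_key(label: str) -> tuple:
    """Sort key for dotted version labels like ``1.1.9.2``.

    Numeric components order numerically and before non-numeric ones;
    non-numeric components order lexicographically.
    """
    key = []
    for comp in str(label).split("."):
        if comp.isdigit():
            key.append((0, int(comp), ""))
        else:
            key.append((1, 0, comp))
    return tuple(key)


@dataclass(slots=True)
class DatabaseVersion:
    """One release of a star-allele definition database.

    ``alleles`` maps gene -> {allele name -> :class:`StarAllele`};
    ``excluded_genes`` are omitted from counting/diffing (e.g. genes whose
    variants should be described with HGVS nomenclature instead of star
    alleles); ``wildtype_names`` overrides the default ``*1`` per gene.
    """

    version_label: str
    alleles: dict[str, dict[str, StarAllele]] = field(default_factory=dict)
    excluded_genes: frozenset[str] = frozenset()
    wildtype_names: dict[str, str] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def genes(self) -> list[str]:
        return sorted(self.alleles)

    def counted_genes(self) -> list[str]:
        return sorted(g for g in self.alleles if g not in self.excluded_genes)

    def allele_names(self, gene: str) -> frozenset[str]:
        self._require_gene(gene)
        return frozenset(self.alleles[gene])

    def gene_alleles(self, gene: str) -> Iterator[StarAllele]:
        self._require_gene(gene)
        return iter(self.alleles[gene].values())

    def has_gene(self, gene: str) -> bool:
        return gene in self.alleles

    def has_allele(self, gene: str, allele_name: str) -> bool:
        return gene in self.alleles and allele_name in self.alleles[gene]

    def get_allele(self, gene: str, allele_name: str) -> StarAllele:
        self._require_gene(gene)
        try:
            return self.alleles[gene][allele_name]
        except KeyError:
            raise UnknownAlleleError(
                f"allele {allele_name!r} not defined for gene {gene!r} "
                f"in version {self.version_label}"
            ) from None

    def wildtype_name(self, gene: str) -> str:
        return self.wildtype_names.get(gene, DEFAULT_WILDTYPE)

    def _require_gene(self, gene: str) -> None:
        if gene not in self.alleles:
            raise UnknownGeneError(
                f"gene {gene!r} not present in version {self.version_label}"
            )


def core_variant_set(db: DatabaseVersion, gene: str, allele_name: str) -> frozenset[Variant]:
    """The stored defining-variant set; empty for the wild-type allele."""
    return db.get_allele(gene, allele_name).core_variants


def is_extension_of(db: DatabaseVersion, gene: str, allele_a: str, allele_b: str) -> bool:
    """True iff ``allele_a``'s core variants are a superset of ``allele_b``'s.

    Self-extension is excluded by the name-inequality clause.  Any named
    allele with at least one variant extends the wild-type allele (whose
    defining set is empty).
    """
    if allele_a == allele_b:
        return False
    va = core_variant_set(db, gene, allele_a)
    vb = core_variant_set(db, gene, allele_b)
    return va >= vb


# ---------------------------------------------------------------------------
# definition-table I/O
#
# TSV columns: gene, allele, variants, function (optional).  ``variants`` is
# a semicolon-separated list of chrom:pos:ref:alt tokens; an empty field
# denotes the wild-type allele.  Lines starting with '#' are comments.
# ---------------------------------------------------------------------------

_COLUMNS = ("gene", "allele", "variants", "function")


def load_allele_definitions(
    stream: TextIO | Iterable[str],
    version_label: str,
    *,
    excluded_genes: Iterable[str] = (),
    wildtype_names: Mapping[str, str] | None = None,
) -> DatabaseVersion:
    """Load one definition table into a :class:`DatabaseVersion`.

    Sub-allele rows are collapsed onto their core allele; the first core
    definition wins, and a later row for the same core with a *different*
    variant set raises :class:`~pgxrev.errors.ConflictError` (identical
    duplicates merge silently).
    """
    db = DatabaseVersion(
        version_label=version_label,
        excluded_genes=frozenset(excluded_genes),
        wildtype_names=dict(wildtype_names or {}),
    )
    header: list[str] | None = None
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            missing = {"gene", "allele", "variants"} - set(header)
            if missing:
                raise ParseError(
                    f"definition table header missing columns: {sorted(missing)}", line_no
                )
            continue
        row = dict(zip(header, fields))
        gene = row.get("gene", "").strip()
        allele = row.get("allele", "").strip()
        if not gene or not allele:
            raise ParseError("row missing gene or allele", line_no)
        try:
            core = strip_suballele(allele)
        except FormatError as exc:
            raise ParseError(str(exc), line_no) from None
        variants_field = row.get("variants", "").strip()
        variants = frozenset(
            parse_variant_token(tok, line_no)
            for tok in variants_field.split(";")
            if tok.strip()
        )
        function = row.get("function", "").strip() or None

        gene_map = db.alleles.setdefault(gene, {})
        if core in gene_map:
            existing = gene_map[core]
            if existing.core_variants != variants and "." not in allele:
                raise ConflictError(
                    f"line {line_no}: duplicate core allele {gene} {core} "
                    f"with conflicting variant sets"
                )
            # sub-allele rows collapse onto the first core definition
            continue
        gene_map[core] = StarAllele(gene=gene, name=core, core_variants=variants, function=function)
    return db


def serialize_allele_definitions(db: DatabaseVersion) -> str:
    """Render a :class:`DatabaseVersion` back to definition-table TSV."""
    lines = [f"# pgxrev allele definitions, version {db.version_label}"]
    lines.append("\t".join(_COLUMNS))
    for gene in db.genes():
        for name in sorted(db.alleles[gene], key=_allele_name_key):
            allele = db.alleles[gene][name]
            variants = ";".join(
                v.token
                for v in sorted(allele.core_variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
            )
            lines.append("\t".join([gene, name, variants, allele.function or ""]))
    return "\n".join(lines) + "\n"


def _allele_name_key(name: str) -> tuple:
    m = re.match(r"\*(\d+)", name)
    return (int(m.group(1)) if m else 10**9, name)


def load_history(
    directory: str | Path,
    *,
    excluded_genes: Iterable[str] = (),
    wildtype_names: Mapping[str, str] | None = None,
) -> list[DatabaseVersion]:
    """Load every ``<version_label>.tsv`` in *directory*, sorted by version.

    The file stem is the version label.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"), key=lambda p: version_key(p.stem))
    versions = []
    for path in paths:
        with open(path, encoding="utf-8") as fh:
            versions.append(
                load_allele_definitions(
                    fh,
                    path.stem,
                    excluded_genes=excluded_genes,
                    wildtype_names=wildtype_names,
                )
            )
    return versions
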