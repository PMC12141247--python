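"""Multi-caller diplotype revision and five-way allele classification.

Ground-truth (consensus reference material) diplotypes age as star-allele
nomenclature evolves.  Given the calls of several independent star-allele
callers, the current definition database, each tool's known-allele
registry and the set of recently added alleles, every sample x gene cell
is revised by the first applicable criterion, in fixed order:

C1    all callers that produced a call (at least two) agree on a diplotype
      that differs from the original: accept the consensus.
C2    a strict majority of callers agrees on a diplotype whose novel
      allele(s) are externally verified (evidence tags on the truth row or
      a supplied verification list): accept the majority call.
C3    the majority call substitutes allele(s) that *extend* the original
      allele(s) (their core-variant set is a superset): apply the
      substitution per allele, preserving the partner allele.
C3_WT the original allele is wild-type, at least one caller reports a
      recently added allele and every other caller reports either the
      wild-type or that same allele (outdated tool databases): substitute
      the new allele.
C4    an original allele is obsolete (absent from the current definition
      version): replace it with the majority-called counterpart, falling
      back to wild-type with an explicit note.
C5    no consensus emerged, but every tool's database contains the
      original alleles: retain the experimentally observed original.

If nothing fires and some tool database lacks the original allele, the
cell is retained with an "unresolvable" note (criterion NONE).  Cells
where the consensus simply confirms the original are criterion NONE; a
tentative original confirmed by at least two callers is noted as such.

Each allele of the revised diplotype then receives exactly one class:
ORIGINAL (unchanged, not independently reproduced), CONFIRMED (unchanged,
initially tentative, reproduced by >= 2 callers), CONCORDANT (unchanged,
reproduced by >= 2 callers), LEGACY (changed through nomenclature
turnover: renaming or obsolescence), DISCORDANT (changed because callers
disagree with the original).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

from .allele_db import DatabaseVersion, is_extension_of
from .call_model import (
    NO_CALL,
    AlleleCall,
    Call,
    CallMatrix,
    Diplotype,
    TruthCell,
    format_diplotype,
)
from .errors import ParseError, UnknownGeneError
from .frequency_report import format_percent


class AlleleClass(str, Enum):
    ORIGINAL = "original"
    CONFIRMED = "confirmed"
    CONCORDANT = "concordant"
    LEGACY = "legacy"
    DISCORDANT = "discordant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Criterion(str, Enum):
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C3_WT = "C3_WT"
    C4 = "C4"
    C5 = "C5"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: criteria that change the call (C5/NONE retain the original)
REVISING_CRITERIA = frozenset({Criterion.C1, Criterion.C2, Criterion.C3,
                               Criterion.C3_WT, Criterion.C4})


@dataclass(frozen=True, slots=True)
class RevisionRecord:
    """Outcome of revising one sample x gene cell."""

    sample: str
    gene: str
    original: Diplotype
    revised: Diplotype
    criterion: Criterion
    allele_classes: tuple[AlleleClass, AlleleClass]
    notes: str = ""

    @property
    def updated(self) -> bool:
        return self.revised != self.original


@dataclass(slots=True)
class ToolDbRegistry:
    """Which allele names each calling tool knows, per gene."""

    known: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    @property
    def tools(self) -> list[str]:
        return sorted(self.known)

    def knows(self, tool: str, gene: str, allele_name: str) -> bool:
        return allele_name in self.known.get(tool, {}).get(gene, frozenset())

    def digest(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for tool in self.tools:
            for gene in sorted(self.known[tool]):
                h.update(
                    f"{tool}\t{gene}\t{','.join(sorted(self.known[tool][gene]))}\n".encode()
                )
        return h.hexdigest()[:16]


def load_tool_registry(stream: TextIO | Iterable[str]) -> ToolDbRegistry:
    """Read a tool-database TSV: columns tool, gene, alleles (semicolon-sep)."""
    reg = ToolDbRegistry()
    header = None
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            if not {"tool", "gene", "alleles"} <= set(header):
                raise ParseError("tool-db table needs columns tool, gene, alleles", line_no)
            continue
        row = dict(zip(header, fields))
        names = frozenset(a.strip() for a in row["alleles"].split(";") if a.strip())
        reg.known.setdefault(row["tool"].strip(), {})[row["gene"].strip()] = names
    return reg


# ---------------------------------------------------------------------------
# voting primitives
# ---------------------------------------------------------------------------


def consensus_call(cell_calls: Mapping[str, Call]) -> Diplotype | None:
    """Unanimous diplotype among callers that called; needs >= 2 callers.

    A single caller cannot form a consensus — this keeps one outdated tool
    from rewriting the reference on its own.
    """
    called = [c for c in cell_calls.values() if c is not NO_CALL]
    if len(called) < 2:
        return None
    if all(c == called[0] for c in called[1:]):
        return called[0]
    return None


def majority_diplotype(cell_calls: Mapping[str, Call]) -> Diplotype | None:
    """The diplotype called by a strict majority of callers that called."""
    called = [c for c in cell_calls.values() if c is not NO_CALL]
    if not called:
        return None
    top, n = Counter(called).most_common(1)[0]
    return top if 2 * n > len(called) else None


# ---------------------------------------------------------------------------
# allele alignment between original and revised diplotypes
# ---------------------------------------------------------------------------


def _align(
    revised: Diplotype, original: Diplotype, db: DatabaseVersion, gene: str
) -> list[tuple[AlleleCall, AlleleCall]]:
    """Pair each revised allele (in canonical slot order) with an original.

    Matching preference: identical allele call, then identical core name,
    then the extension relation, then position.  Deterministic for every
    input, which keeps per-allele classification reproducible under
    substitutions.
    """
    rev = list(revised.alleles)
    orig = list(original.alleles)
    assigned: list[AlleleCall | None] = [None, None]
    used = [False, False]

    def match(predicate) -> None:
        for i, r in enumerate(rev):
            if assigned[i] is not None:
                continue
            for j, o in enumerate(orig):
                if not used[j] and predicate(r, o):
                    assigned[i] = o
                    used[j] = True
                    break

    match(lambda r, o: r == o)
    match(lambda r, o: r.core_name == o.core_name)
    match(lambda r, o: _extends(db, gene, r.core_name, o.core_name))
    for i in range(2):
        if assigned[i] is None:
            j = used.index(False)
            assigned[i] = orig[j]
            used[j] = True
    return [(rev[0], assigned[0]), (rev[1], assigned[1])]


def _extends(db: DatabaseVersion, gene: str, a: str, b: str) -> bool:
    """Extension check that treats alleles absent from *db* as non-extending."""
    if not (db.has_allele(gene, a) and db.has_allele(gene, b)):
        return False
    return is_extension_of(db, gene, a, b)


# ---------------------------------------------------------------------------
# criterion evaluation for one cell
# ---------------------------------------------------------------------------


def apply_revision_criteria(
    sample: str,
    gene: str,
    truth_cell: TruthCell,
    cell_calls: Mapping[str, Call],
    current_db: DatabaseVersion,
    tool_dbs: ToolDbRegistry,
    recent_alleles: Iterable[str],
    *,
    verified_alleles: Iterable[tuple[str, str]] = (),
    rename_map: Mapping[tuple[str, str], str] | None = None,
) -> RevisionRecord:
    """Evaluate criteria C1..C5 in order for one cell and classify alleles."""
    if not current_db.has_gene(gene):
        raise UnknownGeneError(f"gene {gene!r} absent from version {current_db.version_label}")
    recent = frozenset(recent_alleles)
    verified = frozenset(verified_alleles)
    rename_map = dict(rename_map or {})
    original = truth_cell.diplotype
    orig_cores = {a.core_name for a in original.alleles}

    cons = consensus_call(cell_calls)
    maj = majority_diplotype(cell_calls)
    criterion: Criterion | None = None
    revised: Diplotype = original
    notes: list[str] = []

    # C1: unanimous consensus differing from the original
    if cons is not None and cons != original:
        criterion, revised = Criterion.C1, cons
        notes.append("consensus of all callers")

    # C2: verified majority call / C3: extension substitution
    if criterion is None and maj is not None and maj != original:
        novel = [a for a in maj.alleles if a.core_name not in orig_cores]
        if novel and all(
            truth_cell.evidence or (gene, a.core_name) in verified for a in novel
        ):
            criterion, revised = Criterion.C2, maj
            notes.append("majority call with external verification")
        else:
            pairs = _align(maj, original, current_db, gene)
            diffs = [(r, o) for r, o in pairs if r != o]
            if diffs and all(
                _extends(current_db, gene, r.core_name, o.core_name) for r, o in diffs
            ):
                criterion, revised = Criterion.C3, maj
                notes.append(
                    "; ".join(
                        f"{r.core_name} includes all core variants of {o.core_name}"
                        for r, o in diffs
                    )
                )

    # C3_WT: recently added allele replacing a wild-type call
    if criterion is None:
        target = _wildtype_novel_target(original, cell_calls, current_db, gene, recent)
        if target is not None:
            criterion, revised = Criterion.C3_WT, target
            notes.append("recently added allele; other callers on outdated databases")

    # C4: obsolete original alleles removed
    if criterion is None:
        missing = [a for a in original.alleles if not current_db.has_allele(gene, a.core_name)]
        if missing:
            criterion = Criterion.C4
            revised = _replace_obsolete(original, missing, maj, current_db, gene, notes)

    # retention paths
    if criterion is None:
        revised = original
        if cons is not None:  # cons == original here
            criterion = Criterion.NONE
            if truth_cell.tentative:
                notes.append("tentative call confirmed by callers")
        elif all(
            tool_dbs.knows(tool, gene, core)
            for tool in tool_dbs.tools
            for core in orig_cores
        ):
            criterion = Criterion.C5
            notes.append("ambiguous calls; experimentally observed diplotype retained")
        else:
            criterion = Criterion.NONE
            notes.append("unresolvable: original allele absent from a tool database")

    classes = _classify_cell(
        original, revised, cell_calls, truth_cell.tentative, criterion,
        rename_map, current_db, gene,
    )
    return RevisionRecord(
        sample=sample,
        gene=gene,
        original=original,
        revised=revised,
        criterion=criterion,
        allele_classes=classes,
        notes="; ".join(notes),
    )


def _wildtype_novel_target(
    original: Diplotype,
    cell_calls: Mapping[str, Call],
    db: DatabaseVersion,
    gene: str,
    recent: frozenset[str],
) -> Diplotype | None:
    wt = db.wildtype_name(gene)
    slots = list(original.alleles)
    wt_idx = next((i for i, a in enumerate(slots) if a.core_name == wt), None)
    if wt_idx is None:
        return None
    called = [c for c in cell_calls.values() if c is not NO_CALL]
    if not called:
        return None
    orig_cores = {a.core_name for a in slots}
    candidates = sorted(
        {
            a
            for c in called
            for a in c.alleles
            if a.core_name in recent
            and a.core_name not in orig_cores
            and db.has_allele(gene, a.core_name)
        },
        key=lambda a: a.sort_key(),
    )
    for cand in candidates:
        replaced = list(slots)
        replaced[wt_idx] = cand
        target = Diplotype(*replaced)
        if any(c == target for c in called) and all(c in (original, target) for c in called):
            return target
    return None


def _replace_obsolete(
    original: Diplotype,
    missing: list[AlleleCall],
    maj: Diplotype | None,
    db: DatabaseVersion,
    gene: str,
    notes: list[str],
) -> Diplotype:
    counterpart: dict[AlleleCall, AlleleCall] = {}
    if maj is not None:
        for r, o in _align(maj, original, db, gene):
            counterpart[o] = r
    wildtype = AlleleCall(db.wildtype_name(gene))
    new_slots = []
    for allele in original.alleles:
        if allele not in missing:
            new_slots.append(allele)
            continue
        repl = counterpart.get(allele)
        if repl is not None and db.has_allele(gene, repl.core_name):
            notes.append(
                f"obsolete allele {allele.label} replaced with majority call {repl.label}"
            )
            new_slots.append(repl)
        else:
            notes.append(
                f"obsolete allele {allele.label} removed; wild-type substituted (no majority replacement)"
            )
            new_slots.append(wildtype)
    return Diplotype(*new_slots)


def classify_allele(
    original_allele: AlleleCall,
    revised_allele: AlleleCall,
    *,
    tentative: bool,
    criterion: Criterion,
    n_tools_reproducing: int,
    renamed: bool = False,
) -> AlleleClass:
    """Classify one (original, revised) allele pair.

    ``n_tools_reproducing`` counts callers whose call contains the revised
    allele.  The boundary between ORIGINAL and CONCORDANT is independent
    reproduction by at least two callers.
    """
    if revised_allele == original_allele:
        if n_tools_reproducing >= 2:
            return AlleleClass.CONFIRMED if tentative else AlleleClass.CONCORDANT
        return AlleleClass.ORIGINAL
    if criterion == Criterion.C4 or renamed:
        return AlleleClass.LEGACY
    return AlleleClass.DISCORDANT


def _classify_cell(
    original: Diplotype,
    revised: Diplotype,
    cell_calls: Mapping[str, Call],
    tentative: bool,
    criterion: Criterion,
    rename_map: Mapping[tuple[str, str], str],
    db: DatabaseVersion,
    gene: str,
) -> tuple[AlleleClass, AlleleClass]:
    called = [c for c in cell_calls.values() if c is not NO_CALL]
    classes = []
    for r, o in _align(revised, original, db, gene):
        reproducing = sum(1 for c in called if c.contains(r))
        renamed = rename_map.get((gene, o.core_name)) == r.core_name
        classes.append(
            classify_allele(
                o,
                r,
                tentative=tentative,
                criterion=criterion,
                n_tools_reproducing=reproducing,
                renamed=renamed,
            )
        )
    return (classes[0], classes[1])


# ---------------------------------------------------------------------------
# whole-dataset revision
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class RevisionResult:
    """All per-cell revision records plus cohort-level summary counts."""

    records: list[RevisionRecord]
    summary: dict

    def record_map(self) -> dict[tuple[str, str], RevisionRecord]:
        return {(r.sample, r.gene): r for r in self.records}


def revise_dataset(
    matrix: CallMatrix,
    current_db: DatabaseVersion,
    tool_dbs: ToolDbRegistry,
    recent_alleles: Mapping[str, Iterable[str]] | Iterable[str],
    *,
    verified_alleles: Iterable[tuple[str, str]] = (),
    rename_map: Mapping[tuple[str, str], str] | None = None,
) -> RevisionResult:
    """Revise every cell of the matrix and summarise the outcome.

    ``recent_alleles`` may be a per-gene mapping or one flat name set.
    Deterministic: identical inputs produce identical records and summary.
    """
    matrix.validate()
    if isinstance(recent_alleles, Mapping):
        recent_by_gene = {g: frozenset(v) for g, v in recent_alleles.items()}
        flat: frozenset[str] | None = None
    else:
        recent_by_gene = {}
        flat = frozenset(recent_alleles)

    records: list[RevisionRecord] = []
    for sample in matrix.samples:
        for gene in matrix.genes:
            records.append(
                apply_revision_criteria(
                    sample,
                    gene,
                    matrix.truth[(sample, gene)],
                    matrix.cell_calls(sample, gene),
                    current_db,
                    tool_dbs,
                    recent_by_gene.get(gene, flat if flat is not None else frozenset()),
                    verified_alleles=verified_alleles,
                    rename_map=rename_map,
                )
            )
    return RevisionResult(records=records, summary=summarize_records(records, matrix))


def summarize_records(records: Sequence[RevisionRecord], matrix: CallMatrix) -> dict:
    n_diplotypes = len(records)
    n_updated = sum(1 for r in records if r.updated)
    n_alleles = 2 * n_diplotypes
    n_alleles_revised = 0
    class_totals: Counter = Counter()
    criterion_counts: Counter = Counter()
    per_gene: dict[str, Counter] = {gene: Counter() for gene in matrix.genes}
    for rec in records:
        criterion_counts[rec.criterion.value] += 1
        for cls in rec.allele_classes:
            class_totals[cls.value] += 1
            per_gene[rec.gene][cls.value] += 1
            # LEGACY and DISCORDANT are exactly the changed-allele classes
            if cls in (AlleleClass.LEGACY, AlleleClass.DISCORDANT):
                n_alleles_revised += 1
    return {
        "n_diplotypes": n_diplotypes,
        "n_updated": n_updated,
        "pct_updated": format_percent(n_updated, n_diplotypes) if n_diplotypes else "0.00",
        "n_alleles": n_alleles,
        "n_alleles_revised": n_alleles_revised,
        "pct_alleles_revised": format_percent(n_alleles_revised, n_alleles) if n_alleles else "0.00",
        "class_totals": dict(class_totals),
        "criterion_counts": dict(criterion_counts),
        "per_gene_class_counts": {g: dict(c) for g, c in per_gene.items()},
    }


def revision_rows(records: Sequence[RevisionRecord]) -> list[tuple[str, ...]]:
    """Flatten records to TSV rows: sample, gene, original, revised,
    criterion, class_allele1, class_allele2, notes."""
    return [
        (
            rec.sample,
            rec.gene,
            format_diplotype(rec.original),
            format_diplotype(rec.revised),
            rec.criterion.value,
            rec.allele_classes[0].value,
            rec.allele_classes[1].value,
            rec.notes,
        )
        for rec in records
    ]
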