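"""Added/retired/unaltered core-allele deltas across a definition history.

Allele lifecycles are tracked at the level of *names*: an allele that keeps
its name but changes its defining variant set is "unaltered" here (the
change is surfaced as a warning by callers that care), while a renamed
allele counts as one retirement plus one addition.  The first version of a
history is the baseline and contributes no additions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .allele_db import DatabaseVersion, version_key
from .errors import HistoryError, VersionOrderError


@dataclass(slots=True)
class VersionDelta:
    """Name-level allele differences between two consecutive versions."""

    from_version: str
    to_version: str
    added: dict[str, frozenset[str]] = field(default_factory=dict)
    retired: dict[str, frozenset[str]] = field(default_factory=dict)
    unaltered: dict[str, frozenset[str]] = field(default_factory=dict)

    def n_added(self) -> int:
        return sum(len(v) for v in self.added.values())

    def n_retired(self) -> int:
        return sum(len(v) for v in self.retired.values())

    def n_unaltered(self) -> int:
        return sum(len(v) for v in self.unaltered.values())

    def genes(self) -> list[str]:
        return sorted(set(self.added) | set(self.retired) | set(self.unaltered))


@dataclass(slots=True)
class HistoryDiff:
    """Consecutive pairwise deltas plus cumulative add/retire totals."""

    deltas: list[VersionDelta]
    total_added: int
    total_retired: int


def diff_versions(v_old: DatabaseVersion, v_new: DatabaseVersion) -> VersionDelta:
    """Per-gene name-level set differences between two versions.

    Genes present in only one version contribute all their alleles to the
    corresponding side; genes excluded in either version are skipped.
    """
    if version_key(v_old.version_label) >= version_key(v_new.version_label):
        raise VersionOrderError(
            f"version labels must be strictly increasing: "
            f"{v_old.version_label!r} !< {v_new.version_label!r}"
        )
    skip = v_old.excluded_genes | v_new.excluded_genes
    delta = VersionDelta(from_version=v_old.version_label, to_version=v_new.version_label)
    for gene in sorted(set(v_old.alleles) | set(v_new.alleles)):
        if gene in skip:
            continue
        old_names = frozenset(v_old.alleles.get(gene, ()))
        new_names = frozenset(v_new.alleles.get(gene, ()))
        added = new_names - old_names
        retired = old_names - new_names
        unaltered = old_names & new_names
        if added:
            delta.added[gene] = added
        if retired:
            delta.retired[gene] = retired
        if unaltered:
            delta.unaltered[gene] = unaltered
    return delta


def diff_history(versions: Sequence[DatabaseVersion]) -> HistoryDiff:
    """Pairwise deltas over an ordered history plus cumulative totals.

    An allele retired and later re-added counts once in each total.
    """
    if len(versions) < 2:
        raise HistoryError(f"need at least 2 versions to diff, got {len(versions)}")
    deltas = [diff_versions(a, b) for a, b in zip(versions, versions[1:])]
    return HistoryDiff(
        deltas=deltas,
        total_added=sum(d.n_added() for d in deltas),
        total_retired=sum(d.n_retired() for d in deltas),
    )


def per_gene_counts(v: DatabaseVersion) -> dict[str, int]:
    """Core alleles per non-excluded gene."""
    return {gene: len(v.alleles[gene]) for gene in v.counted_genes()}


def delta_rows(delta: VersionDelta) -> list[tuple[str, str, str, str, str]]:
    """Flatten a delta to (from, to, gene, allele, status) rows for TSV output."""
    rows = []
    for status, mapping in (
        ("added", delta.added),
        ("retired", delta.retired),
        ("unaltered", delta.unaltered),
    ):
        for gene in sorted(mapping):
            for allele in sorted(mapping[gene]):
                rows.append((delta.from_version, delta.to_version, gene, allele, status))
    return rows


def detect_renames(versions: Sequence[DatabaseVersion]) -> dict[tuple[str, str], str]:
    """Infer nomenclature renamings from a history.

    A retirement whose variant set reappears verbatim as an addition in the
    same transition is treated as a renaming; returns
    ``{(gene, old_name): new_name}``.
    """
    renames: dict[tuple[str, str], str] = {}
    for v_old, v_new in zip(versions, versions[1:]):
        delta = diff_versions(v_old, v_new)
        for gene, retired in delta.retired.items():
            added = delta.added.get(gene, frozenset())
            added_by_variants = {}
            for name in sorted(added):
                added_by_variants.setdefault(
                    v_new.get_allele(gene, name).core_variants, name
                )
            for old_name in sorted(retired):
                variants = v_old.get_allele(gene, old_name).core_variants
                if variants and variants in added_by_variants:
                    renames[(gene, old_name)] = added_by_variants[variants]
    return renames
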