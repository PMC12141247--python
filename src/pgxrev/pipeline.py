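"""End-to-end pipeline: diff -> revise -> phenotype -> frequencies.

Every output is a TSV with ``#``-prefixed metadata lines recording the
definition-database version, the tool-database registry digest and a
digest of the run configuration, so any report can be traced back to the
exact nomenclature release it was interpreted against.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import __version__
from .allele_db import DatabaseVersion, load_history
from .call_model import CallMatrix, load_call_matrix
from .errors import ConfigError
from .frequency_report import allele_frequencies
from .phenotype_engine import (
    FunctionTable,
    load_function_table,
    phenotype_change_report,
)
from .revision_engine import (
    RevisionResult,
    ToolDbRegistry,
    load_tool_registry,
    revise_dataset,
    revision_rows,
)
from .version_diff import delta_rows, detect_renames, diff_history

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    defs_dir: Path
    truth: Path
    tool_calls: dict[str, Path]
    tool_dbs: Path
    functions: Path
    rules: Path
    out_dir: Path
    current_version: str | None = None  # default: latest in the history
    excluded_genes: tuple[str, ...] = ()
    wildtype_names: dict[str, str] = field(default_factory=dict)
    recent_window: int = 3
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def p(key: str) -> Path:
            if key not in raw:
                raise ConfigError(f"config missing required key {key!r}")
            return (base / raw[key]).resolve()

        return cls(
            defs_dir=p("defs_dir"),
            truth=p("truth"),
            tool_calls={t: (base / v).resolve() for t, v in raw.get("tool_calls", {}).items()},
            tool_dbs=p("tool_dbs"),
            functions=p("functions"),
            rules=p("rules"),
            out_dir=(base / raw.get("out_dir", "out")).resolve(),
            current_version=raw.get("current_version"),
            excluded_genes=tuple(raw.get("excluded_genes", ())),
            wildtype_names=dict(raw.get("wildtype_names", {})),
            recent_window=int(raw.get("recent_window", 3)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def digest(self) -> str:
        payload = json.dumps(
            {
                "defs_dir": str(self.defs_dir),
                "truth": str(self.truth),
                "tool_calls": {t: str(p) for t, p in sorted(self.tool_calls.items())},
                "tool_dbs": str(self.tool_dbs),
                "functions": str(self.functions),
                "rules": str(self.rules),
                "current_version": self.current_version,
                "excluded_genes": list(self.excluded_genes),
                "wildtype_names": self.wildtype_names,
                "recent_window": self.recent_window,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_tsv(
    path: Path,
    meta: dict[str, str],
    columns: Sequence[str],
    rows: Iterable[Sequence],
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def recent_alleles_from_history(
    versions: Sequence[DatabaseVersion], window: int
) -> dict[str, frozenset[str]]:
    """Allele names first appearing within the last *window* transitions."""
    recent: dict[str, set[str]] = {}
    pairs = list(zip(versions, versions[1:]))[-window:] if len(versions) > 1 else []
    for v_old, v_new in pairs:
        for gene in v_new.alleles:
            old_names = set(v_old.alleles.get(gene, ()))
            for name in set(v_new.alleles[gene]) - old_names:
                recent.setdefault(gene, set()).add(name)
    return {gene: frozenset(names) for gene, names in recent.items()}


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute all stages and write deltas, revision, summary, phenotypes
    and frequency TSVs into ``cfg.out_dir``.

    On any stage error, partially written outputs are removed and the
    exception re-raised.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    for label, path in [("truth table", cfg.truth), ("tool-db table", cfg.tool_dbs),
                        ("function table", cfg.functions), ("phenotype rules", cfg.rules)]:
        if not Path(path).exists():
            raise ConfigError(f"{label} not found: {path}")
    for tool, path in cfg.tool_calls.items():
        if not Path(path).exists():
            raise ConfigError(f"call table for tool {tool!r} not found: {path}")

    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        history = load_history(
            cfg.defs_dir,
            excluded_genes=cfg.excluded_genes,
            wildtype_names=cfg.wildtype_names,
        )
        if not history:
            raise ConfigError(f"no definition tables found in {cfg.defs_dir}")
        if cfg.current_version is not None:
            by_label = {v.version_label: v for v in history}
            if cfg.current_version not in by_label:
                raise ConfigError(
                    f"current version {cfg.current_version!r} not in history "
                    f"({sorted(by_label)})"
                )
            current = by_label[cfg.current_version]
        else:
            current = history[-1]
        logger.info("definition history: %d versions, current=%s",
                    len(history), current.version_label)

        with open(cfg.tool_dbs, encoding="utf-8") as fh:
            registry = load_tool_registry(fh)
        meta = {
            "pgxrev_version": __version__,
            "definition_version": current.version_label,
            "tool_db_digest": registry.digest(),
            "config_digest": cfg.digest(),
        }

        # stage 1: version diff
        hist_diff = diff_history(history)
        deltas_path = cfg.out_dir / "deltas.tsv"
        write_tsv(
            deltas_path,
            {**meta, "total_added": str(hist_diff.total_added),
             "total_retired": str(hist_diff.total_retired)},
            ("from_version", "to_version", "gene", "allele", "status"),
            (row for delta in hist_diff.deltas for row in delta_rows(delta)),
        )
        written.append(deltas_path)

        # stage 2: revision
        matrix = _load_matrix(cfg)
        recent = recent_alleles_from_history(history, cfg.recent_window)
        renames = detect_renames(history)
        result = revise_dataset(
            matrix, current, registry, recent, rename_map=renames
        )
        revision_path = cfg.out_dir / "revision.tsv"
        write_tsv(
            revision_path,
            meta,
            ("sample", "gene", "original", "revised", "criterion",
             "class_allele1", "class_allele2", "notes"),
            revision_rows(result.records),
        )
        written.append(revision_path)
        written.append(_write_summary(cfg.out_dir / "summary.tsv", meta, result))

        # stage 3: phenotypes
        ft = _load_functions(cfg)
        report = phenotype_change_report(result.records, ft)
        phenotypes_path = cfg.out_dir / "phenotypes.tsv"
        write_tsv(
            phenotypes_path,
            {**meta, **{f"pct_samples_altered_{g}": p
                        for g, p in report.pct_altered_by_gene.items()}},
            ("sample", "gene", "old_phenotype", "new_phenotype", "altered"),
            ((r.sample, r.gene, r.old_phenotype, r.new_phenotype,
              "T" if r.altered else "F") for r in report.rows),
        )
        written.append(phenotypes_path)

        # stage 4: allele frequencies over the revised calls
        revised_calls = {
            (rec.sample, rec.gene): rec.revised for rec in result.records
        }
        freq_path = cfg.out_dir / "freq.tsv"
        freq_rows = []
        for gene in matrix.genes:
            for row in allele_frequencies(
                {k: v for k, v in revised_calls.items() if k[1] == gene}, gene
            ):
                freq_rows.append((row.gene, row.allele, row.count, row.percent))
        write_tsv(freq_path, meta, ("gene", "allele", "count", "frequency_pct"), freq_rows)
        written.append(freq_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return {
        "deltas": cfg.out_dir / "deltas.tsv",
        "revision": cfg.out_dir / "revision.tsv",
        "summary": cfg.out_dir / "summary.tsv",
        "phenotypes": cfg.out_dir / "phenotypes.tsv",
        "freq": cfg.out_dir / "freq.tsv",
    }


def _load_matrix(cfg: RunConfig) -> CallMatrix:
    streams = {}
    try:
        truth_fh = open(cfg.truth, encoding="utf-8")
        streams = {t: open(p, encoding="utf-8") for t, p in cfg.tool_calls.items()}
        return load_call_matrix(truth_fh, streams)
    finally:
        for fh in streams.values():
            fh.close()
        try:
            truth_fh.close()
        except NameError:  # pragma: no cover - open() itself failed
            pass


def _load_functions(cfg: RunConfig) -> FunctionTable:
    with open(cfg.functions, encoding="utf-8") as fn, open(cfg.rules, encoding="utf-8") as rl:
        return load_function_table(fn, rl)


def _write_summary(path: Path, meta: dict[str, str], result: RevisionResult) -> Path:
    summary = result.summary
    rows: list[tuple[str, str, str]] = []
    for key in ("n_diplotypes", "n_updated", "pct_updated",
                "n_alleles", "n_alleles_revised", "pct_alleles_revised"):
        rows.append(("cohort", key, str(summary[key])))
    for cls, count in sorted(summary["class_totals"].items()):
        rows.append(("class_total", cls, str(count)))
    for crit, count in sorted(summary["criterion_counts"].items()):
        rows.append(("criterion", crit, str(count)))
    for gene, counts in sorted(summary["per_gene_class_counts"].items()):
        for cls, count in sorted(counts.items()):
            rows.append((f"gene:{gene}", cls, str(count)))
    write_tsv(path, meta, ("section", "key", "value"), rows)
    return path
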