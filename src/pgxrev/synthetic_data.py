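"""Synthetic versioned definition histories and multi-caller cohorts.

The generator emulates the structure of a reference-material reanalysis:
a nomenclature database evolving over releases (additions, retirements,
renamings, planted extension pairs), a cohort of diploid samples with a
consensus "truth" diplotype per pharmacogene, and several star-allele
callers whose internal databases lag the current release by a configurable
number of versions.  Every injected discrepancy is recorded in an event
log (scenario, expected criterion, expected allele classes, expected
revised diplotype), so revision results can be checked cell-by-cell
against a known answer — parameter recovery without any external data.

Per-gene planted structure (always present):

* wild-type ``*1`` (empty variant set) and base alleles ``*2``..``*7``,
  stable across all versions except the planted retirements;
* ``*8`` added in the first transition with a variant set that strictly
  extends ``*2`` (the extension pair);
* in the final transition: ``*3`` renamed to ``*9`` (same variants),
  ``*4`` retired outright (obsolete), and ``*10`` added fresh (the
  "recently added" allele).

Random extra additions/retirements draw names from a disjoint ``*9xx``
namespace so they can never collide with the planted structure.

Scenario mix defaults follow the discrepancy profile reported for
consensus-characterised reference cohorts: roughly one in five diplotypes
needs updating, dominated by legacy nomenclature and discordant consensus
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .allele_db import DatabaseVersion, StarAllele, Variant
from .call_model import NO_CALL, AlleleCall, Call, CallMatrix, Diplotype, TruthCell
from .errors import ConfigError
from .revision_engine import AlleleClass, Criterion, ToolDbRegistry

WILDTYPE = "*1"

DEFAULT_GENES: tuple[str, ...] = (
    "CYP1A1", "CYP1A2", "CYP2A6", "CYP2A13", "CYP2B6", "CYP2C8", "CYP2C9",
    "CYP2C19", "CYP2D6", "CYP2F1", "CYP2J2", "CYP2S1", "CYP3A4", "CYP3A5",
    "CYP4F2", "NAT1", "NAT2", "NUDT15", "SLCO1B1", "TPMT",
)


@dataclass(frozen=True, slots=True)
class ToolProfile:
    """How a simulated caller behaves.

    ``db_version_lag`` selects which release the tool's internal database
    mirrors (current minus lag); noise rates overlay random no-calls and
    miscalls after scenario construction.
    """

    db_version_lag: int = 0
    miscall_rate: float = 0.0
    no_call_rate: float = 0.0


@dataclass(frozen=True, slots=True)
class EventMix:
    """Per-cell scenario probabilities; the remainder is concordant."""

    tentative_confirmed: float = 0.01
    discordant_consensus: float = 0.06
    extension: float = 0.03
    wildtype_novel: float = 0.03
    legacy_rename: float = 0.05
    obsolete: float = 0.02
    ambiguous: float = 0.02

    def as_items(self) -> list[tuple[str, float]]:
        return [
            ("tentative_confirmed", self.tentative_confirmed),
            ("discordant_consensus", self.discordant_consensus),
            ("extension", self.extension),
            ("wildtype_novel", self.wildtype_novel),
            ("legacy_rename", self.legacy_rename),
            ("obsolete", self.obsolete),
            ("ambiguous", self.ambiguous),
        ]

    @property
    def concordant(self) -> float:
        return 1.0 - sum(rate for _, rate in self.as_items())

    def validate(self) -> None:
        for name, rate in self.as_items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"scenario rate {name} = {rate} outside [0, 1]")
        if self.concordant < 0:
            raise ConfigError("scenario rates sum to more than 1")


def _default_tools() -> dict[str, ToolProfile]:
    return {
        "aldy": ToolProfile(db_version_lag=1),
        "pypgx": ToolProfile(db_version_lag=0),
        "stellarpgx": ToolProfile(db_version_lag=1),
    }


@dataclass(slots=True)
class SimulationConfig:
    """Knobs for the synthetic study; defaults mirror a 70-sample,
    20-gene reference cohort reviewed with three callers."""

    n_samples: int = 70
    genes: tuple[str, ...] = DEFAULT_GENES
    n_versions: int = 5
    add_rate: float = 1.0  # expected random additions per gene per transition
    retire_rate: float = 0.3  # expected random retirements per gene per transition
    tools: dict[str, ToolProfile] = field(default_factory=_default_tools)
    event_mix: EventMix = field(default_factory=EventMix)
    recent_window: int = 3  # "recently added" = last K transitions
    seed: int = 0

    def validate(self) -> None:
        if self.n_versions < 2:
            raise ConfigError(f"need n_versions >= 2, got {self.n_versions}")
        if self.n_samples < 1:
            raise ConfigError("need at least one sample")
        if not self.tools:
            raise ConfigError("need at least one tool profile")
        max_lag = max(p.db_version_lag for p in self.tools.values())
        if max_lag >= self.n_versions:
            raise ConfigError("tool db lag exceeds history length")
        self.event_mix.validate()


# ---------------------------------------------------------------------------
# per-gene planted structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class GeneStructure:
    """Names of the planted alleles in one gene's history."""

    extension_base: str = "*2"  # B: extended by *8
    rename_old: str = "*3"  # O: renamed to *9 in the final transition
    obsolete: str = "*4"  # O2: retired with no successor
    pool: tuple[str, ...] = ("*5", "*6", "*7")  # stable alleles for calls
    extension: str = "*8"  # E: superset of B's variants
    rename_new: str = "*9"  # N: successor of O
    recent: str = "*10"  # R: added in the final transition

    @property
    def base_names(self) -> tuple[str, ...]:
        return (self.extension_base, self.rename_old, self.obsolete) + self.pool


STRUCTURE = GeneStructure()


@dataclass(slots=True)
class VersionEvent:
    """Planted + random add/retire names for one version transition."""

    from_version: str
    to_version: str
    added: dict[str, set[str]] = field(default_factory=dict)
    retired: dict[str, set[str]] = field(default_factory=dict)


@dataclass(slots=True)
class HistoryLog:
    """Ground truth for the simulated definition history."""

    transitions: list[VersionEvent] = field(default_factory=list)
    extension_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)  # gene -> (E, B)
    rename_map: dict[tuple[str, str], str] = field(default_factory=dict)
    obsolete_alleles: dict[str, str] = field(default_factory=dict)  # gene -> O2
    recent_alleles: dict[str, set[str]] = field(default_factory=dict)  # last-K additions

    def total_added(self) -> int:
        return sum(len(s) for t in self.transitions for s in t.added.values())

    def total_retired(self) -> int:
        return sum(len(s) for t in self.transitions for s in t.retired.values())


def _variant(gene_idx: int, offset: int) -> Variant:
    chrom = f"chr{1 + gene_idx % 22}"
    return Variant(chrom, 100_000 * (gene_idx + 1) + offset, "G", "A")


def simulate_version_history(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[DatabaseVersion], HistoryLog]:
    """Build an ordered definition history with a full event log.

    Versions are labelled ``1.0``..``<n>.0``.  Planted events are
    deterministic given the config; random extras are driven by *rng*
    (derived from ``cfg.seed`` when not supplied).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    log = HistoryLog()
    s = STRUCTURE

    # version 1: wild-type + base alleles per gene
    current: dict[str, dict[str, StarAllele]] = {}
    for g_idx, gene in enumerate(cfg.genes):
        alleles = {WILDTYPE: StarAllele(gene, WILDTYPE, frozenset())}
        for k, name in enumerate(s.base_names, start=2):
            alleles[name] = StarAllele(gene, name, frozenset({_variant(g_idx, 10 * k)}))
        current[gene] = alleles

    versions = [_snapshot(current, "1.0")]
    random_pool: dict[str, list[str]] = {gene: [] for gene in cfg.genes}
    counters = {gene: 900 for gene in cfg.genes}

    n_transitions = cfg.n_versions - 1
    for t in range(1, n_transitions + 1):
        event = VersionEvent(from_version=f"{t}.0", to_version=f"{t + 1}.0")
        for g_idx, gene in enumerate(cfg.genes):
            added: set[str] = set()
            retired: set[str] = set()

            if t == 1:  # plant the extension pair E > B
                base = current[gene][s.extension_base]
                ext_variants = base.core_variants | {_variant(g_idx, 9_000)}
                current[gene][s.extension] = StarAllele(gene, s.extension, ext_variants)
                added.add(s.extension)
                log.extension_pairs[gene] = (s.extension, s.extension_base)

            if t == n_transitions:  # final transition: rename, retire, add recent
                old = current[gene].pop(s.rename_old)
                current[gene][s.rename_new] = StarAllele(
                    gene, s.rename_new, old.core_variants
                )
                retired.add(s.rename_old)
                added.add(s.rename_new)
                log.rename_map[(gene, s.rename_old)] = s.rename_new

                current[gene].pop(s.obsolete)
                retired.add(s.obsolete)
                log.obsolete_alleles[gene] = s.obsolete

                current[gene][s.recent] = StarAllele(
                    gene, s.recent, frozenset({_variant(g_idx, 9_500)})
                )
                added.add(s.recent)

            # random extra additions (disjoint *9xx namespace)
            for _ in range(int(rng.poisson(cfg.add_rate))):
                counters[gene] += 1
                name = f"*{counters[gene]}"
                variants = frozenset(
                    {_variant(g_idx, 20_000 + 7 * counters[gene] + int(rng.integers(0, 3)))}
                )
                current[gene][name] = StarAllele(gene, name, variants)
                added.add(name)
                random_pool[gene].append(name)

            # random retirements drawn only from earlier random additions
            eligible = [n for n in random_pool[gene] if n in current[gene] and n not in added]
            n_retire = min(int(rng.poisson(cfg.retire_rate)), len(eligible))
            if n_retire:
                for name in rng.choice(eligible, size=n_retire, replace=False):
                    current[gene].pop(str(name))
                    retired.add(str(name))

            if added:
                event.added[gene] = added
            if retired:
                event.retired[gene] = retired
        versions.append(_snapshot(current, f"{t + 1}.0"))
        log.transitions.append(event)

    window = min(cfg.recent_window, n_transitions)
    for gene in cfg.genes:
        recent: set[str] = set()
        for event in log.transitions[-window:]:
            recent |= event.added.get(gene, set())
        log.recent_alleles[gene] = recent
    return versions, log


def _snapshot(current: Mapping[str, Mapping[str, StarAllele]], label: str) -> DatabaseVersion:
    return DatabaseVersion(
        version_label=label,
        alleles={gene: dict(alleles) for gene, alleles in current.items()},
    )


def make_tool_registry(
    cfg: SimulationConfig, versions: Sequence[DatabaseVersion]
) -> ToolDbRegistry:
    """Tool databases mirroring the release each tool lags at."""
    reg = ToolDbRegistry()
    for tool, profile in cfg.tools.items():
        idx = len(versions) - 1 - profile.db_version_lag
        reg.known[tool] = {
            gene: frozenset(versions[idx].alleles[gene]) for gene in versions[idx].alleles
        }
    return reg


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CellEvent:
    """Expected revision outcome for one injected cell."""

    scenario: str
    expected_criterion: Criterion
    expected_classes: tuple[AlleleClass, AlleleClass]
    expected_revised: Diplotype
    noise_applied: bool = False


@dataclass(slots=True)
class CohortLog:
    cells: dict[tuple[str, str], CellEvent] = field(default_factory=dict)

    def scenario_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ev in self.cells.values():
            counts[ev.scenario] = counts.get(ev.scenario, 0) + 1
        return counts


def simulate_cohort(
    cfg: SimulationConfig,
    versions: Sequence[DatabaseVersion],
    history_log: HistoryLog,
    rng: np.random.Generator | None = None,
) -> tuple[CallMatrix, CohortLog]:
    """Draw a scenario per cell and construct truth + tool calls for it.

    With zero tool noise the expected criterion, allele classes and revised
    diplotype recorded in the log hold exactly by construction.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    s = STRUCTURE
    tools = sorted(cfg.tools)
    if len(tools) < 3:
        raise ConfigError("cohort scenarios require at least three tools")
    lag_tools = [t for t in tools if cfg.tools[t].db_version_lag >= 1]
    fresh_tools = [t for t in tools if cfg.tools[t].db_version_lag == 0]
    if not lag_tools or not fresh_tools:
        raise ConfigError("need at least one lagging and one up-to-date tool")
    for gene in cfg.genes:
        if gene not in history_log.extension_pairs:
            raise ConfigError(f"history lacks a planted extension pair for {gene}")

    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    items = cfg.event_mix.as_items()
    names = [name for name, _ in items] + ["concordant"]
    probs = np.array([rate for _, rate in items] + [cfg.event_mix.concordant])

    wt = AlleleCall(WILDTYPE)
    matrix = CallMatrix(samples=samples, genes=list(cfg.genes), tools=tools)
    log = CohortLog()

    for sample in samples:
        for gene in cfg.genes:
            scenario = names[int(rng.choice(len(names), p=probs))]
            truth, calls, event = _build_cell(
                scenario, gene, s, wt, tools, lag_tools, fresh_tools, rng
            )
            matrix.truth[(sample, gene)] = truth
            noised = False
            for tool in tools:
                profile = cfg.tools[tool]
                call = calls[tool]
                if profile.no_call_rate > 0 and rng.random() < profile.no_call_rate:
                    call, noised = NO_CALL, True
                elif (
                    profile.miscall_rate > 0
                    and call is not NO_CALL
                    and rng.random() < profile.miscall_rate
                ):
                    pool = sorted(versions[-1].alleles[gene])
                    pick = rng.choice(pool, size=2, replace=True)
                    call, noised = (
                        Diplotype(AlleleCall(str(pick[0])), AlleleCall(str(pick[1]))),
                        True,
                    )
                matrix.tool_calls[(sample, gene, tool)] = call
            log.cells[(sample, gene)] = (
                replace(event, noise_applied=True) if noised else event
            )
    return matrix, log


def _build_cell(
    scenario: str,
    gene: str,
    s: GeneStructure,
    wt: AlleleCall,
    tools: list[str],
    lag_tools: list[str],
    fresh_tools: list[str],
    rng: np.random.Generator,
) -> tuple[TruthCell, dict[str, Call], CellEvent]:
    pool = [AlleleCall(name) for name in s.pool]
    CONC, CONF = AlleleClass.CONCORDANT, AlleleClass.CONFIRMED
    ORIG, LEG, DISC = AlleleClass.ORIGINAL, AlleleClass.LEGACY, AlleleClass.DISCORDANT

    def pick(options):  # deterministic under rng
        return options[int(rng.integers(0, len(options)))]

    if scenario in ("concordant", "tentative_confirmed"):
        x = pick(pool + [AlleleCall(s.extension_base)])
        d = Diplotype(wt, x)
        truth = TruthCell(d, tentative=(scenario == "tentative_confirmed"))
        calls = {t: d for t in tools}
        cls = (CONF, CONF) if truth.tentative else (CONC, CONC)
        return truth, calls, CellEvent(scenario, Criterion.NONE, cls, d)

    if scenario == "discordant_consensus":
        if rng.random() < 0.25:
            # both alleles disagree (e.g. *1/*1 -> *31/*37 style cells)
            four = pool + [AlleleCall(s.extension_base)]
            idx = rng.permutation(len(four))
            truth = TruthCell(Diplotype(four[idx[0]], four[idx[1]]))
            revised = Diplotype(four[idx[2]], four[idx[3]])
            calls = {t: revised for t in tools}
            return truth, calls, CellEvent(scenario, Criterion.C1, (DISC, DISC), revised)
        x = pick(pool)
        y = pick([a for a in pool if a != x])
        truth = TruthCell(Diplotype(wt, x))
        revised = Diplotype(wt, y)
        calls = {t: revised for t in tools}
        return truth, calls, CellEvent(scenario, Criterion.C1, (CONC, DISC), revised)

    if scenario == "extension":
        base, ext = AlleleCall(s.extension_base), AlleleCall(s.extension)
        truth = TruthCell(Diplotype(wt, base))
        revised = Diplotype(wt, ext)
        majority = [tools[0], tools[1]]
        calls = {t: (revised if t in majority else Diplotype(wt, base)) for t in tools}
        return truth, calls, CellEvent(scenario, Criterion.C3, (CONC, DISC), revised)

    if scenario == "wildtype_novel":
        recent = AlleleCall(s.recent)
        truth = TruthCell(Diplotype(wt, wt))
        revised = Diplotype(wt, recent)
        caller = fresh_tools[0]
        calls = {t: (revised if t == caller else Diplotype(wt, wt)) for t in tools}
        return truth, calls, CellEvent(scenario, Criterion.C3_WT, (CONC, DISC), revised)

    if scenario == "legacy_rename":
        old, new = AlleleCall(s.rename_old), AlleleCall(s.rename_new)
        truth = TruthCell(Diplotype(wt, old))
        revised = Diplotype(wt, new)
        laggard = lag_tools[0]
        calls = {t: (Diplotype(wt, old) if t == laggard else revised) for t in tools}
        return truth, calls, CellEvent(scenario, Criterion.C4, (CONC, LEG), revised)

    if scenario == "obsolete":
        gone = AlleleCall(s.obsolete)
        truth = TruthCell(Diplotype(wt, gone))
        revised = Diplotype(wt, wt)
        calls: dict[str, Call] = {
            tools[0]: Diplotype(wt, pool[0]),
            tools[1]: Diplotype(wt, pool[1]),
            tools[2]: NO_CALL,
        }
        for t in tools[3:]:
            calls[t] = NO_CALL
        return truth, calls, CellEvent(scenario, Criterion.C4, (CONC, LEG), revised)

    if scenario == "ambiguous":
        x = pick(pool)
        others = [a for a in pool + [AlleleCall(s.extension_base)] if a != x][:3]
        truth = TruthCell(Diplotype(wt, x))
        calls = {t: Diplotype(wt, others[i]) for i, t in enumerate(tools[:3])}
        for t in tools[3:]:
            calls[t] = NO_CALL
        return truth, calls, CellEvent(scenario, Criterion.C5, (CONC, ORIG), truth.diplotype)

    raise ConfigError(f"unknown scenario {scenario!r}")


def recent_allele_map(log: HistoryLog) -> dict[str, frozenset[str]]:
    """Per-gene recently added allele names, ready for the revision engine."""
    return {gene: frozenset(names) for gene, names in log.recent_alleles.items()}


def simulate(cfg: SimulationConfig):
    """Convenience wrapper: history, registry, cohort and logs in one call."""
    rng = np.random.default_rng(cfg.seed)
    versions, hist_log = simulate_version_history(cfg, rng)
    registry = make_tool_registry(cfg, versions)
    matrix, cohort_log = simulate_cohort(cfg, versions, hist_log, rng)
    return versions, hist_log, registry, matrix, cohort_log


def write_dataset(
    out_dir,
    cfg: SimulationConfig,
    versions: Sequence[DatabaseVersion],
    hist_log: HistoryLog,
    registry: ToolDbRegistry,
    matrix: CallMatrix,
    cohort_log: CohortLog,
) -> dict[str, object]:
    """Write a simulated dataset as pipeline-ready TSVs.

    Produces ``defs_dir/<version>.tsv``, ``truth.tsv``, ``calls_<tool>.tsv``,
    ``tooldbs.tsv`` and ``event_log.tsv`` under *out_dir*.
    """
    from pathlib import Path

    from .allele_db import serialize_allele_definitions
    from .call_model import format_diplotype

    out = Path(out_dir)
    defs_dir = out / "defs_dir"
    defs_dir.mkdir(parents=True, exist_ok=True)
    for version in versions:
        (defs_dir / f"{version.version_label}.tsv").write_text(
            serialize_allele_definitions(version), encoding="utf-8"
        )

    def _write(path, columns, rows):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# pgxrev synthetic dataset, seed {cfg.seed}\n")
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(str(v) for v in row) + "\n")

    _write(
        out / "truth.tsv",
        ("sample", "gene", "diplotype", "tentative", "evidence"),
        (
            (s, g, format_diplotype(cell.diplotype),
             "T" if cell.tentative else "F", ",".join(cell.evidence))
            for (s, g), cell in sorted(matrix.truth.items())
        ),
    )
    call_paths = {}
    for tool in matrix.tools:
        path = out / f"calls_{tool}.tsv"
        _write(
            path,
            ("sample", "gene", "diplotype"),
            (
                (s, g, "." if (c := matrix.tool_calls[(s, g, tool)]) is NO_CALL
                 else format_diplotype(c))
                for (s, g) in sorted(matrix.truth)
            ),
        )
        call_paths[tool] = path
    _write(
        out / "tooldbs.tsv",
        ("tool", "gene", "alleles"),
        (
            (tool, gene, ";".join(sorted(registry.known[tool][gene])))
            for tool in registry.tools
            for gene in sorted(registry.known[tool])
        ),
    )
    _write(
        out / "event_log.tsv",
        ("sample", "gene", "scenario", "expected_criterion",
         "expected_class1", "expected_class2", "expected_revised", "noise_applied"),
        (
            (s, g, ev.scenario, ev.expected_criterion.value,
             ev.expected_classes[0].value, ev.expected_classes[1].value,
             format_diplotype(ev.expected_revised), "T" if ev.noise_applied else "F")
            for (s, g), ev in sorted(cohort_log.cells.items())
        ),
    )
    return {
        "defs_dir": defs_dir,
        "truth": out / "truth.tsv",
        "tool_calls": call_paths,
        "tool_dbs": out / "tooldbs.tsv",
        "event_log": out / "event_log.tsv",
    }
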