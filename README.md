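# pgxrev

Star-allele nomenclature is a moving target. Pharmacogene haplotypes
("star alleles", e.g. `CYP2D6*2`, `SLCO1B1*31`) are defined by sets of
core variants in versioned databases, and alleles are continually added,
renamed and retired between releases. Consensus-characterised reference
materials and the internal databases of star-allele calling tools age
accordingly: a diplotype recorded as `*1/*1` years ago may be `*31/*37`
under current definitions — with real consequences for phenotype
prediction and drug dosing (for `SLCO1B1`, statin recommendations).

`pgxrev` is a toolkit for quantifying and repairing this drift. It is
aimed at people who maintain or benchmark pharmacogenomic reference
datasets and star-allele callers. It provides:

* **`allele_db`** — a data model for versioned star-allele definition
  tables: sub-allele collapsing (`*2.001` → `*2`), core-variant sets, and
  the *extension* relation (allele `a` extends `b` iff `a`'s core-variant
  set ⊇ `b`'s and `a ≠ b`).
* **`version_diff`** — added / retired / unaltered core-allele deltas
  across an ordered release history, with per-gene counts, cumulative
  totals and rename detection.
* **`call_model`** — diplotype parsing and canonicalisation
  (order-insensitive, copy-number aware: `*1x2/*7`), plus the cohort
  call matrix of truth and per-tool calls.
* **`revision_engine`** — a fixed five-criterion procedure that revises
  each truth diplotype against the calls of multiple tools (consensus,
  verified majority, extension substitution, recently added allele vs
  wild-type, obsolete-allele removal, ambiguous-call retention) and
  classifies every allele as *original*, *confirmed*, *concordant*,
  *legacy* or *discordant*.
* **`phenotype_engine`** — diplotype → phenotype translation via
  allele-function tables and statin recommendation lookup with default
  phenotype profiles for co-genes (CYP2C9, ABCG2).
* **`frequency_report`** — cohort allele frequencies (2 chromosomes per
  sample, copy-number calls as their own rows) and reports of alleles
  absent from a baseline.
* **`synthetic_data`** — a generator for definition histories and
  multi-caller cohorts with a complete injected event log, so every
  stage can be validated by exact parameter recovery.

## Worked example

Simulate a 70-sample × 20-gene cohort with three callers whose internal
databases lag the current release, then revise it:

```python
from pgxrev.synthetic_data import SimulationConfig, simulate, recent_allele_map
from pgxrev.revision_engine import revise_dataset

cfg = SimulationConfig(seed=1)            # 70 samples, 20 genes, 3 tools
versions, hlog, registry, matrix, clog = simulate(cfg)
result = revise_dataset(
    matrix, versions[-1], registry,
    recent_allele_map(hlog), rename_map=hlog.rename_map,
)
s = result.summary
print(f"{s['n_updated']} of {s['n_diplotypes']} diplotypes updated ({s['pct_updated']}%)")
print(f"{s['n_alleles_revised']} of {s['n_alleles']} alleles revised ({s['pct_alleles_revised']}%)")
print("class totals:", dict(sorted(s['class_totals'].items())))
```

prints

```
281 of 1400 diplotypes updated (20.1%)
308 of 2800 alleles revised (11.0%)
class totals: {'concordant': 2429, 'confirmed': 32, 'discordant': 204, 'legacy': 104, 'original': 31}
```

1400 diplotypes = 70 samples × 20 genes; each contributes two alleles.
About one in five cells needed revision under the default event mix;
*legacy* alleles are nomenclature turnover (renamed or retired names),
*discordant* alleles are cells where the callers agree with each other
but not with the recorded truth. Because the generator logs the injected
scenario for every cell, `revise_dataset` can be checked against it
exactly — the criterion, both allele classes and the revised diplotype
are recovered on 100% of cells when tool noise is zero.

The downstream translation uses the shipped guideline tables:

```python
from pgxrev.data import load_default_function_table, load_statin_recommendations
from pgxrev.phenotype_engine import diplotype_to_phenotype, lookup_recommendation
from pgxrev.call_model import parse_diplotype

ft = load_default_function_table()
print(diplotype_to_phenotype(ft, "SLCO1B1", parse_diplotype("*31/*37")))
# Decreased function
rt = load_statin_recommendations()
print(lookup_recommendation(rt, "simvastatin", {"SLCO1B1": "Decreased function"}))
# Prescribe an alternative statin depending on the desired potency. If
# simvastatin therapy is warranted, limit dose to < 20 mg/day
```

Everything is also reachable from the command line:

```bash
pgxrev simulate --out-dir simdata --seed 1
pgxrev diff --history-dir simdata/defs_dir --out deltas.tsv
pgxrev revise --truth simdata/truth.tsv \
  --calls aldy=simdata/calls_aldy.tsv,pypgx=simdata/calls_pypgx.tsv,stellarpgx=simdata/calls_stellarpgx.tsv \
  --defs simdata/defs_dir --tool-dbs simdata/tooldbs.tsv --out revision.tsv
pgxrev run --config run.yaml          # all stages, TSV reports with version metadata
```

Every report embeds the definition-database version and a digest of the
tool-database registry in its header, so results are always traceable to
the nomenclature release they were interpreted against.

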