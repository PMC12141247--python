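# Methods

## Problem setting

A star allele is a named haplotype of a pharmacogene defined by a set of
core variants; sub-alleles (`*2.001`) refine a core allele with benign
variation and are collapsed onto it for all counting here. Nomenclature
databases release versioned definition sets in which alleles are added,
renamed and retired. Reference-material consensus diplotypes and the
internal databases of star-allele callers lag these releases, so a cohort
of recorded truth diplotypes accumulates three kinds of staleness:
nomenclature turnover (legacy/obsolete names), refinement (a newer allele
whose definition extends the recorded one), and plain discordance with
what modern callers see. `pgxrev` models the database dynamics, applies a
fixed revision procedure to a truth-vs-callers matrix, and propagates the
result to phenotypes, drug recommendations and allele frequencies.

## Data model and conventions

* Variants are `chrom:pos:ref:alt` tokens, 1-based, compared token-exact.
  No normalisation or liftover is performed: alleles are compared by
  definitional identity, not variant semantics.
* Allele-name lifecycle is tracked at the level of names. A same-name
  definition change is *not* a retirement; a renaming counts as one
  retirement plus one addition (rename detection pairs a retired name
  with an added name carrying an identical variant set within the same
  transition).
* The wild-type allele (default `*1`, configurable per gene) has an empty
  core-variant set, so any defined allele extends it.
* Copy-number suffixes (`x2`) are call-level annotations, not allele
  names: `*1x2` is a call of allele `*1` with copy number 2, and is
  reported as its own frequency row.
* Diplotypes are unordered; the canonical form sorts by the numeric part
  of the allele name (`*2` before `*10`), then full label, then copy
  number, so canonical-text equality coincides with multiset equality.
* Version labels sort by dotted-numeric components (`1.1.9.2 < 2.0`),
  with non-numeric components after numeric ones.

## Revision procedure

Criteria are evaluated in a fixed order per cell; the first that applies
determines the revision:

1. **C1 (consensus)** — all callers that produced a call agree, and the
   shared diplotype differs from the original. At least two callers are
   required: a single caller cannot form a consensus, which keeps one
   outdated tool from rewriting the reference.
2. **C2 (verified majority)** — a strict majority (> half of callers
   that called) agrees on a diplotype whose novel alleles are externally
   verified. Verification is an *input* (evidence tags on the truth row,
   or a supplied verification list), never computed: literature and
   orthogonal-benchmark checks are not algorithmic.
3. **C3 (extension)** — the majority call substitutes alleles that
   extend the corresponding original alleles (core-variant superset,
   both present in the current definitions). Substitution is per allele;
   the partner allele is preserved. The direction is: original (truth)
   allele → extending called allele.
4. **C3_WT (recent allele vs wild-type)** — the original has a wild-type
   allele, at least one caller reports a recently added allele, and
   every other caller reports either the wild-type or that same allele
   (the signature of outdated internal databases). "Recently added"
   means added within the last K version transitions (default K = 3,
   configurable). The candidate must not already be present in the
   original call, which also makes the procedure idempotent.
5. **C4 (obsolete)** — an original allele is absent from the current
   definition version. It is replaced by the majority-called counterpart
   when one exists and is currently defined; otherwise wild-type is
   substituted and the record is flagged, so the fallback never silently
   fabricates a genotype.
6. **C5 (retention)** — no consensus emerged, but every tool's database
   contains the original alleles: the experimentally observed original is
   retained. If some tool database lacks the original allele and nothing
   fired, the cell is retained with an "unresolvable" note.

A cell whose consensus simply equals the original is not a criterion
case; it is recorded as unchanged, with a note when an initially
tentative call is thereby confirmed.

**Allele classes.** Each allele of the revised diplotype gets exactly one
label: CONFIRMED (unchanged, tentative, reproduced by ≥ 2 callers),
CONCORDANT (unchanged, reproduced by ≥ 2 callers), ORIGINAL (unchanged,
not independently reproduced), LEGACY (changed by nomenclature turnover:
criterion C4 or a detected renaming, under any criterion), DISCORDANT
(changed because callers disagree with the original). The ≥ 2-caller
reproduction boundary between ORIGINAL and CONCORDANT is a documented
choice; the distinction is not otherwise operationalised in the source
material for this design.

**Alignment.** Per-allele classification requires pairing original with
revised alleles. Matching prefers identical calls, then identical core
names, then the extension relation, then position in canonical order —
deterministic for every input, including degenerate cases such as
`*1/*X → *1/*1` (the slot matched by identity stays CONCORDANT; the
replaced slot carries the change).

**Summary percentages** use the frequency-report formatting rules (see
below); `n_alleles = 2 × n_diplotypes` always, and per-gene class counts
sum to `2 × n_samples` by construction.

## Phenotype translation and recommendations

Phenotype prediction is a two-stage lookup shipped as data: allele →
function category, then unordered function pair → phenotype label. No
activity-score arithmetic is attempted; the tables are deliberately
editable. Unknown alleles yield `indeterminate` function and an
`Indeterminate` phenotype, and phenotype-change counting excludes any
transition involving an indeterminate side. The altered-sample
percentage is formatted to one decimal (half-up).

The shipped SLCO1B1 tables assign `*1`, `*37` (and a few others) normal
function and `*31` no function, chosen so the diplotype-level phenotypes
`*1/*1 →` Normal function and `*31/*37 →` Decreased function hold; the
per-allele assignments themselves are fixture data, as are the
"Poor function" recommendation rows (marked as synthetic placeholders in
the file). The fourteen Normal/Decreased-function statin texts are stored
verbatim as opaque strings, including dose thresholds. Recommendation
lookup completes the query profile from configured defaults (CYP2C9 and
ABCG2 assumed Normal Metabolizer) before matching; the most specific
matching rule wins.

## Frequencies

Each sample contributes two chromosome observations per gene; copy-number
calls occupy one slot each (`*1x2` is one observation of that labelled
call), keeping the per-gene total at exactly 2N. Percentages are printed
with two decimals below 10% and one decimal at or above 10%, half-up —
the convention that reproduces published frequency-table values
(0.71, 1.43, ..., 15.0, 17.9) for a 70-sample / 140-chromosome cohort.

## Synthetic data generator

The generator is first-class, tested code: it emulates the study design
(default 70 samples × 20 pharmacogenes × 3 callers over a 5-version
definition history) and records every injected event so results can be
verified by exact recovery.

Per gene the history plants, deterministically: base alleles `*2`–`*7`
(singleton, mutually disjoint variant sets); `*8` added in the first
transition as a strict superset of `*2` (the extension pair); and in the
final transition a renaming `*3 → *9` (same variants), the retirement of
`*4` with no successor, and a fresh `*10` (the "recently added" allele).
Random extra additions/retirements (Poisson, defaults 1.0 and 0.3 per
gene per transition) draw names from a disjoint `*9xx` namespace and
retirements touch only previously random-added names, so the planted
structure is never disturbed. Caller databases mirror the release
`current − lag` (defaults: one up-to-date tool, two lagging one version),
which is what produces legacy and wild-type behaviour for new alleles.

Per cell a scenario is drawn: concordant (remainder), tentative-confirmed
(0.01), discordant consensus (0.06, of which one quarter substitutes both
alleles, e.g. `*5/*6 → *2/*7`), extension (0.03), wild-type/novel (0.03),
legacy rename (0.05), obsolete (0.02), ambiguous (0.02). The non-concordant
mass of 0.22 with 0.19 update-inducing puts the expected updated-diplotype
rate near one in five and the expected revised-allele rate near one in
nine — the regime reported for consensus-characterised reference cohorts
re-called with modern tools. Each scenario constructs tool calls whose
revision outcome is forced by the criteria above, and logs the expected
criterion, allele classes and revised diplotype. Optional per-tool noise
(no-call and miscall rates, default 0) is overlaid afterwards and flags
the affected cells in the log.

What the generator does **not** emulate: realistic population allele
frequencies (truth alleles are drawn uniformly from a small pool),
linkage between genes, phasing ambiguity, sequence-level error modes, or
multi-candidate caller output. Exact parameter recovery on this synthetic
cohort therefore demonstrates that the revision logic implements its
specification faithfully — not that any particular real cohort would be
revised at these rates.

## Numerical and degenerate-input choices

* Half-up decimal rounding everywhere percentages are printed (via
  `decimal.Decimal`), never binary-float rounding.
* All tools NO_CALL: no consensus, no majority; the cell falls through to
  retention.
* A truth allele obsolete *and* unanimously re-called by the tools is a
  C1 case (precedence); C4 only fires when no voting criterion resolved
  the cell.
* Duplicate core-allele rows with conflicting variant sets are a load
  error; identical duplicates (typical after sub-allele collapsing)
  merge silently with the first definition winning.
* Multi-candidate caller output (`;`-separated) takes the first candidate
  and logs a warning.

## Scale of shipped checks

The test suite and acceptance script run entirely on synthetic data:
parameter recovery uses 100 seeds × 1400 cells (tests) and 25 seeds
(acceptance script); oracle equivalence uses 1000 random version pairs
and ~200 random small databases for the extension relation. These sizes
were chosen to exercise every scenario and criterion many hundreds of
times while completing in well under a minute each.

## Known limitations

* Renaming detection requires variant-set identity within a single
  transition; a rename combined with a definition change in the same
  release is counted as an unrelated retirement plus addition.
* The revision engine consumes caller *outputs*; no adapters for any
  specific caller's native report format are included.
* Phenotype translation ignores copy number (function is keyed on the
  core allele name), which is inadequate for genes where duplications
  change activity scores — such genes need explicit rules.
* The recommendation matcher is exact on phenotype strings; there is no
  fuzzy matching or activity-score algebra.
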