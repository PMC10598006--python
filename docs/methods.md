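# Methods

## The problem and the model

SDRF-Proteomics describes a mass-spectrometry experiment as a rectangular,
tab-delimited table: one row per sample-in-a-run, one typed column per
property. Columns fall into six categories — `source name` (the sample
identifier), `characteristics[...]` (biological sample properties),
`technology type`, `assay name` (the run), `comment[...]` (technical run
properties), and `factor value[...]` (the experimentally varied
conditions). Cell values are expected to be ontology/CV terms so that the
table is machine-readable; free-text synonyms ("human", "QE") are the main
source of downstream ambiguity, and canonicalizing them is the core service
this package provides.

`sdrfkit` models the annotation process as a pipeline of pure functions
over an immutable-by-convention `SDRFTable` (every operation returns a new
table). The pipeline mirrors how a curator works: species template → raw
file registration → local metadata mapping → label-channel expansion →
column filling → validation → submission digest.

## Controlled vocabularies

Ontologies are ingested from OBO term stanzas (`id`, `name`, `is_a`,
`synonym`, `def`, `is_obsolete`); vocabularies only distributed as OWL/JSON
term dumps enter through an equivalent flat term-list JSON importer rather
than an OWL reasoner — the vocabularies are used purely as term sources, so
description-logic semantics would buy nothing here. Parsing is backed by
`obonet`, with a light pre-scan supplying stanza-ordinal error messages and
`networkx` providing cycle detection; dangling `is_a` targets and cyclic
chains are construction-time errors.

From a graph, three derived artifacts are built, matching the cache shapes
an annotation front-end serves:

* the **element list** — every non-obsolete label, sorted
  case-insensitively (a deterministic choice; any stable order would do);
* the **nested tree** — a recursive label → children map; a DAG term with
  k parents appears under each of its k parents (duplication by path),
  recursion capped at a configurable depth (default 50) to guard
  pathological inputs;
* the **select-nodes tree** — the same shape with CURIEs attached, for
  tree-select widgets.

Obsolete terms are excluded from all three: an obsolete term must never be
offered for annotation. A non-obsolete term all of whose parents are
obsolete is promoted to the top level of the tree artifacts rather than
dropped (the toy generator additionally never gives obsolete terms
children, so top-level nodes coincide with graph roots on all fixtures).
Artifacts persist as gzipped JSON with the gzip header mtime pinned to
zero, so identical inputs are byte-identical on disk.

The **term index** normalizes labels and synonyms (case-fold, collapse
whitespace). Label/synonym collisions are resolved deterministically —
lowest CURIE wins, collision recorded as an index warning — instead of
guessing curator intent. Search ranks matches by class (exact label >
label prefix > label substring > the same three over synonyms), then
shorter label, then case-insensitive label order; each term contributes
its best match only.

## Templates, schemes, presets, bindings

Species templates (which required columns a table starts with), label
schemes (channel lists for TMT 6/10/11/16-plex, SILAC light/heavy, iTRAQ
4/8-plex, label-free), the metaproteomics column preset, and the
column→vocabulary binding map are all **data-driven JSON configuration**
shipped in `sdrfkit/data/` and overridable at run time. The shipped
template sets are a frozen, deliberately small stand-in for the evolving
community template collection; real templates drop in without code change.
TMT channel names follow PSI-MS conventions (the 16-plex series ends at
`TMT134N`).

## Workflow semantics

* **Raw-file registration** adds one row per file, auto-naming blank
  samples `sample <i>` and runs `run <i>` (1-based). At most **250
  distinct files** per session/table (pre-expansion), enforced at
  registration, at merge, and re-checked by validation; larger datasets
  are annotated as partial files and merged.
* **Metadata mapping** aligns local rows positionally when counts match,
  or by joining a declared file-name column on `comment[data file]`;
  mismatches are errors, never silent truncation. Each mapped cell is
  resolved against the vocabulary bound to its target column: exact
  matches keep the canonical casing, synonym matches are **rewritten to
  the canonical label** (canonicalization is the point — synonym spellings
  are what breaks machine readability), anything else stays in place and
  is reported. Unbound columns accept free text verbatim and count as
  resolved, so the report always partitions the mapped cells.
* **Label expansion** replaces each row by one row per channel;
  `comment[label]` carries the channel and source names gain a ` ch<j>`
  suffix so (sample, channel) pairs stay unique. Single-channel schemes
  (label-free) keep source names verbatim — no ambiguity is created, so no
  suffix. Re-expanding a table whose files already carry every channel of
  the scheme is rejected.
* **Column filling** against a bound vocabulary is atomic: one
  unresolvable value fails the whole call, leaving the table untouched
  (mirroring drop-down-only entry).
* **Partial merge** keys rows by `comment[data file]`; annotated
  (non-default) cells from the partial win over template defaults, two
  disagreeing non-default cells are a conflict, and a source-name
  disagreement for the same file is a key error. Merge and preset
  application are idempotent on their own output.
* **Missing values**: `not available` marks unknown-but-applicable cells,
  `not applicable` semantically void ones. Both pass vocabulary checks
  everywhere but count as empty on the three hard-required identity cells
  (source name, data file, organism).

## Submission digest

The digest is SHA-256 over a canonical byte form (tag
`sdrf-canonical-v1`): canonical category order with columns sorted by
rendered header within each category, lowercase headers, LF endings,
single trailing newline, UTF-8. Sorting within category makes the digest a
pure function of table *content* — permuting columns or re-casing headers
cannot change it, while any cell edit does. Note this is stricter than
file serialization (`write_sdrf`), which keeps insertion order within a
category for human readability. The digest ships as a conventional
checksum sidecar (`<digest>  <filename>`), since SDRF has no in-band
comment syntax; what a submission system does with it is outside this
package's contract.

## Validation

Validation returns findings, never exceptions. The code registry is
closed and documented (`FINDING_CODES`). Severity policy: unresolved terms
are errors on template-required columns, warnings on additional ones;
synonym matches warn with the canonical label suggested; the factor-value
orphan check (a `factor value[x]` without `characteristics[x]`) warns
rather than errors, since factor values may legitimately mirror comment
columns. Modification and cleavage cells follow a `KEY=value;…` grammar
with eight recognized keys (NT, AC, MT, PP, TA, TS, CS, MM); unknown keys
warn rather than fail because the format grows keys over time, while a
missing NT, a duplicate key, or a token without `=` is an error. Findings
sort stably by (row, column, code).

## Toy fixtures: what they emulate, what they don't

The fixture generators are pure functions of their spec/seed. The toy
taxonomy (default: 50 terms, depth 4, 20% synonym rate, no obsoletes)
embeds a fixed four-term block (root *organism*; *Homo sapiens* with
synonym *human*; its subspecies; *Mus musculus* with synonym *mouse*) so
cross-module examples are stable, then adds seeded random terms including
occasional second parents to exercise DAG-to-tree duplication. Companion
fixed mini-vocabularies cover anatomy, instruments, diseases, proteases
and a four-row Unimod-style catalog. Toy metadata mixes canonical labels
with synonym spellings and plants exactly one unresolvable value (row 5)
for mapping tests.

These fixtures exercise every code path at desk scale, but they are small
and clean: real CVs have millions of terms, deeper DAGs, heavy label
ambiguity, and messier synonym typing. Passing tests therefore demonstrate
the *logic* (resolution order, conservation laws, limits, determinism),
not performance or recall on production ontologies — the index and tree
builders are linear in term count plus path count, and the path-duplicated
tree can grow combinatorially on dense multi-parent DAGs, which is why the
depth guard exists.

## Numerical and procedural choices

* Percentages round **half-up to one decimal** on the 0–100 scale (the
  convention under which 156/9671 → 1.6 and 376/9671 → 3.9; the two
  annotated-project pools are treated as disjoint, which the published
  arithmetic supports). Implemented with `decimal` to avoid binary-float
  rounding surprises.
* SDRF cells may not contain tabs or newlines — SDRF has no quoting
  dialect, so such cells are a serialization error, not something to
  escape. Headers parse case-insensitively and always emit lowercase.
* Problem sizes in tests and the acceptance script: 50-term ontologies,
  2–12 raw files, 100 queries/corruptions per property class, 1000
  single-cell edits for digest collision checking — sizes at which the
  brute-force oracles (linear scans, DFS path enumeration, fixed-point
  ancestor closure) are trivially correct and the whole suite runs in
  seconds.
* Exit codes (CLI): 0 success, 1 validation/domain failure, 2 usage error.
  Logs go to standard error; data to files or standard output.

## Known limitations

* No OWL parsing or reasoning; no live ontology downloads; no
  cross-ontology mapping.
* The shipped species templates and the metaproteomics preset are
  configuration stand-ins, not authoritative community lists.
* The validator covers the rules this workflow produces and consumes; it
  is not a re-implementation of the full official SDRF rule set.
* `merge_partial` operates on pre-expansion tables (unique file keys); a
  label-expanded partial must be merged before expansion or re-expanded
  afterwards.
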