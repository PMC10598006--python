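# sdrfkit

A headless annotation engine for **SDRF-Proteomics** — the Sample and Data
Relationship Format that maps raw mass-spectrometry files to sample
characteristics, technical metadata and studied variables, with values drawn
from ontologies and controlled vocabularies (CVs).

Public proteomics datasets routinely ship without the metadata needed to
reuse them: organism, tissue, labeling technique, protease, instrument,
modifications. SDRF fixes the representation, but writing a valid SDRF by
hand in a spreadsheet is laborious and inconsistent. `sdrfkit` implements
the machinery a streamlined annotation tool needs, as an importable Python
library plus a thin CLI — no GUI, no network:

* **Ontology store** (`sdrfkit.ontology`) — parse OBO CVs (or flat
  term-list JSON dumps) into a term DAG; derive the three cached artifacts
  an annotation front-end serves (flat element list, nested label tree,
  widget-ready nodes tree, all persisted as gzipped JSON); resolve and
  rank-search terms by label and synonym; load Unimod-style modification
  catalogs from CSV.
* **SDRF model** (`sdrfkit.model`) — typed columns
  (`source name`, `characteristics[...]`, `technology type`, `assay name`,
  `comment[...]`, `factor value[...]`), species templates of required
  columns, canonical column ordering, strict TSV parse/serialize, raw-file
  registration with a 250-files-per-session cap.
* **Workflow** (`sdrfkit.workflow`) — the five-step annotation flow as
  composable, value-semantic operations: local-metadata mapping with
  synonym canonicalization, label-channel row expansion (TMT / SILAC /
  iTRAQ: one row per channel per run), vocabulary-checked column filling,
  column presets, partial-file merge, and a canonical SHA-256 submission
  digest.
* **Validation** (`sdrfkit.validation`) — structural and
  ontology-compliance checks producing machine-readable findings
  (`REQUIRED_MISSING`, `TERM_UNRESOLVED`, `KV_MALFORMED`, `FILE_LIMIT`, …),
  including the `NT=...;AC=...` key=value grammar of modification and
  cleavage cells.
* **Fixtures & stats** (`sdrfkit.fixtures`, `sdrfkit.stats`) — seeded toy
  vocabularies and metadata for offline use, and the adoption/funnel
  arithmetic (e.g. 156/9671 = 1.6% of repository datasets carrying
  submitter-supplied SDRF).

## Worked example

`examples/03_map_expand_validate_hash.py` runs the whole workflow on toy
fixtures — template, raw files, metadata mapping, TMT expansion, filling,
validation, digest:

```text
'organism' -> characteristics[organism]: 0 exact, 2 synonym-rewritten, 0 unresolved
'organism part' -> characteristics[organism part]: 2 exact, 0 synonym-rewritten, 0 unresolved
'instrument' -> comment[instrument]: 1 exact, 1 synonym-rewritten, 0 unresolved
'disease' -> characteristics[disease]: 1 exact, 1 synonym-rewritten, 0 unresolved

after TMT10plex expansion: 20 rows (2 files x 10 channels)
validation passed: True (0 errors, 0 warnings)
submission digest (SHA-256): 8e03a2c78112a16bc569d2f1186aff66f91622e70cf61487d23dd7f6dde3b9e0
```

The mapping report partitions every mapped cell: spellings like `"human"`
or `"QE"` were synonym matches and were rewritten to their canonical labels
(`Homo sapiens`, `Q Exactive`); nothing was left unresolved. Label
expansion multiplied 2 runs by the 10 TMT channels into 20 sample rows.
The digest is computed over the canonical serialization, so it identifies
the table's content independent of column order or header casing.

The other examples cover ontology artifact building and autocomplete
search (`01`), species templates and the file limit (`02`), partial-file
merging and presets (`04`), and the adoption/funnel arithmetic (`05`).

The same pipeline is available from a shell:

```bash
sdrfkit template human --files run_001.raw,run_002.raw -o exp.sdrf.tsv
sdrfkit map exp.sdrf.tsv meta.tsv --map "organism:characteristics[organism]"
sdrfkit expand exp.sdrf.tsv --scheme TMT10plex
sdrfkit validate exp.sdrf.tsv --species human   # exit 1 on errors
sdrfkit hash exp.sdrf.tsv --sidecar
```

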