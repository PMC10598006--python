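"""The full five-step workflow: template, files, metadata mapping, label
expansion, column filling, validation and the submission digest.

Synonym spellings in the local metadata ("human", "QE") are rewritten to
their canonical ontology labels during mapping; TMT expansion turns each
run into ten channel rows; validation checks required columns, vocabulary
compliance and the key=value grammar of modification/cleavage cells.
"""

import sdrfkit as sk

indices = sk.toy_binding_indices()
templates = sk.load_template_registry()
schemes = sk.load_label_schemes()

table = sk.create_template("human", templates)
table = sk.set_raw_files(table, ["run_001.raw", "run_002.raw"])

metadata = sk.read_local_metadata(sk.generate_toy_metadata(2, seed=3))
mapping = sk.ColumnMapping.of(
    {
        "organism": "characteristics[organism]",
        "organism part": "characteristics[organism part]",
        "instrument": "comment[instrument]",
        "disease": "characteristics[disease]",
    }
)
table, report = sk.map_metadata(table, metadata, mapping, indices)
for pair in report.pairs:
    print(
        f"{pair.local_column!r} -> {pair.target.render()}: "
        f"{pair.resolved_count} exact, {pair.synonym_resolved_count} synonym-rewritten, "
        f"{len(pair.unresolved_values)} unresolved"
    )

table = sk.expand_labels(table, schemes["TMT10plex"])
print(f"\nafter TMT10plex expansion: {table.n_rows} rows (2 files x 10 channels)")

table = sk.fill_column(table, "comment[cleavage agent details]", "NT=Trypsin")
table = sk.fill_column(
    table, "comment[modification parameters]",
    "NT=Oxidation;AC=UNIMOD:35;MT=Variable;TA=M",
)
table = sk.fill_column(table, "technology type",
                       "proteomic profiling by mass spectrometry")
table = sk.fill_column(table, "comment[fraction identifier]", "1")
for header in ("characteristics[cell type]", "characteristics[ancestry category]",
               "characteristics[age]", "characteristics[sex]"):
    table = sk.fill_column(table, header, sk.NOT_APPLICABLE)

validation = sk.validate_table(table, templates["human"], indices)
print(f"validation passed: {validation.passed} "
      f"({len(validation.errors)} errors, {len(validation.warnings)} warnings)")

digest = sk.stamp_hash(sk.write_sdrf(table))
print(f"submission digest ({digest.algorithm}): {digest.digest}")
# the digest is over the canonical serialization, so it identifies the
# table's content regardless of column order or header casing
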