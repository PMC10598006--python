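"""Partial-file continuation and one-click column presets.

Datasets larger than one session are annotated in partial SDRF files and
merged back into a templated table: annotated cells win over template
defaults, keyed by raw file name. Presets add community column bundles
(here: metaproteomics) in one call, idempotently.
"""

import sdrfkit as sk

templates = sk.load_template_registry()
indices = sk.toy_binding_indices()

# a partial SDRF annotated elsewhere, covering two files
partial = sk.set_raw_files(
    sk.create_template("default", templates), ["a.raw", "b.raw"]
)
partial = sk.fill_column(
    partial, "characteristics[organism]", "Homo sapiens",
    index=indices["characteristics[organism]"],
)

# a fresh template session listing an extra, third file
session = sk.set_raw_files(
    sk.create_template("default", templates), ["a.raw", "b.raw", "c.raw"]
)

merged = sk.merge_partial(partial, session)
print(f"merged: {merged.n_rows} rows over files {merged.data_files()}")
print("organisms:", merged.column_values("characteristics[organism]"))
# a.raw/b.raw keep the partial's annotation; c.raw stays 'not available'

with_preset = sk.apply_preset(merged, "metaproteomics")
added = [c.render() for c in with_preset.columns if not merged.has_column(c)]
print(f"metaproteomics preset added {len(added)} columns: {added}")
assert sk.apply_preset(with_preset, "metaproteomics") == with_preset  # idempotent
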