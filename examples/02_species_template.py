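"""Start an SDRF from a species template and register raw files.

The species template supplies the required columns; registering raw file
names creates one row per file with auto-named samples and assay runs. A
session accepts at most 250 files.
"""

import sdrfkit as sk
from sdrfkit.errors import FileLimitError

table = sk.create_template("human")
print(f"human template: {table.n_columns} required columns, {table.n_rows} rows")
print("columns:", ", ".join(c.render() for c in table.columns))

table = sk.set_raw_files(table, ["run_001.raw", "run_002.raw", "run_003.raw"])
print(f"\nafter registering 3 files: {table.n_rows} rows")
print(sk.write_sdrf(table))

# the 250-file cap keeps interactive sessions responsive; larger datasets
# are annotated as partial files and merged
try:
    sk.set_raw_files(sk.create_template("human"), [f"f{i}.raw" for i in range(251)])
except FileLimitError as exc:
    print("251 files refused:", exc)
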