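"""The five-step annotation workflow as composable operations.

A typical session: start a species template, register the raw file names,
map a local metadata table onto SDRF columns (rewriting synonyms to their
canonical ontology labels as it goes), expand rows over the label channels
of a multiplexing scheme (TMT, SILAC, iTRAQ — one SDRF row per channel per
run), fill the remaining required and optional columns with vocabulary
terms, and finally stamp the canonical serialization with a SHA-256 digest
that downstream submission systems can verify.

Every operation returns a new table (value semantics) and the vocabulary-
constrained ones are atomic: a single unresolvable value fails the whole
call and leaves the input untouched.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .errors import (
    AlignmentError,
    DoubleExpansionError,
    FileLimitError,
    InputError,
    MappingError,
    MergeConflictError,
    MergeKeyError,
    PresetError,
    SdrfParseError,
    TermResolutionError,
)
from .model import (
    MAX_FILES_PER_SESSION,
    MISSING_TOKENS,
    NOT_AVAILABLE,
    UNIVERSAL_REQUIRED,
    ColumnKey,
    LabelScheme,
    SDRFTable,
    add_column,
    canonical_order,
    parse_sdrf,
    write_sdrf,
)

#: Tag naming the canonical form the submission hash is computed over:
#: canonical category order with columns sorted by rendered header within
#: each category (so any column permutation hashes identically), lowercase
#: headers, LF endings, single trailing newline, UTF-8 bytes.
CANONICALIZATION_TAG = "sdrf-canonical-v1"


# ---------------------------------------------------------------------------
# Local metadata input
# ---------------------------------------------------------------------------


def read_local_metadata(text: str, delimiter: str | None = None) -> list[dict[str, str]]:
    """Parse a local TSV/CSV metadata file into a list of row dicts.

    The delimiter is sniffed from the header line (tab beats comma) unless
    given explicitly. The first row is the header; values are stripped at
    the ends.
    """
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise InputError("metadata file is empty")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    rows = []
    for rec in reader:
        rows.append({(k or "").strip(): (v or "").strip() for k, v in rec.items()})
    return rows


# ---------------------------------------------------------------------------
# Metadata mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColumnMapping:
    """Pairs of (local metadata column name → target SDRF column)."""

    pairs: tuple[tuple[str, ColumnKey], ...]

    def __post_init__(self) -> None:
        locals_ = [p[0] for p in self.pairs]
        targets = [p[1] for p in self.pairs]
        if len(set(locals_)) != len(locals_):
            raise MappingError("local column names in a mapping must be unique")
        if len(set(targets)) != len(targets):
            raise MappingError("target columns in a mapping must be unique")

    @classmethod
    def of(cls, pairs: Mapping[str, ColumnKey | str]) -> "ColumnMapping":
        return cls(
            tuple(
                (local, t if isinstance(t, ColumnKey) else ColumnKey.parse(t))
                for local, t in pairs.items()
            )
        )


@dataclass
class PairReport:
    """Resolution tally for one mapped column pair.

    ``resolved_count`` counts cells accepted verbatim (exact label match, a
    missing-value token, or any value on an unbound free-text column);
    ``synonym_resolved_count`` counts cells rewritten to the canonical
    label; ``unresolved_values`` lists the distinct offending strings left
    in place. The three together partition the mapped cells.
    """

    local_column: str
    target: ColumnKey
    resolved_count: int = 0
    synonym_resolved_count: int = 0
    unresolved_values: list[str] = field(default_factory=list)
    unresolved_occurrences: int = 0


@dataclass
class MappingReport:
    pairs: list[PairReport] = field(default_factory=list)

    @property
    def total_unresolved_values(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.update(p.unresolved_values)
        return out


def _resolve_cell(value: str, index) -> tuple[str, str]:
    """Resolve one cell against a vocabulary-like object exposing
    ``resolve(value) -> (status, canonical) | None``.

    Returns (status, new_cell_value); missing-value tokens always pass as
    exact, unresolved values are left in place.
    """
    if value.strip().lower() in MISSING_TOKENS:
        return "exact", value
    hit = index.resolve(value)
    if hit is None:
        return "unresolved", value
    status, canonical = hit
    return status, canonical


def map_metadata(
    table: SDRFTable,
    local_rows: Sequence[Mapping[str, str]],
    mapping: ColumnMapping,
    indices: Mapping[str, object] | None = None,
    file_column: str | None = None,
) -> tuple[SDRFTable, MappingReport]:
    """Map local metadata columns onto SDRF columns with ontology compliance.

    Alignment is positional when ``len(local_rows)`` equals the table's row
    count and no ``file_column`` is named; otherwise rows are joined on
    ``file_column`` against comment[data file]. Each value is resolved
    against the vocabulary bound to the target column (``indices`` maps
    rendered headers to index-like objects): exact matches are kept in
    canonical casing, synonyms are rewritten to the canonical label, and
    anything else is left in place and reported unresolved. Columns with no
    binding accept free text verbatim.
    """
    indices = indices or {}
    for local, _target in mapping.pairs:
        if local_rows and any(local not in row for row in local_rows):
            raise MappingError(f"local metadata has no column {local!r}")

    out = table.copy()
    # row alignment: positional, or join on a declared file-name column
    if file_column is not None:
        if local_rows and any(file_column not in row for row in local_rows):
            raise MappingError(f"local metadata has no column {file_column!r}")
        if not out.has_column("comment[data file]"):
            raise AlignmentError("table has no comment[data file] column to join on")
        by_file = {}
        for rec in local_rows:
            k = rec[file_column]
            if k in by_file:
                raise AlignmentError(f"metadata lists file {k!r} twice")
            by_file[k] = rec
        aligned: list[Mapping[str, str] | None] = [
            by_file.get(f) for f in out.column_values("comment[data file]")
        ]
    elif len(local_rows) == out.n_rows:
        aligned = list(local_rows)
    else:
        raise AlignmentError(
            f"{len(local_rows)} metadata rows cannot be aligned positionally "
            f"with {out.n_rows} table rows and no join column was named"
        )

    report = MappingReport()
    for local, target in mapping.pairs:
        if not out.has_column(target):
            out = add_column(out, target)
        idx = out.column_index(target)
        binding = indices.get(target.render())
        pair = PairReport(local_column=local, target=target)
        for i, rec in enumerate(aligned):
            if rec is None:
                continue
            value = rec[local]
            if binding is None:
                out.rows[i][idx] = value
                pair.resolved_count += 1
                continue
            status, new_value = _resolve_cell(value, binding)
            if status == "exact":
                out.rows[i][idx] = new_value
                pair.resolved_count += 1
            elif status == "synonym":
                out.rows[i][idx] = new_value
                pair.synonym_resolved_count += 1
            else:
                out.rows[i][idx] = value
                if value not in pair.unresolved_values:
                    pair.unresolved_values.append(value)
                pair.unresolved_occurrences += 1
        report.pairs.append(pair)
    return out, report


# ---------------------------------------------------------------------------
# Label expansion
# ---------------------------------------------------------------------------


def expand_labels(table: SDRFTable, scheme: LabelScheme) -> SDRFTable:
    """Replace each row by one row per label channel.

    Multiplexed acquisitions pool several labeled samples into one raw file,
    so each file needs one SDRF row per channel: comment[label] carries the
    channel name and, for multi-channel schemes, source names gain a
    `` ch<j>`` suffix so each (sample, channel) stays unique. Row count
    becomes ``old count × |channels|`` with channel order preserved within
    each file block.
    """
    if table.n_rows == 0:
        raise InputError("cannot expand an empty table; register raw files first")
    out = table.copy()
    if not out.has_column("comment[label]"):
        out = add_column(out, "comment[label]")
    label_idx = out.column_index("comment[label]")
    if out.has_column("comment[data file]"):
        file_idx = out.column_index("comment[data file]")
        per_file: dict[str, set[str]] = {}
        for row in out.rows:
            per_file.setdefault(row[file_idx], set()).add(row[label_idx])
        for filename, labels in per_file.items():
            if set(scheme.channels) <= labels:
                raise DoubleExpansionError(
                    f"file {filename!r} already carries every channel of "
                    f"{scheme.name!r}; the table looks expanded already"
                )
    src_idx = out.column_index("source name") if out.has_column("source name") else None
    multi = len(scheme.channels) > 1
    new_rows: list[list[str]] = []
    for row in out.rows:
        for j, channel in enumerate(scheme.channels, start=1):
            new_row = list(row)
            new_row[label_idx] = channel
            if multi and src_idx is not None:
                new_row[src_idx] = f"{row[src_idx]} ch{j}"
            new_rows.append(new_row)
    out.rows = new_rows
    out.provenance["label_scheme"] = scheme.name
    return out


# ---------------------------------------------------------------------------
# Column filling
# ---------------------------------------------------------------------------


def fill_column(
    table: SDRFTable,
    col: ColumnKey | str,
    values: str | Sequence[str],
    index=None,
) -> SDRFTable:
    """Write a column: one value broadcast to every row, or one per row.

    When a vocabulary ``index`` is bound, every value must resolve (exact or
    synonym, rewritten to the canonical label) or the whole operation fails
    and the table is unchanged — mirroring drop-down-only entry.
    """
    if isinstance(col, str):
        col = ColumnKey.parse(col)
    idx = table.column_index(col)
    if isinstance(values, str):
        cells = [values] * table.n_rows
    else:
        cells = list(values)
        if len(cells) == 1:
            cells = cells * table.n_rows
        elif len(cells) != table.n_rows:
            raise AlignmentError(
                f"{len(cells)} values for {table.n_rows} rows in "
                f"{col.render()!r}"
            )
    if index is not None:
        resolved: list[str] = []
        offenders: list[str] = []
        for value in cells:
            status, new_value = _resolve_cell(value, index)
            if status == "unresolved":
                if value not in offenders:
                    offenders.append(value)
            else:
                resolved.append(new_value)
        if offenders:
            raise TermResolutionError(
                f"values not in the vocabulary bound to {col.render()!r}: "
                f"{offenders}"
            )
        cells = resolved
    out = table.copy()
    for i, cell in enumerate(cells):
        out.rows[i][idx] = cell
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Preset:
    """A named bundle of additional columns importable in one step (e.g. the
    metaproteomics community columns)."""

    name: str
    columns: tuple[ColumnKey, ...]

    def __post_init__(self) -> None:
        clash = [c.render() for c in self.columns if c in UNIVERSAL_REQUIRED]
        if clash:
            raise PresetError(
                f"preset {self.name!r} may not redefine universal required "
                f"columns: {clash}"
            )


def load_preset_registry(path: str | Path | None = None) -> dict[str, Preset]:
    if path:
        raw = json.loads(Path(path).read_text("utf-8"))
    else:
        raw = json.loads(
            resources.files("sdrfkit.data").joinpath("presets.json").read_text("utf-8")
        )
    return {
        name: Preset(name=name, columns=tuple(ColumnKey.parse(h) for h in headers))
        for name, headers in raw.items()
    }


def apply_preset(
    table: SDRFTable,
    preset: Preset | str,
    registry: Mapping[str, Preset] | None = None,
) -> SDRFTable:
    """Add every preset column not already present (cells default to
    ``not available``), at canonical positions. Idempotent."""
    if isinstance(preset, str):
        reg = registry if registry is not None else load_preset_registry()
        if preset not in reg:
            raise PresetError(f"unknown preset {preset!r}; available: {sorted(reg)}")
        preset = reg[preset]
    out = table
    for col in preset.columns:
        if not out.has_column(col):
            out = add_column(out, col)
    out = out.copy()
    applied = out.provenance.setdefault("presets", [])
    if preset.name not in applied:
        applied.append(preset.name)
    return out


# ---------------------------------------------------------------------------
# Submission hash
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionHash:
    """SHA-256 digest over the canonical serialization of an SDRF table.

    Because the digest is taken over the canonical form (column order,
    header casing and line endings normalized), semantically equal files
    hash identically while any cell edit changes the digest.
    """

    digest: str
    algorithm: str = "SHA-256"
    canonicalization: str = CANONICALIZATION_TAG


def canonical_bytes(table: SDRFTable) -> bytes:
    """The byte form the submission digest is computed over.

    Stricter than :func:`write_sdrf`'s insertion-stable ordering: within
    each category columns are sorted by rendered header, making the digest
    a pure function of table *content*, independent of column history.
    """
    by_header = sorted(table.columns, key=lambda c: c.render())
    final_cols = canonical_order(by_header)  # stable: header order kept per category
    col_to_index = {c: i for i, c in enumerate(table.columns)}
    perm = [col_to_index[c] for c in final_cols]
    strict = SDRFTable(
        columns=final_cols,
        rows=[[row[i] for i in perm] for row in table.rows],
    )
    return write_sdrf(strict).encode("utf-8")


def stamp_hash(sdrf_text: str) -> SessionHash:
    """Parse, canonicalize and hash SDRF text. Invalid files get no hash."""
    table = parse_sdrf(sdrf_text)
    if table.n_rows == 0:
        raise SdrfParseError("refusing to stamp an SDRF with no data rows")
    digest = hashlib.sha256(canonical_bytes(table)).hexdigest()
    return SessionHash(digest=digest)


def write_hash_sidecar(hash_: SessionHash, sdrf_path: str | Path) -> Path:
    """Write the checksum sidecar ``<name>.sha256`` next to the SDRF file,
    in the conventional ``<digest>  <filename>`` form."""
    sdrf_path = Path(sdrf_path)
    sidecar = sdrf_path.with_name(sdrf_path.name + ".sha256")
    sidecar.write_text(f"{hash_.digest}  {sdrf_path.name}\n", encoding="utf-8")
    return sidecar


# ---------------------------------------------------------------------------
# Partial-file continuation
# ---------------------------------------------------------------------------


def _row_map(table: SDRFTable, what: str) -> dict[str, list[str]]:
    file_idx = table.column_index("comment[data file]")
    out: dict[str, list[str]] = {}
    for row in table.rows:
        k = row[file_idx]
        if k in out:
            raise MergeKeyError(
                f"{what} table lists data file {k!r} twice; merge operates on "
                f"pre-expansion tables keyed by file"
            )
        out[k] = row
    return out


def merge_partial(partial: SDRFTable, template: SDRFTable) -> SDRFTable:
    """Merge a partially annotated SDRF into a (templated) table.

    Rows are keyed by comment[data file]; the merged table takes the union
    of columns in canonical order. Non-default cells from the partial win
    over template defaults; two disagreeing non-default cells are a
    conflict. The merged table may not exceed the per-session file limit.
    """
    for t, what in ((partial, "partial"), (template, "template")):
        for col in UNIVERSAL_REQUIRED:
            if not t.has_column(col):
                raise MergeKeyError(
                    f"{what} table lacks required column {col.render()!r}"
                )
    p_rows = _row_map(partial, "partial")
    t_rows = _row_map(template, "template")
    all_files = list(t_rows) + [f for f in p_rows if f not in t_rows]
    if len(all_files) > MAX_FILES_PER_SESSION:
        raise FileLimitError(
            f"merged table would hold {len(all_files)} distinct files, over "
            f"the limit of {MAX_FILES_PER_SESSION}"
        )
    columns = list(template.columns) + [
        c for c in partial.columns if c not in template.columns
    ]
    columns = canonical_order(columns)
    src_key = ColumnKey.parse("source name")

    def cell_of(table: SDRFTable, row: list[str] | None, col: ColumnKey) -> str:
        if row is None or not table.has_column(col):
            return NOT_AVAILABLE
        return row[table.column_index(col)]

    rows: list[list[str]] = []
    for filename in all_files:
        p_row = p_rows.get(filename)
        t_row = t_rows.get(filename)
        merged: list[str] = []
        for col in columns:
            p_cell = cell_of(partial, p_row, col)
            t_cell = cell_of(template, t_row, col)
            p_set = p_cell.strip().lower() not in MISSING_TOKENS
            t_set = t_cell.strip().lower() not in MISSING_TOKENS
            if p_set and t_set and p_cell != t_cell:
                if col == src_key:
                    raise MergeKeyError(
                        f"data file {filename!r} has different source names: "
                        f"{p_cell!r} vs {t_cell!r}"
                    )
                raise MergeConflictError(
                    f"conflicting values for file {filename!r}, column "
                    f"{col.render()!r}: {p_cell!r} vs {t_cell!r}"
                )
            merged.append(p_cell if p_set else (t_cell if t_set else NOT_AVAILABLE))
        rows.append(merged)
    return SDRFTable(
        columns=columns,
        rows=rows,
        provenance={**template.provenance, "merged_from_partial": True},
    )
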