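"""The SDRF-Proteomics table model.

SDRF (Sample and Data Relationship Format) is a tab-delimited table mapping
raw mass-spectrometry data files to sample characteristics. Each column
belongs to one of six categories — ``source name``, ``characteristics[...]``,
``technology type``, ``assay name``, ``comment[...]``, ``factor value[...]``
— rendered as lowercase headers; each row describes one sample-in-a-run
(after label expansion, one label channel of one run).

:class:`SDRFTable` is the central artifact of the whole package: an ordered
list of :class:`ColumnKey` plus rectangular string rows. All operations have
value semantics — they return a new table and never mutate their input —
so a failed step can never leave a half-written table behind.

Species templates provide the required columns to start a table from;
registering raw files adds one row per file, capped at
:data:`MAX_FILES_PER_SESSION` files per session to keep interactive
annotation responsive. Larger datasets are annotated in partial files and
merged (see :func:`sdrfkit.workflow.merge_partial`).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    ColumnKeyError,
    DuplicateColumnError,
    DuplicateFileError,
    FileLimitError,
    InputError,
    SdrfParseError,
    SerializationError,
    TemplateError,
)

#: Upper bound on raw files registered in one session/table (pre-expansion).
MAX_FILES_PER_SESSION = 250

#: Cell token for a value that exists but is unknown.
NOT_AVAILABLE = "not available"
#: Cell token for a value that is semantically void for this sample.
NOT_APPLICABLE = "not applicable"
#: Tokens that always pass term checks (but still count as empty for the
#: hard-required identity cells).
MISSING_TOKENS = frozenset({NOT_AVAILABLE, NOT_APPLICABLE, ""})

# Category identifiers, in canonical column order.
SOURCE_NAME = "source_name"
CHARACTERISTICS = "characteristics"
TECHNOLOGY_TYPE = "technology_type"
ASSAY_NAME = "assay_name"
COMMENT = "comment"
FACTOR_VALUE = "factor_value"

_CATEGORY_RANK = {
    SOURCE_NAME: 0,
    CHARACTERISTICS: 1,
    TECHNOLOGY_TYPE: 2,
    ASSAY_NAME: 3,
    COMMENT: 4,
    FACTOR_VALUE: 5,
}

_BRACKETED = {
    "characteristics": CHARACTERISTICS,
    "comment": COMMENT,
    "factor value": FACTOR_VALUE,
}
_BARE = {
    "source name": SOURCE_NAME,
    "assay name": ASSAY_NAME,
    "technology type": TECHNOLOGY_TYPE,
}
_HEADER_RE = re.compile(r"^\s*(characteristics|comment|factor value)\s*\[(.+)\]\s*$", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class ColumnKey:
    """A typed SDRF column: a category plus an attribute.

    The attribute is non-empty exactly for the bracketed categories
    (characteristics, comment, factor value); it is stored lowercase, as
    SDRF headers are compared case-insensitively and emitted lowercase.
    """

    category: str
    attribute: str = ""

    def __post_init__(self) -> None:
        if self.category not in _CATEGORY_RANK:
            raise ColumnKeyError(f"unknown column category {self.category!r}")
        bracketed = self.category in (CHARACTERISTICS, COMMENT, FACTOR_VALUE)
        if bracketed and not self.attribute:
            raise ColumnKeyError(f"{self.category} column needs an attribute")
        if not bracketed and self.attribute:
            raise ColumnKeyError(f"{self.category} column takes no attribute")
        object.__setattr__(self, "attribute", self.attribute.strip().lower())

    def render(self) -> str:
        """The lowercase header as written to a file."""
        if self.category == SOURCE_NAME:
            return "source name"
        if self.category == ASSAY_NAME:
            return "assay name"
        if self.category == TECHNOLOGY_TYPE:
            return "technology type"
        word = {CHARACTERISTICS: "characteristics", COMMENT: "comment", FACTOR_VALUE: "factor value"}[self.category]
        return f"{word}[{self.attribute}]"

    @classmethod
    def parse(cls, header: str) -> "ColumnKey":
        """Parse a header token case-insensitively."""
        bare = header.strip().lower()
        if bare in _BARE:
            return cls(_BARE[bare])
        m = _HEADER_RE.match(header)
        if m:
            return cls(_BRACKETED[m.group(1).lower()], m.group(2).strip().lower())
        raise ColumnKeyError(f"unrecognized SDRF header {header!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def key(header: str) -> ColumnKey:
    """Shorthand: ``key("comment[label]")`` → :class:`ColumnKey`."""
    return ColumnKey.parse(header)


def canonical_order(columns: Sequence[ColumnKey]) -> list[ColumnKey]:
    """Sort columns into canonical SDRF order.

    source name, then characteristics, technology type, assay name, comment,
    and factor value last; within a category the original (insertion) order
    is preserved. Idempotent, and a pure permutation of its input.
    """
    return sorted(columns, key=lambda c: _CATEGORY_RANK[c.category])


@dataclass
class SDRFTable:
    """An ordered, rectangular SDRF table with value semantics.

    ``provenance`` is a free-form note (template species, presets applied)
    carried through operations but ignored by equality and serialization.
    """

    columns: list[ColumnKey]
    rows: list[list[str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[ColumnKey] = set()
        for col in self.columns:
            if col in seen:
                raise DuplicateColumnError(f"duplicate column {col.render()!r}")
            seen.add(col)

    # -- equality ignores provenance: two tables are equal when they would
    # serialize identically
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SDRFTable):
            return NotImplemented
        return self.columns == other.columns and self.rows == other.rows

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def copy(self) -> "SDRFTable":
        return SDRFTable(
            columns=list(self.columns),
            rows=[list(r) for r in self.rows],
            provenance=dict(self.provenance),
        )

    def column_index(self, col: ColumnKey | str) -> int:
        if isinstance(col, str):
            col = ColumnKey.parse(col)
        try:
            return self.columns.index(col)
        except ValueError:
            raise ColumnKeyError(f"table has no column {col.render()!r}") from None

    def has_column(self, col: ColumnKey | str) -> bool:
        if isinstance(col, str):
            col = ColumnKey.parse(col)
        return col in self.columns

    def column_values(self, col: ColumnKey | str) -> list[str]:
        idx = self.column_index(col)
        return [row[idx] for row in self.rows]

    def data_files(self) -> list[str]:
        """Distinct comment[data file] values in first-appearance order."""
        if not self.has_column("comment[data file]"):
            return []
        seen: dict[str, None] = {}
        for value in self.column_values("comment[data file]"):
            seen.setdefault(value, None)
        return list(seen)

    def check_rectangular(self) -> None:
        for i, row in enumerate(self.rows, start=2):
            if len(row) != len(self.columns):
                raise SdrfParseError(
                    f"row at line {i} has {len(row)} cells, expected {len(self.columns)}"
                )

    def to_dataframe(self):
        """Render as a pandas DataFrame (headers as column names)."""
        import pandas as pd

        return pd.DataFrame(
            [list(r) for r in self.rows],
            columns=[c.render() for c in self.columns],
        )


# ---------------------------------------------------------------------------
# Species templates
# ---------------------------------------------------------------------------

#: Columns every template must include, whatever the species.
UNIVERSAL_REQUIRED = (
    ColumnKey(SOURCE_NAME),
    ColumnKey(CHARACTERISTICS, "organism"),
    ColumnKey(ASSAY_NAME),
    ColumnKey(COMMENT, "data file"),
    ColumnKey(TECHNOLOGY_TYPE),
)


@dataclass(frozen=True)
class SpeciesTemplate:
    """Per-species list of required SDRF columns."""

    species_key: str
    required_columns: tuple[ColumnKey, ...]

    def __post_init__(self) -> None:
        missing = [c.render() for c in UNIVERSAL_REQUIRED if c not in self.required_columns]
        if missing:
            raise TemplateError(
                f"template {self.species_key!r} lacks universal required "
                f"columns: {missing}"
            )


def _load_packaged_json(filename: str) -> dict:
    data = resources.files("sdrfkit.data").joinpath(filename).read_text("utf-8")
    return json.loads(data)


def load_template_registry(path: str | Path | None = None) -> dict[str, SpeciesTemplate]:
    """Load the species-template registry: packaged defaults, or a JSON file
    mapping species key → list of headers."""
    raw = json.loads(Path(path).read_text("utf-8")) if path else _load_packaged_json("species_templates.json")
    registry: dict[str, SpeciesTemplate] = {}
    for species, headers in raw.items():
        registry[species.lower()] = SpeciesTemplate(
            species_key=species.lower(),
            required_columns=tuple(ColumnKey.parse(h) for h in headers),
        )
    return registry


def create_template(
    species_key: str,
    templates: Mapping[str, SpeciesTemplate] | None = None,
) -> SDRFTable:
    """Start a zero-row table from a species template (case-insensitive key)."""
    registry = templates if templates is not None else load_template_registry()
    template = registry.get(species_key.strip().lower())
    if template is None:
        raise TemplateError(
            f"unknown species {species_key!r}; available: {sorted(registry)}"
        )
    return SDRFTable(
        columns=canonical_order(template.required_columns),
        rows=[],
        provenance={"species": template.species_key},
    )


# ---------------------------------------------------------------------------
# Label schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelScheme:
    """A named, ordered list of label channels (e.g. the ten TMT10plex
    reporter channels). The special single-channel scheme
    ``"label free sample"`` marks unlabeled runs."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.channels:
            raise InputError(f"label scheme {self.name!r} has no channels")
        if len(set(self.channels)) != len(self.channels):
            raise InputError(f"label scheme {self.name!r} repeats a channel name")


def load_label_schemes(path: str | Path | None = None) -> dict[str, LabelScheme]:
    raw = json.loads(Path(path).read_text("utf-8")) if path else _load_packaged_json("label_schemes.json")
    return {
        name: LabelScheme(name=name, channels=tuple(channels))
        for name, channels in raw.items()
    }


# ---------------------------------------------------------------------------
# Parse / serialize
# ---------------------------------------------------------------------------


def parse_sdrf(text: str) -> SDRFTable:
    """Parse tab-delimited SDRF text.

    The first line is the header; fields are separated by single tabs with
    no quoting dialect (SDRF has none). Headers parse case-insensitively;
    cell whitespace is trimmed at the ends only. Ragged rows are rejected
    with their 1-based line number.
    """
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()  # single trailing newline
    if not lines or not lines[0].strip():
        raise SdrfParseError("empty SDRF: no header line")
    header_tokens = lines[0].rstrip("\r").split("\t")
    columns: list[ColumnKey] = []
    for ordinal, token in enumerate(header_tokens, start=1):
        try:
            columns.append(ColumnKey.parse(token))
        except ColumnKeyError as exc:
            raise SdrfParseError(f"header column {ordinal}: {exc}") from exc
    try:
        table = SDRFTable(columns=columns)
    except DuplicateColumnError as exc:
        raise SdrfParseError(str(exc)) from exc
    for line_no, line in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in line.rstrip("\r").split("\t")]
        if len(cells) != len(columns):
            raise SdrfParseError(
                f"row at line {line_no} has {len(cells)} cells, "
                f"expected {len(columns)}"
            )
        table.rows.append(cells)
    return table


def write_sdrf(table: SDRFTable) -> str:
    """Serialize a table: canonical column order, lowercase headers, LF
    endings, one trailing newline, UTF-8 text, no quoting.

    Refuses tables that violate invariants (ragged rows, cells containing
    tabs or newlines, missing/duplicated source name column).
    """
    table.check_rectangular()
    if sum(1 for c in table.columns if c.category == SOURCE_NAME) != 1:
        raise SerializationError("table must have exactly one source name column")
    for i, row in enumerate(table.rows, start=1):
        for col, cell in zip(table.columns, row):
            if "\t" in cell or "\n" in cell or "\r" in cell:
                raise SerializationError(
                    f"cell at row {i}, column {col.render()!r} contains a tab "
                    f"or newline; SDRF cells cannot be quoted"
                )
    order = canonical_order(table.columns)
    perm = [table.columns.index(c) for c in order]
    lines = ["\t".join(c.render() for c in order)]
    for row in table.rows:
        lines.append("\t".join(row[i] for i in perm))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Table operations
# ---------------------------------------------------------------------------


def add_column(
    table: SDRFTable, col: ColumnKey | str, default_cell: str = NOT_AVAILABLE
) -> SDRFTable:
    """Insert a column at its canonical position, filling existing rows with
    ``default_cell``. Adding an already-present full header is an error."""
    if isinstance(col, str):
        col = ColumnKey.parse(col)
    if table.has_column(col):
        raise DuplicateColumnError(f"column {col.render()!r} already present")
    new_cols = canonical_order(list(table.columns) + [col])
    pos = new_cols.index(col)
    out = table.copy()
    out.columns = new_cols
    out.rows = [row[:pos] + [default_cell] + row[pos:] for row in out.rows]
    return out


def drop_column(table: SDRFTable, col: ColumnKey | str) -> SDRFTable:
    """Remove a column (the inverse of :func:`add_column` for fresh columns)."""
    idx = table.column_index(col)
    out = table.copy()
    out.columns = out.columns[:idx] + out.columns[idx + 1 :]
    out.rows = [row[:idx] + row[idx + 1 :] for row in out.rows]
    return out


def set_raw_files(table: SDRFTable, filenames: Sequence[str]) -> SDRFTable:
    """Register raw data files: one new row per file.

    comment[data file] is set to the file name; blank source names are
    auto-named ``sample <i>`` and assay names ``run <i>`` (1-based). At most
    :data:`MAX_FILES_PER_SESSION` files per call and per table; duplicates
    are rejected.
    """
    if not filenames:
        raise InputError("no raw file names given")
    if any(not f or not f.strip() for f in filenames):
        raise InputError("raw file names must be non-empty strings")
    seen: set[str] = set()
    for f in filenames:
        if f in seen:
            raise DuplicateFileError(f"raw file {f!r} listed twice")
        seen.add(f)
    if len(filenames) > MAX_FILES_PER_SESSION:
        raise FileLimitError(
            f"{len(filenames)} files exceed the limit of "
            f"{MAX_FILES_PER_SESSION} files per session"
        )
    out = table.copy()
    for needed in ("comment[data file]",):
        if not out.has_column(needed):
            out = add_column(out, needed)
    existing = set(out.data_files())
    overlap = existing.intersection(filenames)
    if overlap:
        raise DuplicateFileError(f"raw files already registered: {sorted(overlap)}")
    if len(existing) + len(filenames) > MAX_FILES_PER_SESSION:
        raise FileLimitError(
            f"table would hold {len(existing) + len(filenames)} distinct files, "
            f"over the limit of {MAX_FILES_PER_SESSION}"
        )
    src_idx = out.column_index("source name") if out.has_column("source name") else None
    assay_idx = out.column_index("assay name") if out.has_column("assay name") else None
    file_idx = out.column_index("comment[data file]")
    start = out.n_rows
    for offset, filename in enumerate(filenames):
        i = start + offset + 1
        row = [NOT_AVAILABLE] * out.n_columns
        row[file_idx] = filename
        if src_idx is not None:
            row[src_idx] = f"sample {i}"
        if assay_idx is not None:
            row[assay_idx] = f"run {i}"
        out.rows.append(row)
    return out
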