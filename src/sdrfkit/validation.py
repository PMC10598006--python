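"""Structural and ontology-compliance validation of SDRF tables.

Validation never raises on bad content: it returns a
:class:`ValidationReport` of :class:`Finding` records, each carrying a
machine-readable code from the closed :data:`FINDING_CODES` registry, a
severity, and a (row, column) location. ``passed`` is true exactly when no
finding has error severity.

Two cell grammars get special treatment: comment[modification parameters]
and comment[cleavage agent details] hold ``KEY=value`` lists (e.g.
``NT=Oxidation;AC=UNIMOD:35;MT=Variable;TA=M``) whose structure is checked
by :func:`parse_key_value_cell`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import KeyValueCellError
from .model import (
    MAX_FILES_PER_SESSION,
    MISSING_TOKENS,
    ColumnKey,
    SDRFTable,
    SpeciesTemplate,
)

#: The closed registry of finding codes.
FINDING_CODES: dict[str, str] = {
    "REQUIRED_MISSING": "a column required by the species template is absent",
    "REQUIRED_EMPTY": "a hard-required identity cell (source name, data file, "
    "organism) is blank or a missing-value token",
    "TERM_UNRESOLVED": "a cell on an ontology-bound column matches neither a "
    "label nor a synonym of the bound vocabulary",
    "TERM_SYNONYM": "a cell matches a synonym; the canonical label is suggested",
    "KV_MALFORMED": "a key=value cell contains a token without '='",
    "KV_DUPLICATE": "a key=value cell repeats a key",
    "KV_NO_NAME": "a key=value cell lacks the mandatory NT (name) key",
    "KV_UNKNOWN_KEY": "a key=value cell uses a key outside the recognized set",
    "RAGGED_ROW": "a row's cell count differs from the column count",
    "FILE_LIMIT": f"more than {MAX_FILES_PER_SESSION} distinct data files",
    "FACTOR_ORPHAN": "a factor value[x] column has no characteristics[x] "
    "column describing the varied property",
}

#: Recognized keys in modification / cleavage key=value cells.
KV_KEYS = ("NT", "AC", "MT", "PP", "TA", "TS", "CS", "MM")


@dataclass(frozen=True)
class Finding:
    """One validation finding. ``row`` is 1-based (0 = header, None = whole
    table); ``column`` is the rendered header when applicable."""

    severity: str  # "error" | "warning"
    code: str
    message: str
    row: int | None = None
    column: str | None = None

    def __post_init__(self) -> None:
        assert self.severity in ("error", "warning")
        assert self.code in FINDING_CODES, f"unregistered code {self.code}"

    def to_dict(self) -> dict:
        return {
            "severity": self.severity,
            "code": self.code,
            "row": self.row,
            "column": self.column,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    def codes(self) -> set[str]:
        return {f.code for f in self.findings}

    def to_json_obj(self) -> dict:
        return {
            "passed": self.passed,
            "findings": [f.to_dict() for f in self.findings],
        }

    def to_text(self) -> str:
        if not self.findings:
            return "valid SDRF: no findings\n"
        lines = []
        for f in self.findings:
            loc = []
            if f.row is not None:
                loc.append("header" if f.row == 0 else f"row {f.row}")
            if f.column is not None:
                loc.append(f.column)
            where = " @ " + ", ".join(loc) if loc else ""
            lines.append(f"{f.severity.upper()} {f.code}{where}: {f.message}")
        lines.append(f"=> {'PASSED' if self.passed else 'FAILED'} "
                     f"({len(self.errors)} errors, {len(self.warnings)} warnings)")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# key=value cell grammar
# ---------------------------------------------------------------------------


@dataclass
class KeyValueCell:
    """Parsed ``KEY=value;KEY=value`` cell. Recognized keys: NT (name),
    AC (accession), MT (modification type), PP (position), TA (target amino
    acid), TS (target site), CS (cleavage site), MM (monoisotopic mass, Da).
    Unknown keys are kept and flagged rather than rejected — the format
    grows keys over time."""

    entries: dict[str, str]
    unknown_keys: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return self.entries["NT"]


def parse_key_value_cell(text: str) -> KeyValueCell:
    """Parse one key=value cell; raises :class:`KeyValueCellError` (carrying
    the finding code) on malformed tokens, duplicate keys or a missing NT."""
    entries: dict[str, str] = {}
    unknown: list[str] = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" not in token:
            raise KeyValueCellError(
                "KV_MALFORMED", f"token {token!r} has no '=' separator"
            )
        k, _, v = token.partition("=")
        k = k.strip().upper()
        if k in entries:
            raise KeyValueCellError("KV_DUPLICATE", f"key {k!r} repeated")
        entries[k] = v.strip()
        if k not in KV_KEYS:
            unknown.append(k)
    if "NT" not in entries:
        raise KeyValueCellError("KV_NO_NAME", "mandatory NT (name) key missing")
    return KeyValueCell(entries=entries, unknown_keys=tuple(unknown))


# ---------------------------------------------------------------------------
# Term resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Resolution:
    status: str  # "exact" | "synonym" | "unresolved" | "unbound"
    canonical: str | None = None


def resolve_term(
    value: str,
    col: ColumnKey | str,
    indices: Mapping[str, object] | None,
) -> Resolution:
    """Resolve one cell value against the vocabulary bound to its column.

    ``indices`` maps rendered headers to vocabulary-like objects exposing
    ``resolve(value) -> (status, canonical) | None`` (a
    :class:`~sdrfkit.ontology.TermIndex`, a
    :class:`~sdrfkit.ontology.ModificationCatalog`, or a
    :class:`LabelVocabulary`). Columns with no binding are free text and
    return ``unbound``; missing-value tokens always pass as exact.
    """
    if isinstance(col, str):
        col = ColumnKey.parse(col)
    binding = (indices or {}).get(col.render())
    if binding is None:
        return Resolution(status="unbound")
    if value.strip().lower() in MISSING_TOKENS:
        return Resolution(status="exact", canonical=value)
    hit = binding.resolve(value)
    if hit is None:
        return Resolution(status="unresolved")
    status, canonical = hit
    return Resolution(status=status, canonical=canonical)


class LabelVocabulary:
    """Vocabulary adapter over label schemes: the valid values of
    comment[label] are the channel names of every registered scheme."""

    def __init__(self, schemes) -> None:
        self._channels: dict[str, str] = {}
        for scheme in schemes.values() if isinstance(schemes, Mapping) else schemes:
            for channel in scheme.channels:
                self._channels[channel.casefold()] = channel

    def resolve(self, value: str):
        canonical = self._channels.get(value.strip().casefold())
        if canonical is None:
            return None
        return "exact", canonical


# ---------------------------------------------------------------------------
# Table validation
# ---------------------------------------------------------------------------

#: Columns whose empty/missing-token cells are hard errors.
HARD_REQUIRED = ("source name", "comment[data file]", "characteristics[organism]")

#: Columns whose cells follow the key=value grammar.
KV_COLUMNS = ("comment[modification parameters]", "comment[cleavage agent details]")


def validate_required(
    table: SDRFTable, template: SpeciesTemplate
) -> list[Finding]:
    """Template-required column presence plus hard-required cell content."""
    findings: list[Finding] = []
    for col in template.required_columns:
        if not table.has_column(col):
            findings.append(
                Finding(
                    severity="error",
                    code="REQUIRED_MISSING",
                    row=0,
                    column=col.render(),
                    message=f"required column {col.render()!r} is missing "
                    f"(template {template.species_key!r})",
                )
            )
    for header in HARD_REQUIRED:
        if not table.has_column(header):
            continue
        for i, value in enumerate(table.column_values(header), start=1):
            if value.strip().lower() in MISSING_TOKENS:
                findings.append(
                    Finding(
                        severity="error",
                        code="REQUIRED_EMPTY",
                        row=i,
                        column=header,
                        message=f"{header} must not be empty or a "
                        f"missing-value token (found {value!r})",
                    )
                )
    return findings


def _validate_kv_cell(
    value: str, row: int, header: str, binding
) -> list[Finding]:
    findings: list[Finding] = []
    try:
        cell = parse_key_value_cell(value)
    except KeyValueCellError as exc:
        findings.append(
            Finding(severity="error", code=exc.code, row=row, column=header,
                    message=str(exc))
        )
        return findings
    for k in cell.unknown_keys:
        findings.append(
            Finding(
                severity="warning",
                code="KV_UNKNOWN_KEY",
                row=row,
                column=header,
                message=f"unrecognized key {k!r} (known: {', '.join(KV_KEYS)})",
            )
        )
    if binding is not None:
        hit = binding.resolve(cell.name)
        if hit is None:
            findings.append(
                Finding(
                    severity="warning",
                    code="TERM_UNRESOLVED",
                    row=row,
                    column=header,
                    message=f"NT={cell.name!r} is not in the bound catalog",
                )
            )
    return findings


def validate_table(
    table: SDRFTable,
    template: SpeciesTemplate,
    indices: Mapping[str, object] | None = None,
) -> ValidationReport:
    """Full validation: required columns and cells, rectangularity, per-cell
    term resolution on bound columns, key=value grammar, the per-session
    file limit, and factor-value orphans.

    Severity policy: an unresolved term is an error on a template-required
    column but only a warning on an additional column; synonym matches warn
    with the canonical label suggested.
    """
    indices = indices or {}
    findings: list[Finding] = list(validate_required(table, template))

    for i, row in enumerate(table.rows, start=1):
        if len(row) != table.n_columns:
            findings.append(
                Finding(
                    severity="error",
                    code="RAGGED_ROW",
                    row=i,
                    message=f"row has {len(row)} cells, expected {table.n_columns}",
                )
            )
    ragged_rows = {f.row for f in findings if f.code == "RAGGED_ROW"}

    required_headers = {c.render() for c in template.required_columns}
    for col in table.columns:
        header = col.render()
        binding = indices.get(header)
        is_kv = header in KV_COLUMNS
        if binding is None and not is_kv:
            continue
        idx = table.column_index(col)
        for i, row in enumerate(table.rows, start=1):
            if i in ragged_rows or idx >= len(row):
                continue
            value = row[idx]
            if value.strip().lower() in MISSING_TOKENS:
                continue
            if is_kv:
                findings.extend(_validate_kv_cell(value, i, header, binding))
                continue
            res = resolve_term(value, col, indices)
            if res.status == "unresolved":
                severity = "error" if header in required_headers else "warning"
                findings.append(
                    Finding(
                        severity=severity,
                        code="TERM_UNRESOLVED",
                        row=i,
                        column=header,
                        message=f"{value!r} is not a label or synonym in the "
                        f"vocabulary bound to {header}",
                    )
                )
            elif res.status == "synonym":
                findings.append(
                    Finding(
                        severity="warning",
                        code="TERM_SYNONYM",
                        row=i,
                        column=header,
                        message=f"{value!r} is a synonym; canonical label is "
                        f"{res.canonical!r}",
                    )
                )

    n_files = len(table.data_files())
    if n_files > MAX_FILES_PER_SESSION:
        findings.append(
            Finding(
                severity="error",
                code="FILE_LIMIT",
                column="comment[data file]",
                message=f"{n_files} distinct data files exceed the limit of "
                f"{MAX_FILES_PER_SESSION}",
            )
        )

    characteristic_attrs = {
        c.attribute for c in table.columns if c.category == "characteristics"
    }
    for col in table.columns:
        if col.category == "factor_value" and col.attribute not in characteristic_attrs:
            findings.append(
                Finding(
                    severity="warning",
                    code="FACTOR_ORPHAN",
                    row=0,
                    column=col.render(),
                    message=f"factor value[{col.attribute}] has no matching "
                    f"characteristics[{col.attribute}] column",
                )
            )

    findings.sort(
        key=lambda f: (
            f.row if f.row is not None else -1,
            f.column or "",
            f.code,
        )
    )
    return ValidationReport(findings=findings)
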