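"""Exception hierarchy.

Every failure mode the engine can signal derives from :class:`SdrfKitError`
so callers (and the CLI) can catch one base class. Subclasses are grouped by
the module surface that raises them; messages always name the offending
artifact (stanza ordinal, line number, column header, file name) so errors
are actionable without a debugger.
"""

from __future__ import annotations


class SdrfKitError(Exception):
    """Base class for all errors raised by sdrfkit."""


# --- ontology store ---------------------------------------------------------


class OboParseError(SdrfKitError):
    """Malformed OBO input (a [Term] stanza missing id or name)."""


class CycleError(SdrfKitError):
    """is_a links form a cycle; the message lists one offending cycle."""


class DanglingParentError(SdrfKitError):
    """A parent CURIE does not correspond to any term in the graph."""


class TermListImportError(SdrfKitError):
    """Flat term-list JSON is not a list or a record is missing id/label."""


class ArtifactFormatError(SdrfKitError):
    """On-disk artifact is not a gzipped JSON file of a known shape."""


class ArtifactIntegrityError(SdrfKitError):
    """Gzipped artifact stream is truncated or corrupt."""


class UnknownTermError(SdrfKitError):
    """A CURIE was looked up that is not present in the graph."""


class QueryError(SdrfKitError):
    """Empty or whitespace-only search query."""


class CatalogSchemaError(SdrfKitError):
    """Modification-catalog CSV lacks a mandatory column."""


class CatalogDuplicateError(SdrfKitError):
    """Two catalog rows share one accession."""


# --- SDRF model -------------------------------------------------------------


class ColumnKeyError(SdrfKitError):
    """A header token does not match any recognized SDRF column pattern."""


class SdrfParseError(SdrfKitError):
    """Tab-delimited SDRF text could not be parsed (bad header or ragged row)."""


class SerializationError(SdrfKitError):
    """Table violates an invariant that forbids serialization (e.g. embedded tab)."""


class DuplicateColumnError(SdrfKitError):
    """Attempt to add a column whose full header already exists."""


class TemplateError(SdrfKitError):
    """Unknown species key; the message lists the available keys."""


class FileLimitError(SdrfKitError):
    """More than the per-session maximum of raw files (250)."""


class DuplicateFileError(SdrfKitError):
    """The same raw file name registered twice."""


class InputError(SdrfKitError):
    """Empty or otherwise unusable input collection."""


# --- annotation workflow ----------------------------------------------------


class MappingError(SdrfKitError):
    """Column mapping refers to a local column absent from the metadata file."""


class AlignmentError(SdrfKitError):
    """Row counts differ and no join column is available, or a per-row value
    list has the wrong length."""


class DoubleExpansionError(SdrfKitError):
    """Label expansion applied to a table already carrying every channel of
    the same scheme."""


class TermResolutionError(SdrfKitError):
    """fill_column values that do not resolve against the bound vocabulary;
    the message lists the offending values. The operation is atomic."""


class PresetError(SdrfKitError):
    """Unknown preset name; the message lists the registry."""


class MergeConflictError(SdrfKitError):
    """Two non-default cells disagree for the same (data file, column)."""


class MergeKeyError(SdrfKitError):
    """The same data file carries different source names across the inputs,
    or a data-file key is duplicated within one input."""


class KeyValueCellError(SdrfKitError):
    """Malformed key=value cell; carries the machine-readable finding code."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


# --- toolkit ----------------------------------------------------------------


class FixtureSpecError(SdrfKitError):
    """Inconsistent toy-ontology specification (e.g. depth > n_terms)."""


class DomainError(SdrfKitError):
    """Arithmetic input outside its domain (e.g. annotated > total)."""


class FunnelError(SdrfKitError):
    """A project-selection funnel step drives the running total negative."""
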