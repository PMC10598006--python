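"""Controlled-vocabulary ingestion, derived artifacts, and term search.

Ontologies arrive as OBO text (or as a flat term-list JSON for sources that
are only distributed as OWL/JSON term dumps) and are held as a
:class:`OntologyGraph` — a DAG of :class:`OntologyTerm` records. From a graph
three derived artifacts are built, mirroring how annotation front-ends cache
vocabularies:

* :class:`ElementList` — the flat, sorted list of every usable term label
  (autocomplete source, persisted as ``<name>_all_elements.json.gz``);
* :class:`NestedTree` — a recursive label → children mapping of the ontology
  tree (``<name>_tree.json.gz``); multi-parent terms are duplicated under
  each parent, i.e. the DAG is unrolled into a tree;
* :class:`SelectNodes` — the same tree shape but each node carries its CURIE,
  suitable for tree-select widgets (``<name>_nodes.json.gz``).

All artifacts exclude obsolete terms: an obsolete term must never be offered
for annotation. Artifacts are persisted as gzipped JSON with a fixed mtime so
identical inputs produce byte-identical files.

A :class:`TermIndex` supports exact/synonym resolution and ranked
autocomplete search; :class:`ModificationCatalog` holds a Unimod-style
protein-modification table loaded from CSV.
"""

from __future__ import annotations

import csv
import gzip
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import obonet

from .errors import (
    ArtifactFormatError,
    ArtifactIntegrityError,
    CatalogDuplicateError,
    CatalogSchemaError,
    CycleError,
    DanglingParentError,
    OboParseError,
    QueryError,
    TermListImportError,
    UnknownTermError,
)

#: Maximum recursion depth when unrolling a DAG into the nested tree; guards
#: against pathological multi-parent fixtures whose path count explodes.
DEFAULT_MAX_TREE_DEPTH = 50

_CURIE_RE = re.compile(r"^[^\s:]+:[^\s:]+$")
_QUOTED_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _normalize(text: str) -> str:
    """Case-fold and collapse internal whitespace for index lookups."""
    return " ".join(text.split()).casefold()


# ---------------------------------------------------------------------------
# Core graph types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OntologyTerm:
    """One controlled-vocabulary term.

    ``id`` is a CURIE (``prefix:local``, e.g. ``NCBITaxon:9606``); ``parents``
    lists the CURIEs of direct ``is_a`` targets. Obsolete terms are retained
    in the graph (their accessions remain resolvable history) but are
    excluded from every derived artifact.
    """

    id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()
    definition: str | None = None
    obsolete: bool = False


@dataclass
class OntologyGraph:
    """A named, versioned DAG of terms keyed by CURIE."""

    name: str
    version: str
    terms: dict[str, OntologyTerm]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return self.terms == other.terms

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def roots(self) -> list[str]:
        """Non-obsolete terms with no parents, in CURIE-sorted order."""
        return sorted(
            t.id for t in self.terms.values() if not t.obsolete and not t.parents
        )

    def non_obsolete(self) -> list[OntologyTerm]:
        return [t for t in self.terms.values() if not t.obsolete]

    def children_of(self, term_id: str) -> list[OntologyTerm]:
        """Direct non-obsolete children, sorted case-insensitively by label."""
        kids = [
            t
            for t in self.terms.values()
            if not t.obsolete and term_id in t.parents
        ]
        return sorted(kids, key=lambda t: (t.label.casefold(), t.label, t.id))

    def _validate(self) -> None:
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    raise DanglingParentError(
                        f"term {term.id!r} names parent {parent!r} "
                        f"which is not in ontology {self.name!r}"
                    )
        dg = nx.DiGraph()
        dg.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                dg.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
            raise CycleError(f"is_a links form a cycle: {path}")


def ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    """Transitive closure over parent links, excluding ``term_id`` itself."""
    if term_id not in graph.terms:
        raise UnknownTermError(f"unknown term {term_id!r} in ontology {graph.name!r}")
    seen: set[str] = set()
    frontier = list(graph.terms[term_id].parents)
    while frontier:
        current = frontier.pop()
        if current in seen:
            continue
        seen.add(current)
        frontier.extend(graph.terms[current].parents)
    return seen


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _prescan_stanzas(text: str) -> int:
    """Check each [Term] stanza has id and name; return the stanza count.

    obonet does the heavy lifting of the actual parse, but its error
    reporting does not name stanza ordinals, so malformed stanzas are caught
    here first with a plain line scan.
    """
    count = 0
    in_term = False
    has_id = has_name = True
    ordinal = 0

    def _check() -> None:
        if in_term and not (has_id and has_name):
            missing = []
            if not has_id:
                missing.append("id")
            if not has_name:
                missing.append("name")
            raise OboParseError(
                f"[Term] stanza #{ordinal} is missing: {', '.join(missing)}"
            )

    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("["):
            _check()
            in_term = line == "[Term]"
            if in_term:
                count += 1
                ordinal = count
                has_id = has_name = False
        elif in_term:
            if line.startswith("id:"):
                has_id = True
            elif line.startswith("name:"):
                has_name = True
    _check()
    return count


def _extract_quoted(raw: str) -> str:
    """Pull the quoted payload out of an OBO synonym/def line value."""
    m = _QUOTED_RE.search(raw)
    if m:
        return m.group(1).replace('\\"', '"')
    return raw.strip()


def parse_obo(text: str, name: str = "", version: str = "") -> OntologyGraph:
    """Parse OBO 1.2/1.4 term stanzas into an :class:`OntologyGraph`.

    Recognized tags: ``id``, ``name``, ``is_a``, ``synonym`` (the quoted
    portion is kept), ``def``, ``is_obsolete``. Stanza order is irrelevant to
    the result. A stanza missing id or name raises :class:`OboParseError`
    naming the stanza ordinal; a cyclic ``is_a`` chain raises
    :class:`CycleError` listing one cycle; an ``is_a`` target with no stanza
    raises :class:`DanglingParentError`.
    """
    _prescan_stanzas(text)
    if not text.strip():
        return OntologyGraph(name=name, version=version, terms={})
    nxgraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    graph_meta = nxgraph.graph or {}
    name = name or graph_meta.get("ontology", "")
    version = version or graph_meta.get("data-version", "")

    terms: dict[str, OntologyTerm] = {}
    for node, data in nxgraph.nodes(data=True):
        if "name" not in data:
            # obonet materializes is_a targets without stanzas as bare nodes
            continue
        terms[node] = OntologyTerm(
            id=node,
            label=data["name"],
            synonyms=tuple(_extract_quoted(s) for s in data.get("synonym", [])),
            parents=tuple(data.get("is_a", [])),
            definition=_extract_quoted(data["def"]) if "def" in data else None,
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    graph = OntologyGraph(name=name, version=version, terms=terms)
    graph._validate()
    return graph


def export_term_list_json(graph: OntologyGraph) -> str:
    """Serialize a graph as the flat term-list JSON accepted by
    :func:`import_term_list_json` (the lossless interchange shape)."""
    records = []
    for term in sorted(graph.terms.values(), key=lambda t: t.id):
        rec: dict[str, object] = {"id": term.id, "label": term.label}
        if term.parents:
            rec["parents"] = list(term.parents)
        if term.synonyms:
            rec["synonyms"] = list(term.synonyms)
        if term.definition is not None:
            rec["definition"] = term.definition
        if term.obsolete:
            rec["obsolete"] = True
        records.append(rec)
    return json.dumps(records, ensure_ascii=False, indent=1)


def import_term_list_json(
    text: str, name: str = "", version: str = ""
) -> OntologyGraph:
    """Build a graph from flat term records: a JSON list of
    ``{id, label, parents?, synonyms?, definition?, obsolete?}`` objects.

    This is the ingestion path for vocabularies only distributed as OWL/JSON
    term dumps; the result is indistinguishable from :func:`parse_obo` on
    equivalent content.
    """
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TermListImportError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, list):
        raise TermListImportError(
            f"expected a JSON list of term records, got {type(payload).__name__}"
        )
    terms: dict[str, OntologyTerm] = {}
    for i, rec in enumerate(payload):
        if not isinstance(rec, dict) or "id" not in rec or "label" not in rec:
            raise TermListImportError(
                f"record #{i} is missing a mandatory field (id, label)"
            )
        term = OntologyTerm(
            id=str(rec["id"]),
            label=str(rec["label"]),
            synonyms=tuple(rec.get("synonyms", [])),
            parents=tuple(rec.get("parents", [])),
            definition=rec.get("definition"),
            obsolete=bool(rec.get("obsolete", False)),
        )
        terms[term.id] = term
    graph = OntologyGraph(name=name, version=version, terms=terms)
    graph._validate()
    return graph


# ---------------------------------------------------------------------------
# Derived artifacts
# ---------------------------------------------------------------------------


@dataclass
class ElementList:
    """Flat list of every non-obsolete term label, sorted case-insensitively."""

    ontology: str
    elements: list[str]


@dataclass
class NestedTree:
    """Recursive label → {child label → …} mapping; a leaf is an empty map.

    A term with k parents appears once under each parent (the DAG is
    duplicated by path into a tree).
    """

    ontology: str
    tree: dict


@dataclass
class SelectNodes:
    """Tree of ``{label, value, children}`` records for tree-select widgets;
    ``value`` is the term's CURIE."""

    ontology: str
    nodes: list


Artifact = ElementList | NestedTree | SelectNodes


def build_element_list(graph: OntologyGraph) -> ElementList:
    labels = [t.label for t in graph.non_obsolete()]
    labels.sort(key=lambda s: (s.casefold(), s))
    return ElementList(ontology=graph.name, elements=labels)


def _tree_roots(graph: OntologyGraph) -> list[OntologyTerm]:
    """Terms rendered at the top of the tree artifacts: non-obsolete terms
    none of whose parents survive into the artifact (normally the graph
    roots; a term orphaned by an obsolete parent is promoted rather than
    dropped so every usable label stays reachable)."""
    roots = [
        t
        for t in graph.non_obsolete()
        if not any(not graph.terms[p].obsolete for p in t.parents)
    ]
    return sorted(roots, key=lambda t: (t.label.casefold(), t.label, t.id))


def build_nested_tree(
    graph: OntologyGraph, max_depth: int = DEFAULT_MAX_TREE_DEPTH
) -> NestedTree:
    def subtree(term: OntologyTerm, depth: int) -> dict:
        if depth >= max_depth:
            return {}
        return {
            child.label: subtree(child, depth + 1)
            for child in graph.children_of(term.id)
        }

    tree = {root.label: subtree(root, 1) for root in _tree_roots(graph)}
    return NestedTree(ontology=graph.name, tree=tree)


def build_select_nodes(
    graph: OntologyGraph, max_depth: int = DEFAULT_MAX_TREE_DEPTH
) -> SelectNodes:
    def node(term: OntologyTerm, depth: int) -> dict:
        children = (
            [node(c, depth + 1) for c in graph.children_of(term.id)]
            if depth < max_depth
            else []
        )
        return {"label": term.label, "value": term.id, "children": children}

    return SelectNodes(
        ontology=graph.name, nodes=[node(r, 1) for r in _tree_roots(graph)]
    )


_ARTIFACT_KINDS = {
    "element_list": ElementList,
    "nested_tree": NestedTree,
    "select_nodes": SelectNodes,
}


def _artifact_payload(artifact: Artifact) -> dict:
    if isinstance(artifact, ElementList):
        return {
            "kind": "element_list",
            "ontology": artifact.ontology,
            "elements": artifact.elements,
        }
    if isinstance(artifact, NestedTree):
        return {
            "kind": "nested_tree",
            "ontology": artifact.ontology,
            "tree": artifact.tree,
        }
    if isinstance(artifact, SelectNodes):
        return {
            "kind": "select_nodes",
            "ontology": artifact.ontology,
            "nodes": artifact.nodes,
        }
    raise TypeError(f"not an artifact: {type(artifact).__name__}")


def write_artifact(artifact: Artifact, path: str | Path) -> Path:
    """Persist an artifact as gzipped JSON. mtime in the gzip header is
    pinned to zero so identical artifacts are byte-identical on disk."""
    path = Path(path)
    payload = json.dumps(
        _artifact_payload(artifact), ensure_ascii=False, separators=(",", ":")
    ).encode("utf-8")
    buf = io.BytesIO()
    with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as gz:
        gz.write(payload)
    path.write_bytes(buf.getvalue())
    return path


def read_artifact(path: str | Path) -> Artifact:
    """Read a gzipped JSON artifact back; inverse of :func:`write_artifact`."""
    raw = Path(path).read_bytes()
    if raw[:2] != b"\x1f\x8b":
        raise ArtifactFormatError(f"{path}: not a gzip file (bad magic number)")
    try:
        text = gzip.decompress(raw).decode("utf-8")
        payload = json.loads(text)
    except (EOFError, OSError) as exc:
        raise ArtifactIntegrityError(f"{path}: truncated or corrupt gzip stream") from exc
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ArtifactFormatError(f"{path}: payload is not valid JSON") from exc
    kind = payload.get("kind") if isinstance(payload, dict) else None
    if kind == "element_list":
        return ElementList(ontology=payload["ontology"], elements=payload["elements"])
    if kind == "nested_tree":
        return NestedTree(ontology=payload["ontology"], tree=payload["tree"])
    if kind == "select_nodes":
        return SelectNodes(ontology=payload["ontology"], nodes=payload["nodes"])
    raise ArtifactFormatError(f"{path}: unknown artifact kind {kind!r}")


# ---------------------------------------------------------------------------
# Term index and search
# ---------------------------------------------------------------------------

#: Ranked match classes, best first. Exact label beats any prefix match,
#: label matches beat synonym matches of the same shape.
MATCH_KINDS = (
    "label_exact",
    "label_prefix",
    "label_substring",
    "synonym_exact",
    "synonym_prefix",
    "synonym_substring",
)
_KIND_RANK = {kind: i for i, kind in enumerate(MATCH_KINDS)}


@dataclass
class SearchHit:
    label: str
    curie: str
    match_kind: str


@dataclass
class TermIndex:
    """Exact/synonym lookup plus ranked autocomplete over one vocabulary.

    Lookups are case-insensitive and whitespace-normalized. When two terms
    share a normalized label or synonym, the term with the lexicographically
    smallest CURIE wins and the collision is recorded in ``warnings`` —
    deterministic resolution without guessing curator intent.
    """

    ontology: str
    label_to_curie: dict[str, str] = field(default_factory=dict)
    synonym_to_curie: dict[str, str] = field(default_factory=dict)
    curie_to_label: dict[str, str] = field(default_factory=dict)
    #: (normalized synonym, canonical label, curie) rows for search
    _synonym_rows: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def resolve(self, value: str) -> tuple[str, str] | None:
        """Resolve a value to ``(status, canonical_label)``.

        status is ``"exact"`` when the value matches a term label (the
        canonical casing is returned) or ``"synonym"`` when it matches a
        synonym (the term's canonical label is returned); ``None`` when the
        value matches nothing.
        """
        norm = _normalize(value)
        curie = self.label_to_curie.get(norm)
        if curie is not None:
            return "exact", self.curie_to_label[curie]
        curie = self.synonym_to_curie.get(norm)
        if curie is not None:
            return "synonym", self.curie_to_label[curie]
        return None

    def curie_of(self, value: str) -> str | None:
        norm = _normalize(value)
        return self.label_to_curie.get(norm) or self.synonym_to_curie.get(norm)


def build_term_index(graph: OntologyGraph) -> TermIndex:
    index = TermIndex(ontology=graph.name)
    # CURIE-sorted iteration makes "first writer wins" deterministic
    for term in sorted(graph.non_obsolete(), key=lambda t: t.id):
        norm = _normalize(term.label)
        index.curie_to_label[term.id] = term.label
        if norm in index.label_to_curie:
            index.warnings.append(
                f"label collision: {term.label!r} maps to "
                f"{index.label_to_curie[norm]} and {term.id}; kept the former"
            )
        else:
            index.label_to_curie[norm] = term.id
        for syn in term.synonyms:
            snorm = _normalize(syn)
            index._synonym_rows.append((snorm, term.label, term.id))
            if snorm in index.synonym_to_curie:
                index.warnings.append(
                    f"synonym collision: {syn!r} maps to "
                    f"{index.synonym_to_curie[snorm]} and {term.id}; kept the former"
                )
            else:
                index.synonym_to_curie[snorm] = term.id
    return index


def _match_kind(norm_query: str, norm_label: str, is_synonym: bool) -> str | None:
    if norm_label == norm_query:
        kind = "exact"
    elif norm_label.startswith(norm_query):
        kind = "prefix"
    elif norm_query in norm_label:
        kind = "substring"
    else:
        return None
    return ("synonym_" if is_synonym else "label_") + kind


def search_terms(index: TermIndex, query: str, limit: int = 20) -> list[SearchHit]:
    """Ranked autocomplete over labels and synonyms.

    Ranking: exact label > label prefix > label substring > synonym exact >
    synonym prefix > synonym substring; ties broken by shorter label, then
    case-insensitive label order. Matching is case-insensitive; each term
    contributes at most one hit (its best match kind).
    """
    norm_query = _normalize(query)
    if not norm_query:
        raise QueryError("search query is empty after trimming")
    best: dict[str, str] = {}  # curie -> best match kind
    for norm_label, curie in index.label_to_curie.items():
        kind = _match_kind(norm_query, norm_label, is_synonym=False)
        if kind is not None:
            best[curie] = kind
    for norm_syn, _label, curie in index._synonym_rows:
        kind = _match_kind(norm_query, norm_syn, is_synonym=True)
        if kind is not None and (
            curie not in best or _KIND_RANK[kind] < _KIND_RANK[best[curie]]
        ):
            best[curie] = kind
    hits = [
        SearchHit(label=index.curie_to_label[curie], curie=curie, match_kind=kind)
        for curie, kind in best.items()
    ]
    hits.sort(
        key=lambda h: (
            _KIND_RANK[h.match_kind],
            len(h.label),
            h.label.casefold(),
            h.curie,
        )
    )
    return hits[: max(limit, 0)]


# ---------------------------------------------------------------------------
# Modification catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Modification:
    name: str
    accession: str  # UNIMOD:<n>
    sites: tuple[str, ...] = ()
    position: str | None = None
    mono_mass: float | None = None


@dataclass
class ModificationCatalog:
    """Unimod-style protein-modification table keyed by accession and name."""

    records: list[Modification]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Modification]:
        return iter(self.records)

    def by_accession(self, accession: str) -> Modification | None:
        accession = _normalize_unimod(accession)
        for rec in self.records:
            if rec.accession == accession:
                return rec
        return None

    def by_name(self, name: str) -> Modification | None:
        norm = _normalize(name)
        for rec in self.records:
            if _normalize(rec.name) == norm:
                return rec
        return None

    def resolve(self, value: str) -> tuple[str, str] | None:
        """Vocabulary-style resolution: a modification name is an exact hit,
        a UNIMOD accession resolves (as a synonym would) to the name."""
        rec = self.by_name(value)
        if rec is not None:
            return "exact", rec.name
        try:
            rec = self.by_accession(value)
        except CatalogSchemaError:
            return None
        if rec is not None:
            return "synonym", rec.name
        return None


def _normalize_unimod(raw: str) -> str:
    raw = raw.strip()
    m = re.fullmatch(r"(?:UNIMOD:)?(\d+)", raw, flags=re.IGNORECASE)
    if not m:
        raise CatalogSchemaError(f"accession {raw!r} is not UNIMOD:<integer>")
    return f"UNIMOD:{int(m.group(1))}"


_CATALOG_COLUMNS = {
    "name": ("name", "title", "modification"),
    "accession": ("accession", "unimod id", "unimod_id", "id", "record id"),
    "sites": ("sites", "site", "position sites"),
    "position": ("position",),
    "mono_mass": ("mono_mass", "monoisotopic mass", "mono mass", "monoisotopic"),
}


def load_unimod_csv(text: str) -> ModificationCatalog:
    """Load a comma-separated modification table (UTF-8, header row, column
    names matched case-insensitively). ``name`` and ``accession`` columns are
    mandatory; accessions are normalized to ``UNIMOD:<n>`` and must be unique.
    """
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise CatalogSchemaError("empty CSV: no header row")
    norm_header = [_normalize(h) for h in header]
    col_idx: dict[str, int] = {}
    for field_name, aliases in _CATALOG_COLUMNS.items():
        for alias in aliases:
            if alias in norm_header:
                col_idx[field_name] = norm_header.index(alias)
                break
    for mandatory in ("name", "accession"):
        if mandatory not in col_idx:
            raise CatalogSchemaError(
                f"modification CSV is missing a {mandatory!r} column "
                f"(header: {header})"
            )

    def cell(row: list[str], key: str) -> str:
        idx = col_idx.get(key)
        return row[idx].strip() if idx is not None and idx < len(row) else ""

    records: list[Modification] = []
    seen: set[str] = set()
    for row in reader:
        if not any(c.strip() for c in row):
            continue
        accession = _normalize_unimod(cell(row, "accession"))
        if accession in seen:
            raise CatalogDuplicateError(f"duplicate accession {accession}")
        seen.add(accession)
        sites_raw = cell(row, "sites")
        mass_raw = cell(row, "mono_mass")
        records.append(
            Modification(
                name=cell(row, "name"),
                accession=accession,
                sites=tuple(s for s in re.split(r"[,; ]+", sites_raw) if s),
                position=cell(row, "position") or None,
                mono_mass=float(mass_raw) if mass_raw else None,
            )
        )
    return ModificationCatalog(records=records)
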