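"""Deterministic toy fixtures: ontologies, vocabularies, local metadata.

Real annotation runs against multi-megabyte controlled vocabularies
(taxonomies, instrument CVs, modification catalogs). For tests, examples
and offline demos this module generates small stand-ins that exercise the
same code paths: a seeded random taxonomy-like DAG in OBO format, fixed
mini-vocabularies for anatomy / instruments / diseases / proteases, a
Unimod-style modification CSV, and a local metadata table with a controlled
mix of canonical labels, synonym spellings and one guaranteed junk value.

Every generator is a pure function of its spec/seed: identical inputs give
byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .errors import FixtureSpecError
from .ontology import (
    ModificationCatalog,
    OntologyGraph,
    TermIndex,
    build_term_index,
    load_unimod_csv,
    parse_obo,
)

# ---------------------------------------------------------------------------
# Toy ontology (taxonomy-like)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the toy ontology generator.

    ``depth`` is the maximum root-to-leaf level count the generated DAG may
    reach (the generator builds one backbone chain of exactly that depth
    when ``n_terms`` allows); ``synonym_rate`` / ``obsolete_rate`` are the
    approximate fractions of random terms given one synonym / marked
    obsolete.
    """

    n_terms: int = 50
    depth: int = 4
    seed: int = 1
    synonym_rate: float = 0.2
    obsolete_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise FixtureSpecError("n_terms must be >= 1")
        if self.depth < 1:
            raise FixtureSpecError("depth must be >= 1")
        if self.depth > self.n_terms:
            raise FixtureSpecError(
                f"depth {self.depth} cannot exceed n_terms {self.n_terms}"
            )
        for name in ("synonym_rate", "obsolete_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"{name} must be in [0, 1], got {v}")


#: Fixed mini-taxonomy stanzas always emitted first (truncated when
#: n_terms < 4) so cross-module examples resolve stably.
_FIXED_BLOCK: list[tuple[str, str, list[str], list[str]]] = [
    # (id, label, synonyms, parents)
    ("TOY:0000001", "organism", [], []),
    ("NCBITaxon:9606", "Homo sapiens", ["human"], ["TOY:0000001"]),
    ("NCBITaxon:63221", "Homo sapiens neanderthalensis", [], ["NCBITaxon:9606"]),
    ("NCBITaxon:10090", "Mus musculus", ["mouse"], ["TOY:0000001"]),
]


def generate_toy_ontology(spec: FixtureSpec = FixtureSpec()) -> str:
    """Generate OBO text for a toy taxonomy-like ontology.

    The output has exactly ``spec.n_terms`` [Term] stanzas. The first (up
    to) four stanzas are a fixed mini-taxonomy (root "organism";
    "Homo sapiens" with synonym "human"); the rest are seeded random terms
    whose is_a links form a DAG no deeper than ``spec.depth``, with an
    occasional second parent to exercise multi-parent handling. Obsolete
    terms never get children, so derived tree artifacts stay complete.
    """
    rng = random.Random(spec.seed)
    stanzas: list[str] = []
    # depth bookkeeping and parent pool (non-obsolete terms below the cap)
    depth_of: dict[str, int] = {}
    labels: dict[str, str] = {}
    parent_pool: list[str] = []

    def emit(tid: str, label: str, synonyms: list[str], parents: list[str],
             obsolete: bool = False) -> None:
        lines = ["[Term]", f"id: {tid}", f"name: {label}"]
        for syn in synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for p in parents:
            lines.append(f"is_a: {p} ! {labels[p]}")
        if obsolete:
            lines.append("is_obsolete: true")
        stanzas.append("\n".join(lines))
        labels[tid] = label
        depth_of[tid] = max((depth_of[p] for p in parents), default=0) + 1
        if not obsolete and depth_of[tid] < spec.depth:
            parent_pool.append(tid)

    for tid, label, synonyms, parents in _FIXED_BLOCK[: min(spec.n_terms, 4)]:
        parents = [p for p in parents if p in labels and depth_of[p] < spec.depth]
        emit(tid, label, synonyms, parents)

    n_random = spec.n_terms - len(stanzas)
    # one backbone chain guaranteeing the requested depth is reached
    backbone_needed = max(0, spec.depth - max(depth_of.values(), default=0))
    chain_tail = max(depth_of, key=lambda t: depth_of[t]) if depth_of else None
    for i in range(n_random):
        tid = f"TOY:{i + 5:07d}"
        label = f"toy term {i + 5:04d}"
        synonyms = [f"tt{i + 5:04d}"] if rng.random() < spec.synonym_rate else []
        obsolete = rng.random() < spec.obsolete_rate
        if i < backbone_needed and chain_tail is not None and not obsolete:
            parents = [chain_tail]
            emit(tid, label, synonyms, parents)
            chain_tail = tid
            continue
        if parent_pool:
            parents = [rng.choice(parent_pool)]
            # occasional second parent (kept acyclic: only earlier terms)
            if rng.random() < 0.10:
                other = rng.choice(parent_pool)
                if other != parents[0]:
                    parents.append(other)
        else:
            parents = []
        emit(tid, label, sorted(synonyms), sorted(parents), obsolete=obsolete)

    header = "format-version: 1.2\nontology: toy-taxonomy\n"
    return header + "\n" + "\n\n".join(stanzas) + "\n"


def toy_taxonomy_graph(spec: FixtureSpec = FixtureSpec()) -> OntologyGraph:
    """Parse the generated toy taxonomy into a graph."""
    return parse_obo(generate_toy_ontology(spec), name="toy-taxonomy")


# ---------------------------------------------------------------------------
# Fixed mini-vocabularies
# ---------------------------------------------------------------------------

_ANATOMY_OBO = """format-version: 1.2
ontology: toy-anatomy

[Term]
id: TOYA:0000001
name: anatomical entity

[Term]
id: TOYA:0000002
name: liver
synonym: "hepatic tissue" EXACT []
is_a: TOYA:0000001 ! anatomical entity

[Term]
id: TOYA:0000003
name: brain
synonym: "encephalon" EXACT []
is_a: TOYA:0000001 ! anatomical entity

[Term]
id: TOYA:0000004
name: cerebral cortex
is_a: TOYA:0000003 ! brain

[Term]
id: TOYA:0000005
name: kidney
is_a: TOYA:0000001 ! anatomical entity
"""

_INSTRUMENT_OBO = """format-version: 1.2
ontology: toy-instrument

[Term]
id: TOYMS:0000001
name: instrument model

[Term]
id: TOYMS:0000002
name: Orbitrap Fusion Lumos
synonym: "Lumos" EXACT []
is_a: TOYMS:0000001 ! instrument model

[Term]
id: TOYMS:0000003
name: Q Exactive
synonym: "QE" EXACT []
is_a: TOYMS:0000001 ! instrument model

[Term]
id: TOYMS:0000004
name: LTQ Orbitrap Velos
is_a: TOYMS:0000001 ! instrument model
"""

_DISEASE_OBO = """format-version: 1.2
ontology: toy-disease

[Term]
id: TOYD:0000001
name: disease

[Term]
id: TOYD:0000002
name: COVID-19
synonym: "coronavirus disease 2019" EXACT []
is_a: TOYD:0000001 ! disease

[Term]
id: TOYD:0000003
name: breast carcinoma
synonym: "breast cancer" EXACT []
is_a: TOYD:0000001 ! disease

[Term]
id: TOYD:0000004
name: normal
"""

_PROTEASE_OBO = """format-version: 1.2
ontology: toy-protease

[Term]
id: TOYP:0000001
name: cleavage agent

[Term]
id: TOYP:0000002
name: Trypsin
is_a: TOYP:0000001 ! cleavage agent

[Term]
id: TOYP:0000003
name: Lys-C
is_a: TOYP:0000001 ! cleavage agent

[Term]
id: TOYP:0000004
name: Chymotrypsin
is_a: TOYP:0000001 ! cleavage agent
"""

_UNIMOD_CSV = """name,accession,site,position,mono_mass
Oxidation,35,M,Anywhere,15.994915
Carbamidomethyl,4,C,Anywhere,57.021464
Phospho,21,S T Y,Anywhere,79.966331
Acetyl,1,K,Any N-term,42.010565
"""


def toy_anatomy_graph() -> OntologyGraph:
    return parse_obo(_ANATOMY_OBO, name="toy-anatomy")


def toy_instrument_graph() -> OntologyGraph:
    return parse_obo(_INSTRUMENT_OBO, name="toy-instrument")


def toy_disease_graph() -> OntologyGraph:
    return parse_obo(_DISEASE_OBO, name="toy-disease")


def toy_protease_graph() -> OntologyGraph:
    return parse_obo(_PROTEASE_OBO, name="toy-protease")


def toy_unimod_csv() -> str:
    """A four-row Unimod-style modification CSV."""
    return _UNIMOD_CSV


def toy_modification_catalog() -> ModificationCatalog:
    return load_unimod_csv(_UNIMOD_CSV)


def toy_binding_indices(
    spec: FixtureSpec = FixtureSpec(),
) -> dict[str, object]:
    """The full ontology-binding registry over the toy vocabularies, keyed
    by rendered SDRF header — ready for map_metadata / fill_column /
    validate_table."""
    from .model import load_label_schemes
    from .validation import LabelVocabulary

    return {
        "characteristics[organism]": build_term_index(toy_taxonomy_graph(spec)),
        "characteristics[organism part]": build_term_index(toy_anatomy_graph()),
        "characteristics[cell type]": build_term_index(toy_anatomy_graph()),
        "characteristics[disease]": build_term_index(toy_disease_graph()),
        "comment[instrument]": build_term_index(toy_instrument_graph()),
        "comment[cleavage agent details]": build_term_index(toy_protease_graph()),
        "comment[modification parameters]": toy_modification_catalog(),
        "comment[label]": LabelVocabulary(load_label_schemes()),
    }


# ---------------------------------------------------------------------------
# Toy local metadata
# ---------------------------------------------------------------------------

_ORGANISM_POOL = ["Homo sapiens", "human", "Mus musculus", "mouse"]
_ORGANISM_PART_POOL = ["liver", "hepatic tissue", "brain", "encephalon", "kidney"]
_INSTRUMENT_POOL = ["Orbitrap Fusion Lumos", "Lumos", "Q Exactive", "QE"]
_DISEASE_POOL = ["COVID-19", "breast carcinoma", "breast cancer", "normal"]

#: The one guaranteed-unresolvable organism value (emitted in row 5).
UNRESOLVABLE_VALUE = "unobtainium"


def generate_toy_metadata(n_samples: int, seed: int = 1) -> str:
    """Generate a local metadata TSV: columns file, organism, organism part,
    instrument, disease; one row per sample.

    Values mix canonical labels with synonym spellings from the toy
    vocabularies. When ``n_samples >= 5`` the fifth row's organism is the
    unresolvable value :data:`UNRESOLVABLE_VALUE` — exactly one distinct
    unresolved value for mapping tests. Deterministic per seed.
    """
    if n_samples < 1:
        raise FixtureSpecError("n_samples must be >= 1")
    rng = random.Random(seed)
    lines = ["file\torganism\torganism part\tinstrument\tdisease"]
    for i in range(1, n_samples + 1):
        organism = rng.choice(_ORGANISM_POOL)
        if i == 5:
            organism = UNRESOLVABLE_VALUE
        lines.append(
            "\t".join(
                [
                    f"run_{i:03d}.raw",
                    organism,
                    rng.choice(_ORGANISM_PART_POOL),
                    rng.choice(_INSTRUMENT_POOL),
                    rng.choice(_DISEASE_POOL),
                ]
            )
        )
    return "\n".join(lines) + "\n"
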