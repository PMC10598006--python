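"""Shared fixtures: toy ontologies, binding indices, and a happy-path table."""

from __future__ import annotations

import pytest

import sdrfkit as sk


@pytest.fixture(scope="session")
def toy_spec() -> sk.FixtureSpec:
    return sk.FixtureSpec(n_terms=50, depth=4, seed=1)


@pytest.fixture(scope="session")
def toy_obo(toy_spec) -> str:
    return sk.generate_toy_ontology(toy_spec)


@pytest.fixture(scope="session")
def toy_graph(toy_obo) -> sk.OntologyGraph:
    return sk.parse_obo(toy_obo, name="toy-taxonomy")


@pytest.fixture(scope="session")
def toy_index(toy_graph) -> sk.TermIndex:
    return sk.build_term_index(toy_graph)


@pytest.fixture(scope="session")
def indices(toy_spec) -> dict:
    return sk.toy_binding_indices(toy_spec)


@pytest.fixture(scope="session")
def templates():
    return sk.load_template_registry()


@pytest.fixture(scope="session")
def schemes():
    return sk.load_label_schemes()


def build_happy_table(
    indices: dict,
    n_files: int = 2,
    scheme_name: str = "TMT10plex",
    seed: int = 3,
    species: str = "human",
) -> sk.SDRFTable:
    """Run the whole five-step workflow on toy fixtures and return a table
    that validates cleanly against the species template."""
    schemes = sk.load_label_schemes()
    table = sk.create_template(species)
    table = sk.set_raw_files(
        table, [f"run_{i:03d}.raw" for i in range(1, n_files + 1)]
    )
    meta_rows = sk.read_local_metadata(sk.generate_toy_metadata(n_files, seed=seed))
    mapping = sk.ColumnMapping.of(
        {
            "organism": "characteristics[organism]",
            "organism part": "characteristics[organism part]",
            "instrument": "comment[instrument]",
            "disease": "characteristics[disease]",
        }
    )
    table, _report = sk.map_metadata(table, meta_rows, mapping, indices)
    table = sk.expand_labels(table, schemes[scheme_name])
    table = sk.fill_column(table, "comment[cleavage agent details]", "NT=Trypsin")
    table = sk.fill_column(
        table, "comment[modification parameters]",
        "NT=Oxidation;AC=UNIMOD:35;MT=Variable;TA=M",
    )
    table = sk.fill_column(
        table, "technology type", "proteomic profiling by mass spectrometry"
    )
    table = sk.fill_column(table, "comment[fraction identifier]", "1")
    for header in (
        "characteristics[cell type]",
        "characteristics[ancestry category]",
        "characteristics[age]",
        "characteristics[sex]",
    ):
        if table.has_column(header):
            table = sk.fill_column(table, header, sk.NOT_APPLICABLE)
    return table


@pytest.fixture(scope="session")
def happy_table(indices) -> sk.SDRFTable:
    return build_happy_table(indices)
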