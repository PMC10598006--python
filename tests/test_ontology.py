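"""Controlled-vocabulary parsing, derived artifacts, indexing and search."""

from __future__ import annotations

import gzip
import json
import random

import pytest

import sdrfkit as sk
from sdrfkit.errors import (
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

SIMPLE_OBO = """[Term]
id: X:1
name: A

[Term]
id: X:2
name: B
is_a: X:1

[Term]
id: X:3
name: C
is_a: X:1
"""

DIAMOND_OBO = """[Term]
id: X:1
name: A

[Term]
id: X:2
name: B
is_a: X:1

[Term]
id: X:3
name: C
is_a: X:1

[Term]
id: X:4
name: D
is_a: X:2
is_a: X:3
"""


class TestParseObo:
    def test_three_stanzas(self):
        g = sk.parse_obo(SIMPLE_OBO)
        assert len(g) == 3
        assert g.roots == ["X:1"]
        assert g.terms["X:2"].parents == ("X:1",)

    def test_empty_input(self):
        g = sk.parse_obo("")
        assert len(g) == 0 and g.roots == []

    def test_stanza_count_matches_line_scan(self, toy_obo, toy_graph):
        # independent oracle: count "[Term]" headers by scanning lines
        n_stanzas = sum(1 for line in toy_obo.splitlines() if line.strip() == "[Term]")
        assert len(toy_graph) == n_stanzas == 50

    def test_missing_name_names_stanza_ordinal(self):
        bad = SIMPLE_OBO + "\n[Term]\nid: X:9\n"
        with pytest.raises(OboParseError, match=r"#4.*name"):
            sk.parse_obo(bad)

    def test_missing_id_names_stanza_ordinal(self):
        with pytest.raises(OboParseError, match=r"#1.*id"):
            sk.parse_obo("[Term]\nname: orphan\n")

    def test_cycle_is_rejected(self):
        cyclic = "[Term]\nid: X:1\nname: A\nis_a: X:2\n\n[Term]\nid: X:2\nname: B\nis_a: X:1\n"
        with pytest.raises(CycleError, match="X:"):
            sk.parse_obo(cyclic)

    def test_dangling_parent_is_rejected(self):
        with pytest.raises(DanglingParentError, match="X:9"):
            sk.parse_obo("[Term]\nid: X:1\nname: A\nis_a: X:9\n")

    def test_synonym_quoted_portion_captured(self):
        obo = '[Term]\nid: X:1\nname: Homo sapiens\nsynonym: "human" EXACT []\n'
        g = sk.parse_obo(obo)
        assert g.terms["X:1"].synonyms == ("human",)

    def test_obsolete_flag_honored(self):
        obo = SIMPLE_OBO + "\n[Term]\nid: X:4\nname: old\nis_obsolete: true\n"
        g = sk.parse_obo(obo)
        assert g.terms["X:4"].obsolete
        assert len(g.non_obsolete()) == 3


class TestTermListJson:
    def test_empty_list(self):
        assert len(sk.import_term_list_json("[]")) == 0

    def test_two_records_with_parent(self):
        text = json.dumps(
            [
                {"id": "Y:1", "label": "root"},
                {"id": "Y:2", "label": "child", "parents": ["Y:1"]},
            ]
        )
        g = sk.import_term_list_json(text)
        assert len(g) == 2 and g.roots == ["Y:1"]

    def test_round_trip_from_obo_graph(self, toy_graph):
        again = sk.import_term_list_json(
            sk.export_term_list_json(toy_graph), name=toy_graph.name
        )
        assert again == toy_graph

    @pytest.mark.parametrize("bad", ['{"id": 1}', '[{"id": "Y:1"}]', "3"])
    def test_malformed_input(self, bad):
        with pytest.raises(TermListImportError):
            sk.import_term_list_json(bad)


class TestElementList:
    def test_obsolete_excluded(self):
        obo = SIMPLE_OBO + "\n[Term]\nid: X:4\nname: old\nis_obsolete: true\n"
        el = sk.build_element_list(sk.parse_obo(obo))
        assert el.elements == ["A", "B", "C"]

    def test_empty_graph(self):
        assert sk.build_element_list(sk.parse_obo("")).elements == []

    def test_multiset_equals_term_iteration(self, toy_graph):
        el = sk.build_element_list(toy_graph)
        assert len(el.elements) == 50
        assert sorted(el.elements) == sorted(
            t.label for t in toy_graph.terms.values() if not t.obsolete
        )

    def test_case_insensitive_sort(self):
        obo = "[Term]\nid: X:1\nname: banana\n\n[Term]\nid: X:2\nname: Apple\n"
        assert sk.build_element_list(sk.parse_obo(obo)).elements == ["Apple", "banana"]


def _preorder_nested(tree: dict) -> list[str]:
    out = []
    for label, sub in tree.items():
        out.append(label)
        out.extend(_preorder_nested(sub))
    return out


def _preorder_nodes(nodes: list) -> list[str]:
    out = []
    for node in nodes:
        out.append(node["label"])
        out.extend(_preorder_nodes(node["children"]))
    return out


def _paths_by_dfs(graph: sk.OntologyGraph) -> set[tuple[str, ...]]:
    """Independent oracle: enumerate root-to-leaf label paths by DFS over
    parent links (children looked up the slow way each step)."""
    def children(tid):
        return sorted(
            (t for t in graph.terms.values() if not t.obsolete and tid in t.parents),
            key=lambda t: (t.label.casefold(), t.label, t.id),
        )

    paths: set[tuple[str, ...]] = set()

    def walk(tid, prefix):
        kids = children(tid)
        label_path = prefix + (graph.terms[tid].label,)
        if not kids:
            paths.add(label_path)
        for kid in kids:
            walk(kid.id, label_path)

    for root in graph.roots:
        walk(root, ())
    return paths


def _paths_in_tree(tree: dict) -> set[tuple[str, ...]]:
    paths: set[tuple[str, ...]] = set()

    def walk(sub, prefix):
        for label, kids in sub.items():
            p = prefix + (label,)
            if kids:
                walk(kids, p)
            else:
                paths.add(p)

    walk(tree, ())
    return paths


class TestTrees:
    def test_two_children(self):
        obo = SIMPLE_OBO
        tree = sk.build_nested_tree(sk.parse_obo(obo)).tree
        assert tree == {"A": {"B": {}, "C": {}}}

    def test_diamond_duplicates_under_both_parents(self):
        tree = sk.build_nested_tree(sk.parse_obo(DIAMOND_OBO)).tree
        assert tree["A"]["B"] == {"D": {}}
        assert tree["A"]["C"] == {"D": {}}

    def test_every_label_appears(self, toy_graph):
        labels = set(_preorder_nested(sk.build_nested_tree(toy_graph).tree))
        assert labels == {t.label for t in toy_graph.non_obsolete()}

    def test_paths_match_dfs_oracle(self, toy_graph):
        tree = sk.build_nested_tree(toy_graph).tree
        assert _paths_in_tree(tree) == _paths_by_dfs(toy_graph)

    def test_select_nodes_single_root(self):
        nodes = sk.build_select_nodes(sk.parse_obo("[Term]\nid: X:1\nname: A\n")).nodes
        assert nodes == [{"label": "A", "value": "X:1", "children": []}]

    def test_select_nodes_empty_graph(self):
        assert sk.build_select_nodes(sk.parse_obo("")).nodes == []

    def test_select_nodes_mirror_nested_tree(self, toy_graph):
        nested = sk.build_nested_tree(toy_graph)
        nodes = sk.build_select_nodes(toy_graph)
        assert _preorder_nodes(nodes.nodes) == _preorder_nested(nested.tree)

    def test_select_nodes_top_level_are_roots(self, toy_graph):
        nodes = sk.build_select_nodes(toy_graph)
        assert [n["value"] for n in nodes.nodes] == sorted(
            toy_graph.roots,
            key=lambda i: (
                toy_graph.terms[i].label.casefold(),
                toy_graph.terms[i].label,
                i,
            ),
        )

    def test_select_node_values_are_graph_curies(self, toy_graph):
        def walk(nodes):
            for n in nodes:
                assert n["value"] in toy_graph.terms
                walk(n["children"])

        walk(sk.build_select_nodes(toy_graph).nodes)


@pytest.fixture(scope="module")
def artifacts(toy_graph):
    return [
        sk.build_element_list(toy_graph),
        sk.build_nested_tree(toy_graph),
        sk.build_select_nodes(toy_graph),
    ]


class TestArtifacts:
    def test_round_trip_identity(self, artifacts, tmp_path):
        for i, artifact in enumerate(artifacts):
            path = sk.write_artifact(artifact, tmp_path / f"a{i}.json.gz")
            assert sk.read_artifact(path) == artifact

    def test_gzip_magic_number(self, artifacts, tmp_path):
        path = sk.write_artifact(artifacts[0], tmp_path / "el.json.gz")
        assert path.read_bytes()[:2] == b"\x1f\x8b"

    def test_plain_json_rejected(self, tmp_path):
        p = tmp_path / "plain.json"
        p.write_text('{"kind": "element_list"}')
        with pytest.raises(ArtifactFormatError, match="magic"):
            sk.read_artifact(p)

    def test_truncated_stream_rejected(self, artifacts, tmp_path):
        path = sk.write_artifact(artifacts[1], tmp_path / "t.json.gz")
        path.write_bytes(path.read_bytes()[:-5])
        with pytest.raises(ArtifactIntegrityError):
            sk.read_artifact(path)

    def test_empty_element_list_small_file(self, tmp_path):
        path = sk.write_artifact(
            sk.ElementList(ontology="toy", elements=[]), tmp_path / "e.json.gz"
        )
        assert sk.read_artifact(path) == sk.ElementList(ontology="toy", elements=[])
        assert path.stat().st_size < 200

    def test_byte_identical_determinism(self, artifacts, tmp_path):
        p1 = sk.write_artifact(artifacts[2], tmp_path / "n1.json.gz")
        p2 = sk.write_artifact(artifacts[2], tmp_path / "n2.json.gz")
        assert p1.read_bytes() == p2.read_bytes()


class TestTermIndex:
    def test_synonym_lookup(self, toy_index):
        assert toy_index.resolve("human") == ("synonym", "Homo sapiens")
        assert toy_index.curie_of("human") == "NCBITaxon:9606"

    def test_case_and_whitespace_normalization(self, toy_index):
        assert toy_index.resolve("HOMO  SAPIENS") == ("exact", "Homo sapiens")

    def test_every_label_self_resolves(self, toy_graph, toy_index):
        for term in toy_graph.non_obsolete():
            assert toy_index.curie_of(term.label) == term.id

    def test_ambiguous_label_first_curie_wins_with_warning(self):
        obo = "[Term]\nid: X:2\nname: dup\n\n[Term]\nid: X:1\nname: dup\n"
        index = sk.build_term_index(sk.parse_obo(obo))
        assert index.curie_of("dup") == "X:1"
        assert any("collision" in w for w in index.warnings)


def _brute_force_search(graph: sk.OntologyGraph, query: str) -> set[str]:
    """Oracle: case-insensitive substring scan over all labels and synonyms."""
    q = " ".join(query.split()).casefold()
    hits = set()
    for term in graph.non_obsolete():
        texts = [term.label] + list(term.synonyms)
        if any(q in " ".join(t.split()).casefold() for t in texts):
            hits.add(term.id)
    return hits


class TestSearch:
    def test_prefix_tie_break_shorter_label_first(self, toy_index):
        hits = sk.search_terms(toy_index, "homo sap", limit=10)
        labels = [h.label for h in hits]
        assert labels[:2] == ["Homo sapiens", "Homo sapiens neanderthalensis"]

    def test_exact_label_ranks_first(self, toy_index):
        hits = sk.search_terms(toy_index, "Homo sapiens", limit=10)
        assert hits[0].label == "Homo sapiens"
        assert hits[0].match_kind == "label_exact"

    def test_no_match_is_empty(self, toy_index):
        assert sk.search_terms(toy_index, "zzz-nothing", limit=5) == []

    def test_blank_query_rejected(self, toy_index):
        with pytest.raises(QueryError):
            sk.search_terms(toy_index, "   ", limit=5)

    def test_limit_truncates(self, toy_index):
        assert len(sk.search_terms(toy_index, "toy term", limit=3)) == 3

    def test_matches_brute_force_scan_on_random_queries(self, toy_graph, toy_index):
        rng = random.Random(7)
        corpus = [t.label for t in toy_graph.non_obsolete()] + [
            s for t in toy_graph.non_obsolete() for s in t.synonyms
        ]
        queries = []
        for _ in range(100):
            src = rng.choice(corpus)
            i = rng.randrange(len(src))
            j = rng.randrange(i, len(src)) + 1
            q = src[i:j].strip() or src
            queries.append(q if rng.random() < 0.9 else q + "@none")
        for q in queries:
            got = {h.curie for h in sk.search_terms(toy_index, q, limit=10**6)}
            assert got == _brute_force_search(toy_graph, q), f"query {q!r}"


class TestAncestors:
    def test_root_has_none(self, toy_graph):
        assert sk.ancestors(toy_graph, toy_graph.roots[0]) == set()

    def test_diamond_closure(self):
        g = sk.parse_obo(DIAMOND_OBO)
        assert sk.ancestors(g, "X:4") == {"X:1", "X:2", "X:3"}

    def test_unknown_id(self, toy_graph):
        with pytest.raises(UnknownTermError):
            sk.ancestors(toy_graph, "NOPE:1")

    def test_fixed_point_oracle(self, toy_graph):
        # oracle: repeat parent expansion until no change, for every term
        for tid, term in toy_graph.terms.items():
            closure = set(term.parents)
            while True:
                grown = set(closure)
                for p in closure:
                    grown.update(toy_graph.terms[p].parents)
                if grown == closure:
                    break
                closure = grown
            assert sk.ancestors(toy_graph, tid) == closure

    def test_monotone_over_parent_links(self, toy_graph):
        for term in toy_graph.terms.values():
            anc = sk.ancestors(toy_graph, term.id)
            for parent in term.parents:
                assert sk.ancestors(toy_graph, parent) | {parent} <= anc


class TestUnimodCsv:
    def test_two_rows(self):
        cat = sk.load_unimod_csv(
            "name,accession\nOxidation,UNIMOD:35\nCarbamidomethyl,4\n"
        )
        assert len(cat) == 2
        assert {m.accession for m in cat} == {"UNIMOD:35", "UNIMOD:4"}

    def test_header_only(self):
        assert len(sk.load_unimod_csv("name,accession\n")) == 0

    def test_bare_integer_normalized(self):
        cat = sk.load_unimod_csv("name,accession\nOxidation,35\n")
        assert cat.records[0].accession == "UNIMOD:35"

    def test_missing_mandatory_column(self):
        with pytest.raises(CatalogSchemaError, match="accession"):
            sk.load_unimod_csv("name,mass\nOxidation,15.99\n")

    def test_duplicate_accession(self):
        with pytest.raises(CatalogDuplicateError):
            sk.load_unimod_csv("name,accession\nA,35\nB,UNIMOD:35\n")

    def test_full_toy_catalog_fields(self):
        cat = sk.toy_modification_catalog()
        ox = cat.by_name("oxidation")
        assert ox is not None and ox.accession == "UNIMOD:35"
        assert ox.sites == ("M",) and ox.mono_mass == pytest.approx(15.994915)
        assert cat.resolve("UNIMOD:4") == ("synonym", "Carbamidomethyl")
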