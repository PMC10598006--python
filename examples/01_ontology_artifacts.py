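"""Build the three cached vocabulary artifacts from an OBO ontology.

Generates a 50-term toy taxonomy, parses it, derives the flat element list,
the nested label tree and the widget-ready nodes tree, persists them as
gzipped JSON, and runs an autocomplete query against the term index.
"""

from pathlib import Path

import sdrfkit as sk

out_dir = Path("scratch/artifacts")
out_dir.mkdir(parents=True, exist_ok=True)

obo_text = sk.generate_toy_ontology(sk.FixtureSpec(n_terms=50, depth=4, seed=1))
graph = sk.parse_obo(obo_text, name="toy-taxonomy")
print(f"parsed {len(graph)} terms, roots: {graph.roots}")

elements = sk.build_element_list(graph)
tree = sk.build_nested_tree(graph)
nodes = sk.build_select_nodes(graph)
for artifact, suffix in [
    (elements, "all_elements"),
    (tree, "tree"),
    (nodes, "nodes"),
]:
    path = sk.write_artifact(artifact, out_dir / f"toy-taxonomy_{suffix}.json.gz")
    print(f"wrote {path} ({path.stat().st_size} bytes, gzipped JSON)")

# the element list is the autocomplete source: every usable label, sorted
print("first elements:", elements.elements[:4])

index = sk.build_term_index(graph)
print('search "homo sap":')
for hit in sk.search_terms(index, "homo sap", limit=3):
    print(f"  {hit.curie}  {hit.label}  ({hit.match_kind})")
# the shorter prefix match ranks first; synonyms resolve to canonical labels
print('resolve "human" ->', index.resolve("human"))
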