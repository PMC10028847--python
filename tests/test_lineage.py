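"""Lineage DAG, ancestry, selection queries and document diffs."""

import random

import pytest

from mams import (
    LineageError,
    MamsDocument,
    ancestry,
    build_lineage,
    descendants,
    diff_documents,
    generate_use_case,
    lineage_to_dot,
    make_entry,
    parse_document,
    select_foms,
    serialize_document,
)


def _chain_doc():
    doc = MamsDocument()
    doc.add_entry(make_entry("FOM", {"id": "fom_raw", "dataset_id": "d",
                                     "processing": "counts"}))
    doc.add_entry(make_entry("FOM", {
        "id": "fom_filtered", "dataset_id": "d",
        "parent_id": ["fom_raw"], "parent_relationship": "subset"}))
    doc.add_entry(make_entry("FOM", {
        "id": "fom_norm", "dataset_id": "d",
        "parent_id": ["fom_filtered"],
        "parent_relationship": "transformation"}))
    return doc


def test_chain_yields_expected_nodes_edges_and_root():
    graph = build_lineage(_chain_doc(), "d")
    assert graph.nodes() == ["fom_filtered", "fom_norm", "fom_raw"]
    assert graph.graph.number_of_edges() == 2
    assert graph.roots() == ["fom_raw"]
    assert graph.relationship("fom_raw", "fom_filtered") == "subset"


def test_ancestry_of_chain_is_the_chain():
    graph = build_lineage(_chain_doc(), "d")
    assert ancestry(graph, "fom_norm") == ["fom_raw", "fom_filtered",
                                           "fom_norm"]
    assert ancestry(graph, "fom_raw") == ["fom_raw"]
    assert descendants(graph, "fom_raw") == ["fom_raw", "fom_filtered",
                                             "fom_norm"]


def test_concatenation_node_has_in_degree_two():
    doc = generate_use_case("multimodal_cite")
    graph = build_lineage(doc, "cite_pbmc")
    assert graph.graph.in_degree("fom_joint") == 2
    assert set(graph.parents("fom_joint")) == {"fom_adt_centered",
                                               "fom_rna_lognorm"}


def test_unknown_node_raises():
    graph = build_lineage(_chain_doc(), "d")
    with pytest.raises(LineageError, match="nope"):
        ancestry(graph, "nope")


def test_cyclic_document_is_refused_with_validation_issue():
    doc = MamsDocument()
    for a, b in (("x", "y"), ("y", "x")):
        doc.add_entry(make_entry("FOM", {
            "id": a, "dataset_id": "d", "parent_id": [b],
            "parent_relationship": "subset"}))
    with pytest.raises(LineageError) as excinfo:
        build_lineage(doc, "d")
    assert any(i.rule_id == "GRAPH001" for i in excinfo.value.issues)


def test_dangling_parent_is_refused():
    doc = MamsDocument()
    doc.add_entry(make_entry("FOM", {
        "id": "a", "dataset_id": "d", "parent_id": ["ghost"],
        "parent_relationship": "subset"}))
    with pytest.raises(LineageError) as excinfo:
        build_lineage(doc, "d")
    assert any(i.rule_id == "REF001" for i in excinfo.value.issues)


def test_provenance_records_attach_to_nodes():
    doc = generate_use_case("simple_rnaseq")
    graph = build_lineage(doc, "scrna_pbmc")
    assert graph.provenance["fom_pca"].get("record_function_name") == \
        "run_pca"
    assert graph.provenance["ong_knn"].id == "rec_knn"


def test_graphs_participate_as_lineage_nodes():
    doc = generate_use_case("simple_rnaseq")
    graph = build_lineage(doc, "scrna_pbmc")
    assert "ong_knn" in graph
    assert graph.parents("ong_knn") == ["fom_pca"]


def test_ancestry_agrees_with_brute_force_reachability():
    """Topologically ordered ancestors match exhaustive DFS reachability
    on random DAGs up to 50 nodes."""
    rng = random.Random(77)
    for _ in range(40):
        n = rng.randint(2, 50)
        doc = MamsDocument()
        order = [f"n{i:02d}" for i in range(n)]
        parents = {}
        for i, node in enumerate(order):
            picked = rng.sample(order[:i], min(i, rng.randint(0, 3)))
            parents[node] = picked
            fields = {"id": node, "dataset_id": "d"}
            if picked:
                fields["parent_id"] = picked
                fields["parent_relationship"] = "transformation"
            doc.add_entry(make_entry("FOM", fields))
        graph = build_lineage(doc, "d")
        target = rng.choice(order)
        got = ancestry(graph, target)

        def reach_up(node, acc):
            for parent in parents[node]:
                if parent not in acc:
                    acc.add(parent)
                    reach_up(parent, acc)
            return acc

        expected = reach_up(target, {target})
        assert set(got) == expected
        positions = {node: i for i, node in enumerate(got)}
        for node in got:
            for parent in parents[node]:
                if parent in positions:
                    assert positions[parent] < positions[node]


def test_select_foms_empty_criteria_matches_all(simple_doc):
    all_ids = select_foms(simple_doc, {})
    assert len(all_ids) == 13
    assert all(i.startswith("fom_") for i in all_ids)


def test_select_foms_conjunctive_exact_match(simple_doc):
    assert select_foms(simple_doc, {"analyte": "rna",
                                    "processing": "lognormalized"}) == \
        ["fom_lognorm"]


def test_hierarchical_matching_expands_to_descendants(simple_doc):
    exact = select_foms(simple_doc, {"processing": "raw"})
    hier = select_foms(simple_doc, {"processing": "raw"},
                       hierarchical=True)
    assert exact == []
    assert set(hier) == {"fom_raw", "fom_filtered", "fom_detected",
                         "fom_nonartifact", "fom_clean"}
    assert set(exact) <= set(hier)


def test_multi_valued_analyte_matches_any_element():
    doc = generate_use_case("multimodal_cite")
    assert "fom_joint" in select_foms(doc, {"analyte": "protein"})
    assert "fom_joint" in select_foms(doc, {"analyte": "rna"})


def test_diff_of_identical_documents_is_empty(simple_doc):
    other = generate_use_case("simple_rnaseq")
    changes = diff_documents(simple_doc, other)
    assert not changes
    assert len(changes) == 0


def test_diff_pinpoints_a_single_field_change(simple_doc):
    other = generate_use_case("simple_rnaseq")
    other.get_entry("scrna_pbmc", "FOM", "fom_umap").fields[
        "processing"] = "reduction"
    changes = diff_documents(simple_doc, other)
    assert len(changes) == 1
    change = changes.changes[0]
    assert change.location == "scrna_pbmc/fom/fom_umap/processing"
    assert (change.a, change.b) == ("embedding", "reduction")


def test_diff_is_symmetric_up_to_direction():
    a = generate_use_case("simple_rnaseq")
    b = generate_use_case("simple_rnaseq")
    from mams import MatrixClass
    del b.datasets["scrna_pbmc"][MatrixClass.FOM]["fom_umap"]
    forward = diff_documents(a, b)
    backward = diff_documents(b, a)
    assert {c.location for c in forward.changes} == \
        {c.location for c in backward.changes}
    kinds = {c.kind for c in forward.changes} | \
        {c.kind for c in backward.changes}
    assert kinds == {"entry-removed", "entry-added"}


def test_diff_across_format_conversion_is_empty(simple_doc):
    text = serialize_document(simple_doc, "yaml")
    assert not diff_documents(parse_document(text, "yaml"), simple_doc)


def test_dot_export_contains_nodes_and_labeled_edges(simple_doc):
    graph = build_lineage(simple_doc, "scrna_pbmc")
    dot = lineage_to_dot(graph)
    assert dot.startswith('digraph "scrna_pbmc"')
    assert '"fom_pca" -> "fom_umap" [label="reduction"];' in dot
    assert '"fom_raw"' in dot
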