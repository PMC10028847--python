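"""Validation engine: rule catalog, perturbation soundness, policies."""

import random

import pytest

from mams import (
    ContractError,
    MamsDocument,
    ValidationPolicy,
    generate_use_case,
    make_entry,
    rule_catalog,
    validate,
)
from perturb import CORRUPTIONS


def _new_issues(corruption):
    clean = generate_use_case("simple_rnaseq")
    baseline = set(validate(clean, corruption.policy).issues)
    corrupted = generate_use_case("simple_rnaseq")
    corruption.apply(corrupted)
    report = validate(corrupted, corruption.policy)
    return [i for i in report.issues if i not in baseline]


@pytest.mark.parametrize("corruption", CORRUPTIONS,
                         ids=[c.rule_id for c in CORRUPTIONS])
def test_each_rule_fires_exactly_at_its_corruption(corruption):
    """One targeted defect -> new issues only for that rule, at the
    corrupted location; the pristine document yields none of them."""
    new = _new_issues(corruption)
    assert new, f"{corruption.rule_id} did not fire"
    assert {i.rule_id for i in new} == {corruption.rule_id}
    assert any(corruption.location_part in i.location for i in new), \
        [i.location for i in new]


def test_catalog_covers_exactly_the_firable_rules():
    catalog_ids = {r.rule_id for r in rule_catalog()}
    assert catalog_ids == {c.rule_id for c in CORRUPTIONS}


def test_catalog_describes_acyclicity_and_open_vocabulary():
    by_id = {r.rule_id: r for r in rule_catalog()}
    assert "acyclic" in by_id["GRAPH001"].description
    assert "open" in by_id["VOC001"].description.lower()


def test_every_emitted_issue_has_a_cataloged_rule():
    catalog_ids = {r.rule_id for r in rule_catalog()}
    for corruption in CORRUPTIONS:
        for issue in _new_issues(corruption):
            assert issue.rule_id in catalog_ids


def test_dangling_reference_reports_ref001_with_location():
    doc = generate_use_case("simple_rnaseq")
    entry = doc.get_entry("scrna_pbmc", "FOM", "fom_umap")
    entry.fields["parent_id"] = ["fomX"]
    report = validate(doc)
    issues = report.by_rule("REF001")
    assert len(issues) == 1
    assert issues[0].location == "scrna_pbmc/fom/fom_umap/parent_id"
    assert not report.passed


def test_custom_term_with_description_twin_is_conformant():
    doc = generate_use_case("simple_rnaseq")
    entry = doc.get_entry("scrna_pbmc", "FOM", "fom_umap")
    entry.fields["processing"] = "vst_residuals"
    assert validate(doc).by_rule("VOC001")
    entry.fields["processing_description"] = \
        "Pearson residuals from a variance-stabilizing transformation"
    assert not validate(doc).by_rule("VOC001")


def test_two_cycle_is_a_graph_error():
    doc = MamsDocument()
    doc.add_entry(make_entry("FOM", {"id": "a", "dataset_id": "d",
                                     "parent_id": ["b"],
                                     "parent_relationship": "subset"}))
    doc.add_entry(make_entry("FOM", {"id": "b", "dataset_id": "d",
                                     "parent_id": ["a"],
                                     "parent_relationship": "subset"}))
    report = validate(doc)
    assert report.by_rule("GRAPH001")
    assert not report.passed


def test_strict_policy_reports_superset_with_upgraded_severities():
    doc = generate_use_case("simple_rnaseq")
    entry = doc.get_entry("scrna_pbmc", "FOM", "fom_umap")
    entry.fields["processing"] = "mystery"
    warn = validate(doc, ValidationPolicy(vocab_strictness="warn"))
    strict = validate(doc, ValidationPolicy.strict())
    warn_keys = {(i.rule_id, i.location) for i in warn.issues}
    strict_keys = {(i.rule_id, i.location) for i in strict.issues}
    assert warn_keys <= strict_keys
    voc_warn = warn.by_rule("VOC001")[0]
    voc_strict = strict.by_rule("VOC001")[0]
    assert voc_warn.severity.value == "warning"
    assert voc_strict.severity.value == "error"
    off = validate(doc, ValidationPolicy(vocab_strictness="off"))
    assert not off.by_rule("VOC001")


def test_report_is_deterministic_and_order_independent():
    doc_a = generate_use_case("simple_rnaseq")
    doc_b = generate_use_case("simple_rnaseq")
    # rebuild one dataset with reversed insertion order
    per_class = doc_b.datasets["scrna_pbmc"]
    for cls in list(per_class):
        per_class[cls] = dict(reversed(list(per_class[cls].items())))
    assert validate(doc_a).issues == validate(doc_b).issues
    assert validate(doc_a).to_json() == validate(doc_b).to_json()


def test_passed_iff_no_error_issues(simple_doc):
    report = validate(simple_doc)
    assert report.passed
    assert report.counts["error"] == 0


def test_internally_inconsistent_document_is_a_contract_error():
    doc = MamsDocument()
    doc.add_entry(make_entry("FOM", {"id": "f1", "dataset_id": "d"}))
    entry = list(doc.entries())[0]
    entry.fields["dataset_id"] = "other"  # bypasses the container
    with pytest.raises(ContractError):
        validate(doc)


def _random_dag_doc(rng, n_nodes, extra_back_edge):
    doc = MamsDocument()
    order = [f"n{i:02d}" for i in range(n_nodes)]
    parents = {}
    for i, node in enumerate(order):
        choices = order[:i]
        picked = rng.sample(choices, min(len(choices), rng.randint(0, 2)))
        parents[node] = picked
    if extra_back_edge and n_nodes > 1:
        child_idx = rng.randrange(n_nodes - 1)
        ancestor_idx = rng.randrange(child_idx + 1, n_nodes)
        parents[order[child_idx]].append(order[ancestor_idx])
    for node in order:
        fields = {"id": node, "dataset_id": "d"}
        if parents[node]:
            fields["parent_id"] = parents[node]
            fields["parent_relationship"] = "transformation"
        doc.add_entry(make_entry("FOM", fields))
    return doc, parents


def _has_cycle_brute_force(parents):
    graph = {child: set(ps) for child, ps in parents.items()}

    def reaches(start, target, seen):
        if start == target:
            return True
        for parent in graph.get(start, ()):
            if parent not in seen:
                seen.add(parent)
                if reaches(parent, target, seen):
                    return True
        return False

    return any(reaches(parent, child, set())
               for child, ps in parents.items() for parent in ps)


def test_cycle_detection_agrees_with_brute_force_reachability():
    """GRAPH001 matches exhaustive reachability on random DAGs with and
    without an injected back-edge (up to 50 nodes)."""
    rng = random.Random(20240901)
    for trial in range(60):
        n = rng.randint(2, 50)
        doc, parents = _random_dag_doc(rng, n, extra_back_edge=trial % 2)
        expected = _has_cycle_brute_force(parents)
        flagged = bool(validate(doc).by_rule("GRAPH001"))
        assert flagged == expected, (trial, n)


def test_report_serializes_to_json_and_table():
    doc = generate_use_case("simple_rnaseq")
    doc.get_entry("scrna_pbmc", "FOM", "fom_umap").fields["parent_id"] = \
        ["nope"]
    report = validate(doc)
    import json as _json
    payload = _json.loads(report.to_json())
    assert payload["passed"] is False
    assert payload["counts"]["error"] >= 1
    assert "REF001" in report.to_table()
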