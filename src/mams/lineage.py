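"""Provenance lineage over MAMS matrices, selection queries and diffs.

The ``parent_id`` declarations of FOM/ONG/FNG entries form a directed
acyclic graph whose arrows mirror the steps of the analysis workflow: raw
matrices are roots, derived matrices point back through edges labeled with
their ``parent_relationship`` (subset, transformation, reduction, ...).
``record_id`` links attach provenance records to nodes. All orderings are
deterministic (lexicographic tie-breaks) so query output is diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import networkx as nx

from . import vocab as _vocab
from .schema import (
    ABSENT,
    MamsDocument,
    MamsError,
    MatrixClass,
    MatrixEntry,
    RecordEntry,
    as_value_list,
)
from .validate import ValidationPolicy, validate

__all__ = [
    "LineageError",
    "LineageGraph",
    "build_lineage",
    "ancestry",
    "descendants",
    "select_foms",
    "ChangeSet",
    "Change",
    "diff_documents",
    "lineage_to_dot",
]

_LINEAGE_CLASSES = (MatrixClass.FOM, MatrixClass.ONG, MatrixClass.FNG)


class LineageError(MamsError):
    """The document cannot yield a lineage graph (cycle, dangling
    reference, or an unknown node was queried)."""

    def __init__(self, message: str, issues=()):
        super().__init__(message)
        self.issues = list(issues)


@dataclass
class LineageGraph:
    """A DAG over matrix ids derived from parent_id declarations.

    Nodes are FOM/ONG/FNG ids annotated with their class and entry; edges
    run parent -> child and carry the child's ``parent_relationship``.
    ``provenance`` maps node ids to their REC entries when linked.
    """

    dataset_id: str
    graph: nx.DiGraph
    provenance: dict[str, RecordEntry] = field(default_factory=dict)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def roots(self) -> list[str]:
        """Nodes with no parents — the most raw, unfiltered matrices."""
        return sorted(n for n in self.graph.nodes
                      if self.graph.in_degree(n) == 0)

    def entry(self, node: str) -> MatrixEntry:
        self._require(node)
        return self.graph.nodes[node]["entry"]

    def parents(self, node: str) -> list[str]:
        self._require(node)
        return sorted(self.graph.predecessors(node))

    def children(self, node: str) -> list[str]:
        self._require(node)
        return sorted(self.graph.successors(node))

    def relationship(self, parent: str, child: str) -> str | None:
        return self.graph.edges[parent, child].get("relationship")

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.graph))

    def _require(self, node: str) -> None:
        if node not in self.graph:
            raise LineageError(
                f"unknown node {node!r} in lineage of dataset "
                f"{self.dataset_id!r}"
            )


_STRUCTURAL_RULES = {"REF001", "GRAPH001", "ID001"}


def build_lineage(doc: MamsDocument, dataset_id: str) -> LineageGraph:
    """Build the lineage DAG for one dataset.

    Refuses — raising :class:`LineageError` carrying the validation
    issues — when the dataset has dangling references or parent cycles.
    """
    if dataset_id not in doc.datasets:
        raise LineageError(f"unknown dataset {dataset_id!r}")
    report = validate(doc, ValidationPolicy(vocab_strictness="off"))
    blocking = [
        issue for issue in report.issues
        if issue.rule_id in _STRUCTURAL_RULES
        and issue.location.startswith(f"{dataset_id}/")
    ]
    if blocking:
        raise LineageError(
            "dataset fails structural validation: "
            + "; ".join(f"{i.rule_id} at {i.location}" for i in blocking),
            issues=blocking,
        )

    graph = nx.DiGraph()
    provenance: dict[str, RecordEntry] = {}
    seen: dict[str, MatrixClass] = {}
    for cls in _LINEAGE_CLASSES:
        for entry in doc.entries(dataset_id, cls):
            if entry.id in seen:
                raise LineageError(
                    f"matrix id {entry.id!r} is used by both "
                    f"{seen[entry.id].value} and {cls.value}; lineage "
                    "node ids must be unambiguous"
                )
            seen[entry.id] = cls
            graph.add_node(entry.id, matrix_class=cls, entry=entry)
            record_id = entry.get("record_id")
            if record_id is not ABSENT:
                record = doc.get_entry(dataset_id, MatrixClass.REC,
                                       str(record_id))
                if isinstance(record, RecordEntry):
                    provenance[entry.id] = record
    for node in list(graph.nodes):
        entry = graph.nodes[node]["entry"]
        relationship = entry.get("parent_relationship")
        label = None if relationship is ABSENT else str(relationship)
        for parent in as_value_list(entry.get("parent_id")):
            graph.add_edge(str(parent), node, relationship=label)
    return LineageGraph(dataset_id=dataset_id, graph=graph,
                        provenance=provenance)


def ancestry(graph: LineageGraph, node: str) -> list[str]:
    """All ancestors of ``node`` in topological order, ending at ``node``.

    Incomparable nodes are ordered lexicographically. Useful for walking a
    matrix back to its most raw, unfiltered form.
    """
    graph._require(node)
    keep = nx.ancestors(graph.graph, node) | {node}
    sub = graph.graph.subgraph(keep)
    return list(nx.lexicographical_topological_sort(sub))


def descendants(graph: LineageGraph, node: str) -> list[str]:
    """All nodes derived from ``node`` (inclusive), topologically ordered."""
    graph._require(node)
    keep = nx.descendants(graph.graph, node) | {node}
    sub = graph.graph.subgraph(keep)
    return list(nx.lexicographical_topological_sort(sub))


# --- selection queries -----------------------------------------------------

def _matches(entry: MatrixEntry, field_key: str, wanted: str,
             hierarchical: bool) -> bool:
    value = entry.get(field_key)
    if value is ABSENT:
        return False
    wanted_norm = _vocab.normalize_token(wanted)
    vocabulary = _vocab.builtin_vocabularies().get(field_key)
    for token in as_value_list(value):
        token = str(token)
        if _vocab.normalize_token(token) == wanted_norm:
            return True
        if hierarchical and vocabulary is not None:
            if token in vocabulary and wanted in vocabulary:
                if _vocab.is_descendant(field_key, token, wanted):
                    return True
    return False


def select_foms(doc: MamsDocument, criteria: Mapping[str, str],
                hierarchical: bool = False,
                dataset_id: str | None = None) -> list[str]:
    """Ids of FOMs satisfying every field=token constraint (conjunctive).

    With ``hierarchical`` matching, a constraint token also matches any
    descendant term — ``processing=raw`` retrieves counts and intensities
    matrices. Empty criteria matches every FOM.
    """
    out = []
    for entry in doc.entries(dataset_id, MatrixClass.FOM):
        if all(_matches(entry, k, v, hierarchical)
               for k, v in criteria.items()):
            out.append(entry.id)
    return sorted(out)


# --- document diff ---------------------------------------------------------

@dataclass(frozen=True)
class Change:
    kind: str          # entry-added | entry-removed | value-changed
    location: str      # dataset/class/id[/field]
    a: Any = None
    b: Any = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "location": self.location,
                "a": self.a, "b": self.b}


@dataclass
class ChangeSet:
    """Symmetric field-level difference between two documents."""

    changes: list[Change] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.changes)

    def __len__(self) -> int:
        return len(self.changes)

    def to_json(self) -> str:
        return json.dumps([c.to_dict() for c in self.changes],
                          indent=2, default=str) + "\n"


def _entry_index(doc: MamsDocument) -> dict[tuple, MatrixEntry]:
    return {
        (e.dataset_id, e.matrix_class.value.lower(), e.id): e
        for e in doc.entries()
    }


def diff_documents(a: MamsDocument, b: MamsDocument) -> ChangeSet:
    """Field-level diff; empty iff the documents are semantically equal
    (key order never matters)."""
    changes: list[Change] = []
    if a.spec_version != b.spec_version:
        changes.append(Change("value-changed", "spec_version",
                              a.spec_version, b.spec_version))
    for key in sorted(set(a.extras) | set(b.extras)):
        left, right = a.extras.get(key), b.extras.get(key)
        if left != right:
            changes.append(Change("value-changed", key, left, right))
    index_a, index_b = _entry_index(a), _entry_index(b)
    for key in sorted(set(index_a) | set(index_b)):
        location = "/".join(key)
        if key not in index_b:
            changes.append(Change("entry-removed", location))
            continue
        if key not in index_a:
            changes.append(Change("entry-added", location))
            continue
        entry_a, entry_b = index_a[key], index_b[key]
        fields_a = dict(entry_a.items())
        fields_b = dict(entry_b.items())
        for field_key in sorted(set(fields_a) | set(fields_b)):
            left = fields_a.get(field_key, ABSENT)
            right = fields_b.get(field_key, ABSENT)
            if left != right:
                changes.append(Change(
                    "value-changed", f"{location}/{field_key}",
                    None if left is ABSENT else left,
                    None if right is ABSENT else right,
                ))
    return ChangeSet(changes=changes)


# --- DOT export ------------------------------------------------------------

def lineage_to_dot(graph: LineageGraph) -> str:
    """Render the lineage DAG as DOT text for visualization."""
    lines = [f'digraph "{graph.dataset_id}" {{',
             "  rankdir=TB;"]
    for node in graph.nodes():
        entry = graph.entry(node)
        cls = entry.matrix_class.value
        processing = entry.get("processing")
        label = f"{node}\\n[{cls}]"
        if processing is not ABSENT:
            label += f"\\n{processing}"
        shape = "box" if cls == "FOM" else "ellipse"
        lines.append(f'  "{node}" [label="{label}", shape={shape}];')
    for parent, child in sorted(graph.graph.edges):
        relationship = graph.relationship(parent, child)
        attr = f' [label="{relationship}"]' if relationship else ""
        lines.append(f'  "{parent}" -> "{child}"{attr};')
    lines.append("}")
    return "\n".join(lines) + "\n"
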