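"""Validation of MAMS documents against structural and semantic rules.

Rules are identified by stable codes (``REF001``, ``GRAPH001``, ...) and
problems are *reported*, never raised — the open-vocabulary philosophy of
the standard means most findings are warnings or informational notes by
default. A described custom term (one accompanied by its
``<field>_description`` twin) is conformant and is not flagged at any
strictness.

The one exception: a document object that violates its own container
invariants (an entry filed under the wrong dataset key) raises
:class:`~mams.schema.ContractError`, since such an object cannot have come
from the parser.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from typing import Iterator

import networkx as nx

from . import vocab as _vocab
from .schema import (
    ABSENT,
    MamsDocument,
    MatrixClass,
    MatrixEntry,
    ValueKind,
    as_value_list,
    field_spec,
)

__all__ = [
    "Severity",
    "Issue",
    "Rule",
    "ValidationPolicy",
    "ValidationReport",
    "validate",
    "rule_catalog",
]


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"
    INFO = "info"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Issue:
    """One finding: severity, stable rule id, document location, message.

    ``location`` is ``dataset_id/class_section/matrix_id[/field]`` and is
    always resolvable back into the document.
    """

    severity: Severity
    rule_id: str
    location: str
    message: str

    def to_dict(self) -> dict:
        return {
            "severity": self.severity.value,
            "rule_id": self.rule_id,
            "location": self.location,
            "message": self.message,
        }


@dataclass(frozen=True)
class Rule:
    rule_id: str
    default_severity: Severity
    description: str


_RULES = (
    Rule("ID001", Severity.ERROR,
         "Entry ids must be non-empty and non-blank."),
    Rule("REF001", Severity.ERROR,
         "Every reference field (parent_id, record_id, oid, fid, obs, fea) "
         "must resolve to an entry of the expected class within the same "
         "dataset."),
    Rule("CLASS001", Severity.WARNING,
         "A registry field is placed on a matrix class it does not apply "
         "to (e.g. edge_metric on a FOM)."),
    Rule("GRAPH001", Severity.ERROR,
         "The parent_id relation over FOMs must be acyclic (self-loops "
         "included)."),
    Rule("GRAPH002", Severity.WARNING,
         "A FOM with parent_id should state its parent_relationship."),
    Rule("GRAPH003", Severity.WARNING,
         "A concatenation or aggregation relationship expects multiple "
         "parents."),
    Rule("GRAPH004", Severity.WARNING,
         "A subset, transformation or reduction relationship expects a "
         "single parent."),
    Rule("VOC001", Severity.WARNING,
         "A term outside the suggested vocabulary for its field; "
         "suppressed when the <field>_description twin describes the "
         "custom term (open-vocabulary policy)."),
    Rule("REC001", Severity.ERROR,
         "record_runtime_end must not precede record_runtime_start when "
         "both parse as timestamps."),
    Rule("CID001", Severity.ERROR,
         "On OID/FID entries a delimiter is present if and only if "
         "is_compound is true."),
    Rule("SUB001", Severity.INFO,
         "A subset-relationship child declares a broader obs_subset term "
         "than its parent (expected ordering: full ⊇ filtered ⊇ detected "
         "⊇ nonartifact ⊇ clean)."),
    Rule("FLD001", Severity.INFO,
         "A field key outside the MAMS registry (preserved as an extra; "
         "extras are legal)."),
    Rule("FS001", Severity.WARNING,
         "A filepath value does not exist on the local filesystem "
         "(opt-in check)."),
    Rule("PROV001", Severity.WARNING,
         "A derived FOM (one with parent_id) carries no record_id "
         "provenance link (opt-in check)."),
)

_RULES_BY_ID = {r.rule_id: r for r in _RULES}


def rule_catalog() -> list[Rule]:
    """Every implemented rule with stable id, default severity and
    description; documentation is generated from this."""
    return list(_RULES)


@dataclass(frozen=True)
class ValidationPolicy:
    """Tunable strictness.

    The default reflects the standard's open-vocabulary stance: custom
    terms warn rather than fail, provenance links are optional, and
    filepaths are never touched unless asked.
    """

    vocab_strictness: str = "warn"  # off | warn | strict
    require_record_links: bool = False
    check_filepaths_exist: bool = False
    treat_warnings_as_errors: bool = False

    @classmethod
    def strict(cls) -> "ValidationPolicy":
        return cls(vocab_strictness="strict")


@dataclass
class ValidationReport:
    """Ordered list of issues with severity counts."""

    issues: list[Issue] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out = {s.value: 0 for s in Severity}
        for issue in self.issues:
            out[issue.severity.value] += 1
        return out

    @property
    def passed(self) -> bool:
        return self.counts["error"] == 0

    def by_rule(self, rule_id: str) -> list[Issue]:
        return [i for i in self.issues if i.rule_id == rule_id]

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "counts": self.counts,
                "issues": [i.to_dict() for i in self.issues],
            },
            indent=2,
        ) + "\n"

    def to_table(self) -> str:
        """Plain-text tabulation for terminal display."""
        if not self.issues:
            return "no issues\n"
        rows = [("SEVERITY", "RULE", "LOCATION", "MESSAGE")]
        rows += [(i.severity.value, i.rule_id, i.location, i.message)
                 for i in self.issues]
        widths = [max(len(r[c]) for r in rows) for c in range(3)]
        lines = [
            "  ".join([r[0].ljust(widths[0]), r[1].ljust(widths[1]),
                       r[2].ljust(widths[2]), r[3]])
            for r in rows
        ]
        return "\n".join(lines) + "\n"


# --- rule machinery --------------------------------------------------------

_OBS_SUBSET_RANK = {"full": 0, "filtered": 1, "detected": 2,
                    "nonartifact": 3, "clean": 4}
_MULTI_PARENT = {"concatenation"}
_SINGLE_PARENT = {"subset", "transformation", "reduction"}
_AGGREGATION = {"aggregation"}


def _section(cls: MatrixClass) -> str:
    return cls.value.lower()


def _loc(entry: MatrixEntry, field_key: str | None = None) -> str:
    parts = [entry.dataset_id, _section(entry.matrix_class), entry.id]
    if field_key:
        parts.append(field_key)
    return "/".join(parts)


class _Collector:
    def __init__(self, policy: ValidationPolicy):
        self.policy = policy
        self.issues: list[Issue] = []

    def add(self, rule_id: str, location: str, message: str,
            severity: Severity | None = None) -> None:
        if severity is None:
            severity = _RULES_BY_ID[rule_id].default_severity
        self.issues.append(Issue(severity, rule_id, location, message))


def validate(doc: MamsDocument,
             policy: ValidationPolicy | None = None) -> ValidationReport:
    """Apply the full rule catalog to a document.

    Findings are reported, not raised; ``report.passed`` is true iff no
    error-severity issue was produced. Raises
    :class:`~mams.schema.ContractError` only for an internally
    inconsistent document object.
    """
    if policy is None:
        policy = ValidationPolicy()
    doc.check_invariants()
    collector = _Collector(policy)
    for entry in doc.entries():
        _check_entry(doc, entry, collector)
    for dataset_id in doc.dataset_ids():
        _check_parent_graph(doc, dataset_id, collector)
    issues = sorted(
        collector.issues,
        key=lambda i: (i.location, i.rule_id, i.message),
    )
    return ValidationReport(issues=issues)


def _check_entry(doc: MamsDocument, entry: MatrixEntry,
                 collector: _Collector) -> None:
    policy = collector.policy
    cls = entry.matrix_class

    if not entry.id.strip():
        collector.add("ID001", _loc(entry, "id"),
                      f"blank id {entry.id!r}")

    for key in entry.fields:
        spec = field_spec(key)
        if spec is not None and cls not in spec.applies_to:
            applies = ", ".join(sorted(c.value for c in spec.applies_to))
            collector.add(
                "CLASS001", _loc(entry, key),
                f"field {key!r} applies to {applies}, not {cls.value}",
            )
    for key in entry.extras:
        collector.add("FLD001", _loc(entry, key),
                      f"unknown field {key!r} preserved as extra")

    _check_references(doc, entry, collector)
    _check_vocab(entry, collector)

    if cls in (MatrixClass.OID, MatrixClass.FID):
        _check_compound_id(entry, collector)
    if cls is MatrixClass.REC:
        _check_runtimes(entry, collector)

    if policy.check_filepaths_exist:
        filepath = entry.get("filepath")
        if filepath is not ABSENT and not os.path.exists(str(filepath)):
            collector.add("FS001", _loc(entry, "filepath"),
                          f"filepath {filepath!r} does not exist")

    if (policy.require_record_links and cls is MatrixClass.FOM
            and entry.get("parent_id") is not ABSENT
            and entry.get("record_id") is ABSENT):
        collector.add("PROV001", _loc(entry, "record_id"),
                      "derived FOM has no provenance record link")


def _check_references(doc: MamsDocument, entry: MatrixEntry,
                      collector: _Collector) -> None:
    cls = entry.matrix_class
    for key, value in entry.fields.items():
        spec = field_spec(key)
        if spec is None or cls not in spec.applies_to:
            continue
        if spec.value_kind not in (ValueKind.ID_REF, ValueKind.ID_REF_LIST):
            continue
        if cls is MatrixClass.REC and key == "record_id":
            continue  # the REC's own id, not a link
        target_cls = spec.ref_class
        for ref in as_value_list(value):
            target = doc.get_entry(entry.dataset_id, target_cls, str(ref))
            if target is None:
                collector.add(
                    "REF001", _loc(entry, key),
                    f"{key} {ref!r} does not resolve to a "
                    f"{target_cls.value} entry in dataset "
                    f"{entry.dataset_id!r}",
                )


def _has_twin(entry: MatrixEntry, field_key: str) -> bool:
    spec = field_spec(field_key)
    if spec is None or not spec.has_description_twin:
        return False
    twin = entry.get(f"{field_key}_description")
    return twin is not ABSENT and str(twin).strip() != ""


def _check_vocab(entry: MatrixEntry, collector: _Collector) -> None:
    strictness = collector.policy.vocab_strictness
    if strictness == "off":
        return
    severity = (Severity.ERROR if strictness == "strict"
                else Severity.WARNING)
    vocabularies = _vocab.builtin_vocabularies()
    cls = entry.matrix_class
    for key, value in entry.fields.items():
        spec = field_spec(key)
        if (spec is None or cls not in spec.applies_to
                or spec.value_kind not in (ValueKind.TERM,
                                           ValueKind.TERM_LIST)):
            continue
        vocabulary = vocabularies.get(key)
        if vocabulary is None or not vocabulary.enforced:
            continue
        if _has_twin(entry, key):
            continue  # a described custom term is conformant
        for token in as_value_list(value):
            if str(token) not in vocabulary:
                collector.add(
                    "VOC001", _loc(entry, key),
                    f"{token!r} is not a suggested {key} term and no "
                    f"{key}_description is provided",
                    severity=severity,
                )


def _check_compound_id(entry: MatrixEntry, collector: _Collector) -> None:
    is_compound = entry.get("is_compound")
    delimiter = entry.get("delimiter")
    compound = bool(is_compound) if is_compound is not ABSENT else False
    if compound and delimiter is ABSENT:
        collector.add("CID001", _loc(entry, "delimiter"),
                      "is_compound is true but no delimiter is given")
    elif not compound and delimiter is not ABSENT:
        collector.add("CID001", _loc(entry, "delimiter"),
                      "delimiter given but is_compound is not true")


def _parse_timestamp(value) -> datetime | None:
    try:
        return datetime.fromisoformat(str(value).replace("Z", "+00:00"))
    except (ValueError, TypeError):
        return None


def _check_runtimes(entry: MatrixEntry, collector: _Collector) -> None:
    start = entry.get("record_runtime_start")
    end = entry.get("record_runtime_end")
    if start is ABSENT or end is ABSENT:
        return
    start_dt, end_dt = _parse_timestamp(start), _parse_timestamp(end)
    if start_dt is None or end_dt is None:
        return  # stored verbatim; unparseable values are not judged
    if (start_dt.tzinfo is None) != (end_dt.tzinfo is None):
        return
    if end_dt < start_dt:
        collector.add(
            "REC001", _loc(entry, "record_runtime_end"),
            f"record_runtime_end {end!r} precedes start {start!r}",
        )


def _fom_parent_edges(doc: MamsDocument, dataset_id: str
                      ) -> Iterator[tuple[str, str]]:
    for entry in doc.entries(dataset_id, MatrixClass.FOM):
        for parent in as_value_list(entry.get("parent_id")):
            yield str(parent), entry.id


def _check_parent_graph(doc: MamsDocument, dataset_id: str,
                        collector: _Collector) -> None:
    foms = {e.id: e for e in doc.entries(dataset_id, MatrixClass.FOM)}
    graph = nx.DiGraph()
    graph.add_nodes_from(foms)
    for parent, child in _fom_parent_edges(doc, dataset_id):
        if parent in foms:  # dangling parents already flagged by REF001
            graph.add_edge(parent, child)

    for cycle in sorted(nx.simple_cycles(graph), key=lambda c: sorted(c)):
        anchor = min(cycle)
        path = " -> ".join([*cycle, cycle[0]])
        collector.add(
            "GRAPH001",
            f"{dataset_id}/fom/{anchor}/parent_id",
            f"parent_id cycle: {path}",
        )

    for entry in foms.values():
        parents = as_value_list(entry.get("parent_id"))
        if not parents:
            continue
        relationship = entry.get("parent_relationship")
        if relationship is ABSENT:
            collector.add(
                "GRAPH002", _loc(entry, "parent_relationship"),
                "parent_id present but parent_relationship missing",
            )
            continue
        token = _vocab.normalize_token(str(relationship))
        if token in (_MULTI_PARENT | _AGGREGATION) and len(parents) == 1:
            collector.add(
                "GRAPH003", _loc(entry, "parent_id"),
                f"{relationship} relationship with a single parent",
            )
        elif token in _SINGLE_PARENT and len(parents) > 1:
            collector.add(
                "GRAPH004", _loc(entry, "parent_id"),
                f"{relationship} relationship with {len(parents)} parents",
            )
        if token == "subset" and len(parents) == 1:
            _check_subset_ordering(entry, foms.get(str(parents[0])),
                                   collector)


def _check_subset_ordering(child: MatrixEntry, parent: MatrixEntry | None,
                           collector: _Collector) -> None:
    if parent is None:
        return
    child_token = child.get("obs_subset")
    parent_token = parent.get("obs_subset")
    if child_token is ABSENT or parent_token is ABSENT:
        return
    child_rank = _OBS_SUBSET_RANK.get(
        _vocab.normalize_token(str(child_token)))
    parent_rank = _OBS_SUBSET_RANK.get(
        _vocab.normalize_token(str(parent_token)))
    if child_rank is None or parent_rank is None:
        return
    if child_rank < parent_rank:
        collector.add(
            "SUB001", _loc(child, "obs_subset"),
            f"subset child declares broader obs_subset "
            f"{child_token!r} than its parent's {parent_token!r}",
        )
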