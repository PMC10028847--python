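"""Reading and writing MAMS documents as JSON or YAML.

The canonical on-disk layout is a list-like nested mapping::

    {dataset_id: {class_section: {matrix_id: {field: value, ...}}}}

with class sections named ``fom``/``fea``/``obs``/``oid``/``fid``/``ong``/
``fng``/``rec`` (lower-case on output, case-insensitive on input). Each
entry's mapping key IS its id (``record_id`` for REC); an explicit id field
inside the body must match. A single-dataset shorthand with class sections
at the top level is accepted on input (tolerant reading, strict writing).

Parsing performs no validation beyond structure — parse-then-validate
separation — and is lossless: unknown top-level content and unknown entry
fields are preserved verbatim. Emission is deterministic (sorted datasets,
sections and ids; fields in registry order, then extras sorted) so
serializing twice yields byte-identical text. ``filepath``/``accessor``
values inside documents are opaque strings; the matrix payload files they
point at are never opened here.
"""

from __future__ import annotations

import json
from typing import Any, Mapping

import yaml

from .schema import (
    SPEC_VERSION,
    DuplicateIdError,
    MamsDocument,
    MamsError,
    MatrixClass,
    MatrixEntry,
    field_registry,
    make_entry,
)

__all__ = [
    "ParseError",
    "StructuralError",
    "parse_document",
    "parse_file",
    "serialize_document",
    "write_file",
    "convert",
    "document_to_tree",
    "document_from_tree",
]

_CLASS_SECTIONS = {c.value.lower(): c for c in MatrixClass}
_DEFAULT_DATASET_ID = "dataset"
_RESERVED_TOP_KEYS = {"spec_version"}


class ParseError(MamsError):
    """The text is not well-formed JSON/YAML."""


class StructuralError(MamsError):
    """Well-formed text that does not follow the MAMS document layout."""


# --- low-level loading -----------------------------------------------------

def _json_pairs_hook(pairs):
    mapping: dict[str, Any] = {}
    for key, value in pairs:
        if key in mapping:
            raise DuplicateIdError(f"duplicate key {key!r} in JSON mapping")
        mapping[key] = value
    return mapping


class _StrictYamlLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys and leaves ISO
    timestamps as plain strings (so JSON and YAML parse identically)."""

    def construct_mapping(self, node, deep=False):
        mapping = {}
        for key_node, value_node in node.value:
            key = self.construct_object(key_node, deep=deep)
            if key in mapping:
                raise DuplicateIdError(
                    f"duplicate key {key!r} in YAML mapping at line "
                    f"{key_node.start_mark.line + 1}"
                )
            mapping[key] = self.construct_object(value_node, deep=deep)
        return mapping


# strip the implicit !!timestamp resolver
_StrictYamlLoader.yaml_implicit_resolvers = {
    prefix: [
        (tag, regexp) for tag, regexp in resolvers
        if tag != "tag:yaml.org,2002:timestamp"
    ]
    for prefix, resolvers in yaml.SafeLoader.yaml_implicit_resolvers.items()
}


def _load_tree(text: str, fmt: str) -> Any:
    fmt = _resolve_format(text, fmt)
    if fmt == "json":
        try:
            return json.loads(text, object_pairs_hook=_json_pairs_hook)
        except json.JSONDecodeError as exc:
            raise ParseError(
                f"invalid JSON at line {exc.lineno}, column {exc.colno}: "
                f"{exc.msg}"
            ) from exc
    try:
        return yaml.load(text, Loader=_StrictYamlLoader)
    except DuplicateIdError:
        raise
    except yaml.MarkedYAMLError as exc:
        mark = exc.problem_mark
        where = (f" at line {mark.line + 1}, column {mark.column + 1}"
                 if mark else "")
        raise ParseError(f"invalid YAML{where}: {exc.problem}") from exc
    except yaml.YAMLError as exc:
        raise ParseError(f"invalid YAML: {exc}") from exc


def _resolve_format(text: str, fmt: str) -> str:
    if fmt not in {"json", "yaml", "auto"}:
        raise MamsError(f"unknown format {fmt!r}; expected json/yaml/auto")
    if fmt != "auto":
        return fmt
    stripped = text.lstrip()
    return "json" if stripped.startswith("{") else "yaml"


# --- tree <-> document -----------------------------------------------------

def _is_dataset_shaped(value: Any) -> bool:
    # any mapping under a top-level key is read as a dataset, so a
    # misspelled class section inside it errors instead of being silently
    # preserved; only non-mapping top-level values become extras
    return isinstance(value, Mapping)


def document_from_tree(tree: Any) -> MamsDocument:
    """Build a :class:`MamsDocument` from a parsed JSON/YAML tree."""
    if tree is None:
        tree = {}
    if not isinstance(tree, Mapping):
        raise StructuralError(
            "document root must be a mapping, got "
            f"{type(tree).__name__}"
        )
    doc = MamsDocument(spec_version=str(tree.get("spec_version",
                                                 SPEC_VERSION)))
    # single-dataset shorthand: class sections at the top level
    if any(str(k).lower() in _CLASS_SECTIONS for k in tree):
        sections = {k: v for k, v in tree.items()
                    if k not in _RESERVED_TOP_KEYS}
        _read_dataset(doc, None, sections)
        return doc
    for key, value in tree.items():
        if key in _RESERVED_TOP_KEYS:
            continue
        if _is_dataset_shaped(value):
            _read_dataset(doc, str(key), value)
        else:
            doc.extras[str(key)] = value
    return doc


def _read_dataset(doc: MamsDocument, dataset_id: str | None,
                  sections: Mapping) -> None:
    if dataset_id is not None:
        doc.datasets.setdefault(dataset_id, {})
    for section, entries in sections.items():
        cls = _CLASS_SECTIONS.get(str(section).lower())
        if cls is None:
            raise StructuralError(
                f"unknown class section {section!r} in dataset "
                f"{dataset_id!r}; expected one of "
                f"{', '.join(sorted(_CLASS_SECTIONS))}"
            )
        if entries is None:
            continue
        if not isinstance(entries, Mapping):
            raise StructuralError(
                f"class section {section!r} must map matrix ids to "
                "field mappings"
            )
        for matrix_id, body in entries.items():
            _read_entry(doc, dataset_id, cls, str(matrix_id), body)


def _read_entry(doc: MamsDocument, dataset_id: str | None,
                cls: MatrixClass, matrix_id: str, body: Any) -> None:
    if body is None:
        body = {}
    if not isinstance(body, Mapping):
        raise StructuralError(
            f"entry {matrix_id!r} must be a mapping of fields"
        )
    fields = dict(body)
    id_key = "record_id" if cls is MatrixClass.REC else "id"
    declared = fields.get(id_key)
    if declared is not None and str(declared) != matrix_id:
        raise StructuralError(
            f"entry keyed {matrix_id!r} declares {id_key}="
            f"{declared!r}; the mapping key is the id and must match"
        )
    fields[id_key] = matrix_id
    declared_ds = fields.get("dataset_id")
    if dataset_id is not None:
        if declared_ds is not None and str(declared_ds) != dataset_id:
            raise StructuralError(
                f"entry {matrix_id!r} declares dataset_id="
                f"{declared_ds!r} but is filed under dataset "
                f"{dataset_id!r}"
            )
        fields["dataset_id"] = dataset_id
    elif declared_ds is None:
        fields["dataset_id"] = _DEFAULT_DATASET_ID
    doc.add_entry(make_entry(cls, fields))


_FIELD_ORDER = {spec.key: i for i, spec in enumerate(field_registry())}


def _entry_body(entry: MatrixEntry) -> dict[str, Any]:
    # the mapping key encodes the id (record_id for REC) and the dataset
    # key encodes dataset_id, so neither is repeated in the body
    positional = {"id", "dataset_id", "class"}
    if entry.matrix_class is MatrixClass.REC:
        positional.add("record_id")
    body: dict[str, Any] = {}
    ordered = sorted(
        (k for k in entry.fields if k not in positional),
        key=lambda k: _FIELD_ORDER[k],
    )
    for key in ordered:
        body[key] = entry.fields[key]
    for key in sorted(entry.extras):
        body[key] = entry.extras[key]
    return body


def document_to_tree(doc: MamsDocument) -> dict[str, Any]:
    """Render a document to the canonical nested-mapping layout."""
    tree: dict[str, Any] = {"spec_version": doc.spec_version}
    for dataset_id in sorted(doc.datasets):
        per_class = doc.datasets[dataset_id]
        sections: dict[str, Any] = {}
        for section in sorted(_CLASS_SECTIONS):
            cls = _CLASS_SECTIONS[section]
            collection = per_class.get(cls)
            if not collection:
                continue
            sections[section] = {
                matrix_id: _entry_body(collection[matrix_id])
                for matrix_id in sorted(collection)
            }
        tree[dataset_id] = sections
    for key in sorted(doc.extras):
        tree[key] = doc.extras[key]
    return tree


# --- public API ------------------------------------------------------------

def parse_document(text: str, format: str = "auto") -> MamsDocument:
    """Parse MAMS text in JSON or YAML (``auto`` sniffs the first
    non-space byte) into a :class:`MamsDocument`. No validation beyond
    structure is performed."""
    return document_from_tree(_load_tree(text, format))


def parse_file(path: str, format: str = "auto") -> MamsDocument:
    """Parse a ``.json``/``.yaml``/``.yml`` file; ``auto`` sniffs by
    extension, then by content."""
    with open(path, "r", encoding="utf-8") as handle:
        text = handle.read()
    if format == "auto":
        lower = str(path).lower()
        if lower.endswith(".json"):
            format = "json"
        elif lower.endswith((".yaml", ".yml")):
            format = "yaml"
    return parse_document(text, format)


class _BlockDumper(yaml.SafeDumper):
    pass


def serialize_document(doc: MamsDocument, format: str = "json") -> str:
    """Serialize deterministically; ``parse_document(serialize_document(d))``
    equals ``d`` and serializing twice is byte-identical."""
    tree = document_to_tree(doc)
    if format == "json":
        return json.dumps(tree, indent=2, ensure_ascii=False,
                          sort_keys=False) + "\n"
    if format == "yaml":
        return yaml.dump(tree, Dumper=_BlockDumper,
                         default_flow_style=False, sort_keys=False,
                         allow_unicode=True)
    raise MamsError(f"unknown format {format!r}; expected json or yaml")


def write_file(doc: MamsDocument, path: str,
               format: str | None = None) -> None:
    if format is None:
        format = "yaml" if str(path).lower().endswith((".yaml", ".yml")) \
            else "json"
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(serialize_document(doc, format))


def convert(text: str, from_format: str = "auto",
            to_format: str = "json") -> str:
    """Convert between JSON and YAML with no semantic change."""
    return serialize_document(parse_document(text, from_format), to_format)
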