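"""Core data model for MAMS (Matrix and Analysis Metadata Standards).

MAMS describes metadata *about* feature-observation matrices (FOMs) and the
satellite structures produced by single-cell analysis workflows — annotation
data frames, identifier vectors, neighborhood graphs, and provenance records.
This module defines the eight matrix classes, the registry of every
recognized metadata field with its class applicability, and the in-memory
entry/document containers. No file I/O and no vocabulary checking happens
here: serialization and validation are separate layers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterator, Mapping

#: Version string of the MAMS profile this implementation targets.
SPEC_VERSION = "1.0"


class MamsError(Exception):
    """Base class for all errors raised by this package."""


class UnknownClassError(MamsError):
    """A matrix class name outside the eight MAMS classes."""


class EntryConstructionError(MamsError):
    """An entry could not be built (missing id/dataset_id, class mismatch)."""


class DuplicateIdError(MamsError):
    """Two entries share an id within the same (dataset, class) scope."""


class ContractError(MamsError):
    """A document object violates its own structural invariants."""


class _Absent:
    """Singleton marker for a field that is not present on an entry."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


#: Returned by accessors when a field is absent; distinguishable from any
#: legal field value (including None, "" and False).
ABSENT = _Absent()


class MatrixClass(str, Enum):
    """The eight MAMS matrix classes.

    FOM holds biological measurements at any processing stage (raw counts
    through reduced-dimensional representations); FEA/OBS hold feature and
    observation annotations; OID/FID hold unique identifier vectors;
    ONG/FNG hold observation and feature neighborhood graphs; REC holds
    provenance records for the operations that produced the other matrices.
    """

    FOM = "FOM"
    FEA = "FEA"
    OBS = "OBS"
    OID = "OID"
    FID = "FID"
    ONG = "ONG"
    FNG = "FNG"
    REC = "REC"

    @classmethod
    def coerce(cls, value: "MatrixClass | str") -> "MatrixClass":
        """Canonicalize a class name case-insensitively ("fom" == "FOM")."""
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).strip().upper()]
        except KeyError:
            raise UnknownClassError(
                f"unknown matrix class {value!r}; expected one of "
                f"{', '.join(c.value for c in cls)}"
            ) from None

    def __str__(self) -> str:
        return self.value


ALL_CLASSES = frozenset(MatrixClass)
_NON_REC = frozenset(c for c in MatrixClass if c is not MatrixClass.REC)


class ValueKind(str, Enum):
    """What a field's value is: free text, a vocabulary term, a reference..."""

    FREE_TEXT = "free-text"
    TERM = "term"
    TERM_LIST = "term-list"
    ID_REF = "id-ref"
    ID_REF_LIST = "id-ref-list"
    KEY_VALUE_MAP = "key-value-map"
    TIMESTAMP = "timestamp"
    DURATION = "duration"
    PATH = "path"
    COMMAND_STRING = "command-string"


@dataclass(frozen=True)
class FieldSpec:
    """One canonical MAMS field: its name, applicability and value shape.

    ``ref_class`` names the matrix class an id-ref(-list) value must resolve
    into. ``has_description_twin`` marks fields with a recognized
    ``<key>_description`` companion carrying free-text for custom terms.
    """

    key: str
    applies_to: frozenset[MatrixClass]
    value_kind: ValueKind
    description: str = ""
    has_description_twin: bool = False
    required: bool = False
    ref_class: MatrixClass | None = None


def _spec(key, classes, kind, desc, twin=False, required=False, ref=None):
    return FieldSpec(
        key=key,
        applies_to=frozenset(classes),
        value_kind=kind,
        description=desc,
        has_description_twin=twin,
        required=required,
        ref_class=ref,
    )


_K = ValueKind
_C = MatrixClass

# Registry order is the canonical field emission order used by serialization.
_REGISTRY: tuple[FieldSpec, ...] = (
    _spec("id", ALL_CLASSES, _K.FREE_TEXT,
          "Unique id of the matrix, annotation data frame, or graph; unique "
          "within the set of objects of the same class of the dataset.",
          required=True),
    _spec("dataset_id", ALL_CLASSES, _K.FREE_TEXT,
          "Groups matrices whose observations and features belong to a "
          "superset encompassing an entire dataset.", required=True),
    _spec("class", ALL_CLASSES, _K.TERM,
          "The class of the matrix, array, or data frame."),
    _spec("data_type", {_C.FOM}, _K.TERM,
          "Explicit type of the data stored in the FOM (e.g. int, double)."),
    _spec("representation", {_C.FOM}, _K.TERM,
          "Preferred representation of the matrix (e.g. dense, sparse)."),
    _spec("obs_unit", {_C.FOM}, _K.TERM,
          "Biological unit of the observations (e.g. cell, droplet, roi)."),
    _spec("processing", {_C.FOM}, _K.TERM,
          "Nature of the data contained within the matrix from the analysis "
          "perspective (raw, normalized, reduction, ...).", twin=True),
    _spec("analyte", {_C.FOM}, _K.TERM_LIST,
          "Biological analyte(s) quantified in the matrix.", twin=True),
    _spec("modality", {_C.FOM}, _K.TERM_LIST,
          "Modality of the matrix; a broader integration axis that may "
          "coincide with the analyte or span species/technologies.",
          twin=True),
    _spec("obs_subset", {_C.FOM}, _K.TERM,
          "Subset of observations present in the FOM (level of filtering or "
          "biological category).", twin=True),
    _spec("feature_subset", {_C.FOM}, _K.TERM,
          "Subset of features present in the FOM (e.g. highly variable).",
          twin=True),
    _spec("processing_description", {_C.FOM}, _K.FREE_TEXT,
          "Free-text description of the processing term."),
    _spec("analyte_description", {_C.FOM}, _K.FREE_TEXT,
          "Free-text description of the analyte term(s)."),
    _spec("modality_description", {_C.FOM}, _K.FREE_TEXT,
          "Free-text description of the modality term(s)."),
    _spec("obs_subset_description", {_C.FOM}, _K.FREE_TEXT,
          "Free-text description of the observation subset."),
    _spec("feature_subset_description", {_C.FOM}, _K.FREE_TEXT,
          "Free-text description of the feature subset."),
    _spec("parent_id", {_C.FOM, _C.ONG, _C.FNG}, _K.ID_REF_LIST,
          "Id(s) of the parent matrices used to produce this matrix.",
          ref=_C.FOM),
    _spec("parent_relationship", {_C.FOM}, _K.TERM,
          "Operation relating this matrix to its parent(s): transformation, "
          "subset, concatenation, reduction, factorization, aggregation."),
    _spec("is_compound", {_C.OID, _C.FID}, _K.FREE_TEXT,
          "Whether the ID is a compound ID joined from several character "
          "vectors by a delimiter."),
    _spec("delimiter", {_C.OID, _C.FID}, _K.FREE_TEXT,
          "Delimiter separating the components of a compound ID."),
    _spec("edge_metric", {_C.ONG, _C.FNG}, _K.FREE_TEXT,
          "Name of the distance or similarity metric used to create the "
          "edges of the neighborhood graph."),
    _spec("metric_type", {_C.ONG, _C.FNG}, _K.TERM,
          "Whether the edge metric is a distance (smaller values denote "
          "more relatedness) or a similarity (larger values denote more "
          "relatedness)."),
    _spec("record_id", ALL_CLASSES, _K.ID_REF,
          "Links a matrix, annotation, or graph to a provenance record; "
          "serves as the unique id of a REC entry.", ref=_C.REC),
    _spec("record_package_name", {_C.REC}, _K.FREE_TEXT,
          "Name of the package, tool, or software that ran the algorithm."),
    _spec("record_package_version", {_C.REC}, _K.FREE_TEXT,
          "Version of the package, tool, or software."),
    _spec("record_function_name", {_C.REC}, _K.FREE_TEXT,
          "Name of the function or mathematical operation used."),
    _spec("record_function_parameters", {_C.REC}, _K.KEY_VALUE_MAP,
          "Key/value pairs describing the primary parameters and their "
          "values used in the function call."),
    _spec("record_workflow_link", {_C.REC}, _K.FREE_TEXT,
          "Public link to the workflow that ran the tool."),
    _spec("record_runtime_start", {_C.REC}, _K.TIMESTAMP,
          "Start time of the algorithm or operation (ISO-8601)."),
    _spec("record_runtime_end", {_C.REC}, _K.TIMESTAMP,
          "Finishing time of the algorithm or operation (ISO-8601)."),
    _spec("record_runtime_duration", {_C.REC}, _K.DURATION,
          "Total duration of the algorithm or operation."),
    _spec("filepath", _NON_REC, _K.PATH,
          "Path to the file or data object containing the matrix."),
    _spec("accessor", _NON_REC, _K.COMMAND_STRING,
          "Command to retrieve the matrix from a data object."),
    _spec("oid", {_C.FOM}, _K.ID_REF,
          "Link to the OID entry holding this matrix's observation IDs.",
          ref=_C.OID),
    _spec("fid", {_C.FOM}, _K.ID_REF,
          "Link to the FID entry holding this matrix's feature IDs.",
          ref=_C.FID),
    _spec("obs", {_C.FOM}, _K.ID_REF_LIST,
          "Links to OBS annotation entries aligned to this matrix.",
          ref=_C.OBS),
    _spec("fea", {_C.FOM}, _K.ID_REF_LIST,
          "Links to FEA annotation entries aligned to this matrix.",
          ref=_C.FEA),
)

_REGISTRY_BY_KEY: dict[str, FieldSpec] = {s.key: s for s in _REGISTRY}
assert len(_REGISTRY_BY_KEY) == len(_REGISTRY), "duplicate field key"


def field_registry() -> list[FieldSpec]:
    """Return the full MAMS field registry in canonical emission order."""
    return list(_REGISTRY)


def field_spec(key: str) -> FieldSpec | None:
    """Look up a single field by canonical key, or None if unknown."""
    return _REGISTRY_BY_KEY.get(key)


def fields_for_class(cls: MatrixClass | str) -> list[FieldSpec]:
    """Registry subset applying to one matrix class, in canonical order."""
    cls = MatrixClass.coerce(cls)
    return [s for s in _REGISTRY if cls in s.applies_to]


# ---------------------------------------------------------------------------
# Entries
# ---------------------------------------------------------------------------

_TRUTHY = {"true", "yes", "1"}
_FALSY = {"false", "no", "0"}


def _canonical_key(key: str) -> str:
    return str(key).strip().lower()


@dataclass
class MatrixEntry:
    """A bag of MAMS fields describing one matrix, annotation, or graph.

    ``fields`` holds keys present in the field registry (for any class —
    misplacement is a validation concern, not a construction error);
    ``extras`` preserves unrecognized keys verbatim, never dropped.
    """

    matrix_class: MatrixClass
    fields: dict[str, Any] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)

    ALLOWED_CLASSES: frozenset = ALL_CLASSES

    def __post_init__(self):
        self.matrix_class = MatrixClass.coerce(self.matrix_class)
        if self.matrix_class not in self.ALLOWED_CLASSES:
            allowed = ", ".join(sorted(c.value for c in self.ALLOWED_CLASSES))
            raise EntryConstructionError(
                f"{type(self).__name__} cannot hold class "
                f"{self.matrix_class.value}; allowed: {allowed}"
            )

    @property
    def id(self) -> str:
        return self.fields.get("id", "")

    @property
    def dataset_id(self) -> str:
        return self.fields.get("dataset_id", "")

    def get(self, key: str) -> Any:
        """Uniform accessor over canonical fields and extras.

        Absent fields return :data:`ABSENT`, never a default term.
        """
        key = _canonical_key(key)
        if key in self.fields:
            return self.fields[key]
        if key in self.extras:
            return self.extras[key]
        return ABSENT

    def items(self) -> Iterator[tuple[str, Any]]:
        """All (key, value) pairs: registry fields first, then extras."""
        yield from self.fields.items()
        yield from self.extras.items()


class FomEntry(MatrixEntry):
    """A feature-observation matrix: biological data at any processing
    stage, including reduced-dimensional representations."""

    ALLOWED_CLASSES = frozenset({MatrixClass.FOM})


class AnnotationEntry(MatrixEntry):
    """A feature (FEA) or observation (OBS) annotation data frame, e.g. QC
    metrics or cluster labels; free-form keys are preserved verbatim."""

    ALLOWED_CLASSES = frozenset({MatrixClass.FEA, MatrixClass.OBS})


class IdEntry(MatrixEntry):
    """An observation (OID) or feature (FID) identifier vector, possibly a
    compound ID joined by a delimiter."""

    ALLOWED_CLASSES = frozenset({MatrixClass.OID, MatrixClass.FID})


class GraphEntry(MatrixEntry):
    """An observation (ONG) or feature (FNG) neighborhood graph, annotated
    with the edge metric and whether it is distance- or similarity-based."""

    ALLOWED_CLASSES = frozenset({MatrixClass.ONG, MatrixClass.FNG})


class RecordEntry(MatrixEntry):
    """A provenance record (REC): the package, function, parameters and
    runtimes of the operation that produced one or more matrices."""

    ALLOWED_CLASSES = frozenset({MatrixClass.REC})

    @property
    def id(self) -> str:
        # record_id serves as the REC entry's id.
        return self.fields.get("record_id", "")


_ENTRY_TYPES: dict[MatrixClass, type[MatrixEntry]] = {
    MatrixClass.FOM: FomEntry,
    MatrixClass.FEA: AnnotationEntry,
    MatrixClass.OBS: AnnotationEntry,
    MatrixClass.OID: IdEntry,
    MatrixClass.FID: IdEntry,
    MatrixClass.ONG: GraphEntry,
    MatrixClass.FNG: GraphEntry,
    MatrixClass.REC: RecordEntry,
}


def make_entry(matrix_class: MatrixClass | str,
               fields: Mapping[str, Any]) -> MatrixEntry:
    """Build the class-appropriate entry from a key-value mapping.

    Known (registry) keys are canonicalized; unknown keys are retained in
    the entry's preserved-extras area. No vocabulary checking occurs here.

    Raises
    ------
    UnknownClassError
        If ``matrix_class`` is not one of the eight MAMS classes.
    EntryConstructionError
        If the identifying keys (``id``/``dataset_id``, or ``record_id``
        for REC) are missing or empty, or an explicit ``class`` key
        contradicts ``matrix_class``.
    """
    cls = MatrixClass.coerce(matrix_class)
    id_key = "record_id" if cls is MatrixClass.REC else "id"

    known: dict[str, Any] = {}
    extras: dict[str, Any] = {}
    for raw_key, value in fields.items():
        key = _canonical_key(raw_key)
        if key in _REGISTRY_BY_KEY:
            known[key] = value
        else:
            extras[key] = value

    declared = known.pop("class", None)
    if declared is not None and MatrixClass.coerce(declared) is not cls:
        raise EntryConstructionError(
            f"entry declares class {declared!r} but was constructed as "
            f"{cls.value}"
        )

    for required_key in (id_key, "dataset_id"):
        value = known.get(required_key)
        if value is None or str(value) == "":
            raise EntryConstructionError(
                f"{cls.value} entry is missing required key "
                f"{required_key!r}"
            )
        known[required_key] = str(value)

    if cls is MatrixClass.REC:
        known.pop("id", None)  # record_id is the id

    if "is_compound" in known:
        known["is_compound"] = _coerce_flag(known["is_compound"])

    return _ENTRY_TYPES[cls](matrix_class=cls, fields=known, extras=extras)


def _coerce_flag(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in _TRUTHY:
        return True
    if token in _FALSY:
        return False
    raise EntryConstructionError(
        f"is_compound must be boolean-like, got {value!r}"
    )


def entry_get(entry: MatrixEntry, key: str) -> Any:
    """Functional alias for :meth:`MatrixEntry.get`."""
    return entry.get(key)


# ---------------------------------------------------------------------------
# Document
# ---------------------------------------------------------------------------

@dataclass
class MamsDocument:
    """Top-level MAMS container: datasets, each holding per-class entry
    collections keyed by unique id.

    ``extras`` preserves unrecognized top-level content verbatim.
    """

    datasets: dict[str, dict[MatrixClass, dict[str, MatrixEntry]]] = field(
        default_factory=dict
    )
    spec_version: str = SPEC_VERSION
    extras: dict[str, Any] = field(default_factory=dict)

    def add_entry(self, entry: MatrixEntry) -> None:
        """File an entry under its dataset and class.

        Raises :class:`DuplicateIdError` if an entry with the same id
        already exists in that (dataset, class) scope.
        """
        per_class = self.datasets.setdefault(entry.dataset_id, {})
        collection = per_class.setdefault(entry.matrix_class, {})
        if entry.id in collection:
            raise DuplicateIdError(
                f"duplicate id {entry.id!r} in dataset "
                f"{entry.dataset_id!r} class {entry.matrix_class.value}"
            )
        collection[entry.id] = entry

    def get_entry(self, dataset_id: str, matrix_class: MatrixClass | str,
                  entry_id: str) -> MatrixEntry | None:
        cls = MatrixClass.coerce(matrix_class)
        return self.datasets.get(dataset_id, {}).get(cls, {}).get(entry_id)

    def entries(self, dataset_id: str | None = None,
                matrix_class: MatrixClass | str | None = None
                ) -> Iterator[MatrixEntry]:
        """Iterate entries, optionally restricted to a dataset and/or class,
        in deterministic (dataset, class, id) order."""
        wanted = (MatrixClass.coerce(matrix_class)
                  if matrix_class is not None else None)
        for ds_id in sorted(self.datasets):
            if dataset_id is not None and ds_id != dataset_id:
                continue
            per_class = self.datasets[ds_id]
            for cls in MatrixClass:
                if wanted is not None and cls is not wanted:
                    continue
                for entry_id in sorted(per_class.get(cls, {})):
                    yield per_class[cls][entry_id]

    def dataset_ids(self) -> list[str]:
        return sorted(self.datasets)

    def check_invariants(self) -> None:
        """Raise :class:`ContractError` on internal inconsistency (an entry
        filed under the wrong dataset key or mapping key != entry id)."""
        for ds_id, per_class in self.datasets.items():
            for cls, collection in per_class.items():
                for entry_id, entry in collection.items():
                    if entry.dataset_id != ds_id:
                        raise ContractError(
                            f"entry {entry_id!r} declares dataset "
                            f"{entry.dataset_id!r} but is filed under "
                            f"{ds_id!r}"
                        )
                    if entry.id != entry_id:
                        raise ContractError(
                            f"entry filed under key {entry_id!r} declares "
                            f"id {entry.id!r}"
                        )
                    if entry.matrix_class is not cls:
                        raise ContractError(
                            f"entry {entry_id!r} of class "
                            f"{entry.matrix_class.value} filed under "
                            f"{cls.value}"
                        )


def as_value_list(value: Any) -> list[Any]:
    """Normalize a scalar-or-list field value to a list (ABSENT -> [])."""
    if value is ABSENT or value is None:
        return []
    if isinstance(value, (list, tuple)):
        return list(value)
    return [value]


_ISO_DURATION = re.compile(
    r"^P(?!$)(\d+(?:\.\d+)?Y)?(\d+(?:\.\d+)?M)?(\d+(?:\.\d+)?W)?"
    r"(\d+(?:\.\d+)?D)?(T(?=\d)(\d+(?:\.\d+)?H)?(\d+(?:\.\d+)?M)?"
    r"(\d+(?:\.\d+)?S)?)?$"
)


def looks_like_duration(value: Any) -> bool:
    """True for ISO-8601 duration strings or plain seconds-as-number."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return value >= 0
    return bool(_ISO_DURATION.match(str(value).strip()))
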