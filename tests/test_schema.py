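"""Schema model: field registry, entry construction and uniform access."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mams import (
    ABSENT,
    EntryConstructionError,
    FomEntry,
    MamsDocument,
    MatrixClass,
    RecordEntry,
    UnknownClassError,
    ValueKind,
    entry_get,
    field_registry,
    field_spec,
    fields_for_class,
    make_entry,
)
from mams.schema import DuplicateIdError

ALL = set(MatrixClass)


# (field, classes it applies to) for every standard field, plus the
# implementation-format fields of the list layout.
STANDARD_FIELDS = {
    "id": ALL,
    "dataset_id": ALL,
    "class": ALL,
    "data_type": {MatrixClass.FOM},
    "representation": {MatrixClass.FOM},
    "obs_unit": {MatrixClass.FOM},
    "processing": {MatrixClass.FOM},
    "analyte": {MatrixClass.FOM},
    "modality": {MatrixClass.FOM},
    "obs_subset": {MatrixClass.FOM},
    "feature_subset": {MatrixClass.FOM},
    "parent_id": {MatrixClass.FOM, MatrixClass.ONG, MatrixClass.FNG},
    "parent_relationship": {MatrixClass.FOM},
    "edge_metric": {MatrixClass.ONG, MatrixClass.FNG},
    "metric_type": {MatrixClass.ONG, MatrixClass.FNG},
    "record_id": ALL,
    "record_package_name": {MatrixClass.REC},
    "record_package_version": {MatrixClass.REC},
    "record_function_name": {MatrixClass.REC},
    "record_function_parameters": {MatrixClass.REC},
    "record_workflow_link": {MatrixClass.REC},
    "record_runtime_start": {MatrixClass.REC},
    "record_runtime_end": {MatrixClass.REC},
    "record_runtime_duration": {MatrixClass.REC},
    "filepath": ALL - {MatrixClass.REC},
    "accessor": ALL - {MatrixClass.REC},
    "oid": {MatrixClass.FOM},
    "fid": {MatrixClass.FOM},
    "obs": {MatrixClass.FOM},
    "fea": {MatrixClass.FOM},
}

TWINNED = {"processing", "analyte", "modality", "obs_subset",
           "feature_subset"}


def test_registry_contains_every_standard_field_with_its_classes():
    registry = {s.key: s for s in field_registry()}
    for key, classes in STANDARD_FIELDS.items():
        assert key in registry, key
        assert registry[key].applies_to == frozenset(classes), key


def test_registry_keys_are_unique():
    keys = [s.key for s in field_registry()]
    assert len(keys) == len(set(keys))


def test_description_twins_are_recognized_for_subset_and_term_fields():
    registry = {s.key: s for s in field_registry()}
    for key in TWINNED:
        assert registry[key].has_description_twin
        twin = registry[f"{key}_description"]
        assert twin.value_kind is ValueKind.FREE_TEXT
        assert twin.applies_to == frozenset({MatrixClass.FOM})


@pytest.mark.parametrize("key, kind, ref", [
    ("accessor", ValueKind.COMMAND_STRING, None),
    ("filepath", ValueKind.PATH, None),
    ("parent_id", ValueKind.ID_REF_LIST, MatrixClass.FOM),
    ("record_id", ValueKind.ID_REF, MatrixClass.REC),
    ("oid", ValueKind.ID_REF, MatrixClass.OID),
    ("obs", ValueKind.ID_REF_LIST, MatrixClass.OBS),
    ("record_function_parameters", ValueKind.KEY_VALUE_MAP, None),
    ("record_runtime_start", ValueKind.TIMESTAMP, None),
    ("record_runtime_duration", ValueKind.DURATION, None),
])
def test_value_kinds_and_reference_targets(key, kind, ref):
    spec = field_spec(key)
    assert spec.value_kind is kind
    assert spec.ref_class == ref


def test_metric_type_applies_to_both_graph_classes():
    spec = field_spec("metric_type")
    assert spec.applies_to == frozenset({MatrixClass.ONG, MatrixClass.FNG})


def test_fields_for_class_is_a_registry_subset():
    rec_fields = {s.key for s in fields_for_class("rec")}
    assert "record_package_name" in rec_fields
    assert "processing" not in rec_fields


def test_class_names_canonicalize_case_insensitively():
    assert MatrixClass.coerce("fom") is MatrixClass.FOM
    assert MatrixClass.coerce("Rec") is MatrixClass.REC
    with pytest.raises(UnknownClassError):
        MatrixClass.coerce("matrix")


def test_make_entry_builds_class_specific_entries():
    entry = make_entry("FOM", {"id": "fom1", "dataset_id": "ds1",
                               "processing": "counts"})
    assert isinstance(entry, FomEntry)
    assert entry.get("processing") == "counts"
    rec = make_entry("rec", {"record_id": "r1", "dataset_id": "ds1"})
    assert isinstance(rec, RecordEntry)
    assert rec.id == "r1"


@pytest.mark.parametrize("cls, fields, message_part", [
    ("REC", {"dataset_id": "ds1"}, "record_id"),
    ("FOM", {"dataset_id": "ds1"}, "id"),
    ("FOM", {"id": "f1"}, "dataset_id"),
    ("FOM", {"id": "", "dataset_id": "ds1"}, "id"),
])
def test_missing_identifying_keys_raise_naming_the_key(cls, fields,
                                                       message_part):
    with pytest.raises(EntryConstructionError, match=message_part):
        make_entry(cls, fields)


def test_unknown_class_raises():
    with pytest.raises(UnknownClassError):
        make_entry("XYZ", {"id": "a", "dataset_id": "d"})


def test_unknown_keys_survive_in_preserved_extras():
    entry = make_entry("FOM", {"id": "f", "dataset_id": "d",
                               "my_custom": "x"})
    assert entry.extras == {"my_custom": "x"}
    assert entry.get("my_custom") == "x"


def test_absent_fields_return_marker_not_default():
    entry = make_entry("FOM", {"id": "f", "dataset_id": "d"})
    assert entry_get(entry, "modality") is ABSENT
    assert not ABSENT


def test_record_parameters_returned_verbatim():
    params = {"k": 15, "metric": "euclidean", "dims": [1, 2, 3]}
    rec = make_entry("REC", {"record_id": "r", "dataset_id": "d",
                             "record_function_parameters": params})
    assert rec.get("record_function_parameters") == params


def test_is_compound_coerced_to_boolean():
    entry = make_entry("OID", {"id": "o", "dataset_id": "d",
                               "is_compound": "true", "delimiter": "-"})
    assert entry.get("is_compound") is True


def test_document_rejects_duplicate_ids_in_same_class():
    doc = MamsDocument()
    doc.add_entry(make_entry("FOM", {"id": "f1", "dataset_id": "d"}))
    with pytest.raises(DuplicateIdError):
        doc.add_entry(make_entry("FOM", {"id": "f1", "dataset_id": "d"}))
    # same id in a different class is fine: uniqueness is per class
    doc.add_entry(make_entry("OBS", {"id": "f1", "dataset_id": "d"}))


_keys = st.text(alphabet="abcdefghij_", min_size=1, max_size=12).filter(
    lambda k: field_spec(k) is None and not k.startswith("_"))
_values = st.one_of(
    st.text(max_size=20), st.integers(-1000, 1000),
    st.lists(st.text(max_size=8), max_size=3),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(mapping=st.dictionaries(_keys, _values, max_size=6))
def test_construction_access_round_trip(mapping):
    """entry_get(make_entry(c, m), k) == m[k] for every key of m."""
    fields = {"id": "f1", "dataset_id": "ds1", **mapping}
    entry = make_entry("FOM", fields)
    for key, value in fields.items():
        assert entry.get(key) == value
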