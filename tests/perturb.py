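"""Perturbation harness: one targeted corruption per validation rule.

Each corruption takes a strictly conformant document and introduces the
single defect its rule detects; the expectation is that validating the
corrupted document yields new issues only for that rule, at the corrupted
location, and that the pristine document yields none of them.
"""

from dataclasses import dataclass
from typing import Callable

from mams import MamsDocument, MatrixClass
from mams.validate import ValidationPolicy

_DS = "scrna_pbmc"


def _fom(doc: MamsDocument, fom_id: str):
    return doc.datasets[_DS][MatrixClass.FOM][fom_id]


@dataclass(frozen=True)
class Corruption:
    rule_id: str
    location_part: str
    apply: Callable[[MamsDocument], None]
    policy: ValidationPolicy = ValidationPolicy()


def _blank_id(doc):
    collection = doc.datasets[_DS][MatrixClass.FOM]
    entry = collection.pop("fom_umap")
    entry.fields["id"] = " "
    collection[" "] = entry


def _dangling_parent(doc):
    _fom(doc, "fom_umap").fields["parent_id"] = ["fom_missing"]


def _misplaced_field(doc):
    _fom(doc, "fom_umap").fields["edge_metric"] = "euclidean"


def _two_cycle(doc):
    _fom(doc, "fom_pca").fields["parent_id"] = ["fom_umap"]


def _missing_relationship(doc):
    del _fom(doc, "fom_umap").fields["parent_relationship"]


def _single_parent_concat(doc):
    _fom(doc, "fom_umap").fields["parent_relationship"] = "concatenation"


def _multi_parent_reduction(doc):
    _fom(doc, "fom_umap").fields["parent_id"] = ["fom_pca", "fom_scaled"]


def _custom_term_no_twin(doc):
    _fom(doc, "fom_umap").fields["processing"] = "vst_residuals"


def _end_before_start(doc):
    rec = doc.datasets[_DS][MatrixClass.REC]["rec_umap"]
    rec.fields["record_runtime_end"] = "2024-03-01T08:00:00"


def _compound_without_delimiter(doc):
    del doc.datasets[_DS][MatrixClass.OID]["oid_barcodes"].fields[
        "delimiter"]


def _broader_subset_child(doc):
    _fom(doc, "fom_clean").fields["obs_subset"] = "full"


def _unknown_field(doc):
    _fom(doc, "fom_umap").extras["zz_custom_note"] = "x"


def _missing_filepath(doc):
    _fom(doc, "fom_umap").fields["filepath"] = "/nonexistent/umap.h5"


def _derived_without_record(doc):
    del _fom(doc, "fom_umap").fields["record_id"]


CORRUPTIONS = [
    Corruption("ID001", "/fom/ /id", _blank_id),
    Corruption("REF001", "/fom/fom_umap/parent_id", _dangling_parent),
    Corruption("CLASS001", "/fom/fom_umap/edge_metric", _misplaced_field),
    Corruption("GRAPH001", "/fom/fom_pca/parent_id", _two_cycle),
    Corruption("GRAPH002", "/fom/fom_umap/parent_relationship",
               _missing_relationship),
    Corruption("GRAPH003", "/fom/fom_umap/parent_id",
               _single_parent_concat),
    Corruption("GRAPH004", "/fom/fom_umap/parent_id",
               _multi_parent_reduction),
    Corruption("VOC001", "/fom/fom_umap/processing", _custom_term_no_twin),
    Corruption("REC001", "/rec/rec_umap/record_runtime_end",
               _end_before_start),
    Corruption("CID001", "/oid/oid_barcodes/delimiter",
               _compound_without_delimiter),
    Corruption("SUB001", "/fom/fom_clean/obs_subset",
               _broader_subset_child),
    Corruption("FLD001", "/fom/fom_umap/zz_custom_note", _unknown_field),
    Corruption("FS001", "/fom/fom_umap/filepath", _missing_filepath,
               ValidationPolicy(check_filepaths_exist=True)),
    Corruption("PROV001", "/fom/fom_umap/record_id",
               _derived_without_record,
               ValidationPolicy(require_record_links=True)),
]
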