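"""Complete, conformant example MAMS documents for curated workflows.

Five named use cases cover the common shapes of single-cell analysis:

``simple_rnaseq``
    One scRNA-seq sample: droplet counts filtered down to clean cells,
    normalized, scaled, reduced by PCA and embedded with tSNE/UMAP, with a
    KNN observation graph, compound barcode IDs, QC annotations and one
    provenance record per derived matrix.
``multimodal_cite``
    Parallel RNA / protein (ADT) / chromatin branches with a concatenated
    multimodal matrix and a joint factorization.
``multisample_integration``
    Per-sample roots concatenated, log-normalized, batch-corrected into an
    integrated reduction, plus a pseudobulk aggregation.
``biological_subset``
    A clean matrix subset to one broad cell type (custom ``obs_subset``
    term described via its description twin) and re-analyzed; includes a
    mitochondrial-variant allele-frequency matrix (analyte ``dna``).
``imaging_rois``
    Highly-multiplexed imaging: probe intensities and morphology features
    per cell, imaging-mass-spec lipid/metabolite matrices, and an
    ROI-level aggregation.

Entry counts and ids are this package's own choices; the workflow shapes
follow the standard's curated use cases. Every generated document passes
strict validation with zero errors and zero warnings, and provenance
records use neutral placeholder tool names. ``random_document`` emits
seeded, structurally valid random documents for property-based testing.
"""

from __future__ import annotations

import random
import string

from .schema import MamsDocument, MamsError, make_entry

__all__ = ["USE_CASES", "generate_use_case", "random_document"]

_WORKFLOW_LINK = "https://example.org/workflows/single-cell"


def _add(doc: MamsDocument, dataset_id: str, cls: str, entry_id: str,
         **fields) -> None:
    id_key = "record_id" if cls == "rec" else "id"
    doc.add_entry(make_entry(cls.upper(),
                             {id_key: entry_id, "dataset_id": dataset_id,
                              **fields}))


def _rec(doc, ds, rec_id, function, params, start="2024-03-01T09:00:00",
         end="2024-03-01T09:02:00", duration="PT2M"):
    _add(doc, ds, "rec", rec_id,
         record_package_name="example_tool",
         record_package_version="0.1.0",
         record_function_name=function,
         record_function_parameters=params,
         record_workflow_link=_WORKFLOW_LINK,
         record_runtime_start=start,
         record_runtime_end=end,
         record_runtime_duration=duration)


def _simple_rnaseq() -> MamsDocument:
    doc = MamsDocument()
    ds = "scrna_pbmc"

    steps = [
        ("rec_import", "import_counts", {"min_umi": 0}),
        ("rec_filter", "filter_empty_droplets", {"lower": 100}),
        ("rec_detect", "filter_detected", {"min_features": 200}),
        ("rec_qc", "filter_artifacts",
         {"max_mito_pct": 10, "doublet_rate": 0.05}),
        ("rec_clean", "finalize_observations", {}),
        ("rec_decontaminate", "remove_ambient_rna", {"method": "decontx"}),
        ("rec_normalize", "normalize_library_size", {"target_sum": 10000}),
        ("rec_lognormalize", "log_transform", {"base": 2, "pseudocount": 1}),
        ("rec_scale", "scale_features", {"center": True, "scale": True}),
        ("rec_hvg", "select_variable_features", {"n_features": 2000}),
        ("rec_pca", "run_pca", {"n_components": 50}),
        ("rec_knn", "build_knn_graph", {"k": 15, "metric": "euclidean"}),
        ("rec_tsne", "run_tsne", {"perplexity": 30}),
        ("rec_umap", "run_umap", {"n_neighbors": 15, "min_dist": 0.3}),
        ("rec_annotate", "compute_qc_metrics", {}),
    ]
    for rec_id, function, params in steps:
        _rec(doc, ds, rec_id, function, params)

    _add(doc, ds, "oid", "oid_barcodes", is_compound=True, delimiter="-",
         filepath="data/barcodes.tsv")
    _add(doc, ds, "fid", "fid_genes", is_compound=False,
         filepath="data/features.tsv")
    _add(doc, ds, "obs", "obs_qc", record_id="rec_annotate",
         filepath="data/obs_qc.csv",
         contents="QC metrics, cluster labels and trajectory scores")
    _add(doc, ds, "fea", "fea_gene_meta", filepath="data/gene_meta.csv",
         contents="gene symbols, biotypes and variability metrics")

    common = dict(analyte="rna", modality="rna", oid="oid_barcodes",
                  fid="fid_genes")
    _add(doc, ds, "fom", "fom_raw", processing="counts", obs_subset="full",
         feature_subset="full", obs_unit="droplet", data_type="int",
         representation="sparse", record_id="rec_import",
         fea=["fea_gene_meta"], filepath="data/raw_counts.mtx",
         accessor="counts(sce)", **common)
    chain = [
        ("fom_filtered", "fom_raw", "filtered", "rec_filter"),
        ("fom_detected", "fom_filtered", "detected", "rec_detect"),
        ("fom_nonartifact", "fom_detected", "nonartifact", "rec_qc"),
        ("fom_clean", "fom_nonartifact", "clean", "rec_clean"),
    ]
    for fom_id, parent, subset, rec_id in chain:
        _add(doc, ds, "fom", fom_id, processing="counts",
             obs_subset=subset, feature_subset="full", obs_unit="cell",
             data_type="int", representation="sparse",
             parent_id=[parent], parent_relationship="subset",
             record_id=rec_id, **common)
    transforms = [
        ("fom_decontaminated", "fom_clean", "decontaminated",
         "rec_decontaminate"),
        ("fom_normalized", "fom_decontaminated", "normalized",
         "rec_normalize"),
        ("fom_lognorm", "fom_normalized", "lognormalized",
         "rec_lognormalize"),
        ("fom_scaled", "fom_lognorm", "scaled", "rec_scale"),
    ]
    for fom_id, parent, processing, rec_id in transforms:
        _add(doc, ds, "fom", fom_id, processing=processing,
             obs_subset="clean", feature_subset="full", obs_unit="cell",
             data_type="double", representation="dense",
             parent_id=[parent], parent_relationship="transformation",
             record_id=rec_id, obs=["obs_qc"], **common)
    _add(doc, ds, "fom", "fom_hvg", processing="scaled",
         obs_subset="clean", feature_subset="variable", obs_unit="cell",
         data_type="double", representation="dense",
         parent_id=["fom_scaled"], parent_relationship="subset",
         record_id="rec_hvg", **common)
    _add(doc, ds, "fom", "fom_pca", processing="reduction",
         obs_subset="clean", obs_unit="cell", data_type="double",
         representation="dense", parent_id=["fom_hvg"],
         parent_relationship="reduction", record_id="rec_pca",
         analyte="rna", modality="rna", oid="oid_barcodes",
         accessor="reducedDim(sce, 'PCA')")
    for fom_id, rec_id in (("fom_tsne", "rec_tsne"),
                           ("fom_umap", "rec_umap")):
        _add(doc, ds, "fom", fom_id, processing="embedding",
             obs_subset="clean", obs_unit="cell", data_type="double",
             representation="dense", parent_id=["fom_pca"],
             parent_relationship="reduction", record_id=rec_id,
             analyte="rna", modality="rna", oid="oid_barcodes")
    _add(doc, ds, "ong", "ong_knn", parent_id=["fom_pca"],
         edge_metric="euclidean", metric_type="distance",
         record_id="rec_knn")
    return doc


def _multimodal_cite() -> MamsDocument:
    doc = MamsDocument()
    ds = "cite_pbmc"
    _rec(doc, ds, "rec_rna_norm", "log_normalize", {"target_sum": 10000})
    _rec(doc, ds, "rec_adt_norm", "clr_normalize", {"axis": "features"})
    _rec(doc, ds, "rec_concat", "concatenate_modalities",
         {"join": "inner"})
    _rec(doc, ds, "rec_factor", "joint_factorization", {"k": 30})
    _rec(doc, ds, "rec_umap", "run_umap", {"n_neighbors": 20})

    _add(doc, ds, "oid", "oid_cells", is_compound=False)
    _add(doc, ds, "fid", "fid_rna", is_compound=False)
    _add(doc, ds, "fid", "fid_adt", is_compound=False)

    _add(doc, ds, "fom", "fom_rna_raw", processing="counts",
         analyte="rna", modality="rna", obs_subset="full",
         obs_unit="cell", data_type="int", representation="sparse",
         oid="oid_cells", fid="fid_rna")
    _add(doc, ds, "fom", "fom_rna_lognorm", processing="lognormalized",
         analyte="rna", modality="rna", obs_subset="full",
         obs_unit="cell", parent_id=["fom_rna_raw"],
         parent_relationship="transformation", record_id="rec_rna_norm",
         oid="oid_cells", fid="fid_rna")
    _add(doc, ds, "fom", "fom_adt_raw", processing="counts",
         analyte="protein", modality="protein", obs_subset="full",
         obs_unit="cell", data_type="int", oid="oid_cells", fid="fid_adt")
    _add(doc, ds, "fom", "fom_adt_norm", processing="normalized",
         analyte="protein", modality="protein", obs_subset="full",
         obs_unit="cell", parent_id=["fom_adt_raw"],
         parent_relationship="transformation", record_id="rec_adt_norm",
         oid="oid_cells", fid="fid_adt")
    _add(doc, ds, "fom", "fom_adt_centered", processing="centered",
         analyte="protein", modality="protein", obs_subset="full",
         obs_unit="cell", parent_id=["fom_adt_norm"],
         parent_relationship="transformation", oid="oid_cells",
         fid="fid_adt")
    _add(doc, ds, "fom", "fom_atac_counts", processing="counts",
         analyte="chromatin", modality="chromatin", obs_subset="full",
         obs_unit="cell", data_type="int", representation="sparse",
         oid="oid_cells")
    _add(doc, ds, "fom", "fom_joint", analyte=["rna", "protein"],
         modality=["rna", "protein"], obs_subset="full", obs_unit="cell",
         parent_id=["fom_rna_lognorm", "fom_adt_centered"],
         parent_relationship="concatenation", record_id="rec_concat",
         oid="oid_cells")
    _add(doc, ds, "fom", "fom_joint_factors", processing="reduction",
         analyte=["rna", "protein"], modality=["rna", "protein"],
         obs_subset="full", obs_unit="cell",
         parent_id=["fom_rna_lognorm", "fom_adt_centered"],
         parent_relationship="factorization", record_id="rec_factor",
         oid="oid_cells")
    _add(doc, ds, "fom", "fom_joint_umap", processing="embedding",
         analyte=["rna", "protein"], modality=["rna", "protein"],
         obs_subset="full", obs_unit="cell",
         parent_id=["fom_joint_factors"], parent_relationship="reduction",
         record_id="rec_umap", oid="oid_cells")
    _add(doc, ds, "ong", "ong_joint", parent_id=["fom_joint_factors"],
         edge_metric="pearson", metric_type="similarity")
    return doc


def _multisample_integration() -> MamsDocument:
    doc = MamsDocument()
    ds = "lung_multisample"
    _rec(doc, ds, "rec_merge", "concatenate_samples",
         {"samples": ["s1", "s2"]})
    _rec(doc, ds, "rec_correct", "batch_correction",
         {"method": "example_integration", "batch_key": "sample"})
    _rec(doc, ds, "rec_pca", "run_pca", {"n_components": 30})
    _rec(doc, ds, "rec_pseudobulk", "aggregate_pseudobulk",
         {"group_by": ["sample", "cell_type"]})

    for sample in ("s1", "s2"):
        _add(doc, ds, "fom", f"fom_{sample}_counts", processing="counts",
             analyte="rna", obs_subset="full", obs_unit="droplet",
             data_type="int", representation="sparse")
        _add(doc, ds, "fom", f"fom_{sample}_clean", processing="counts",
             analyte="rna", obs_subset="clean", obs_unit="cell",
             data_type="int", parent_id=[f"fom_{sample}_counts"],
             parent_relationship="subset")
    _add(doc, ds, "fom", "fom_merged", processing="counts", analyte="rna",
         obs_subset="clean", obs_unit="cell", data_type="int",
         parent_id=["fom_s1_clean", "fom_s2_clean"],
         parent_relationship="concatenation", record_id="rec_merge")
    _add(doc, ds, "fom", "fom_merged_lognorm", processing="lognormalized",
         analyte="rna", obs_subset="clean", obs_unit="cell",
         parent_id=["fom_merged"], parent_relationship="transformation")
    _add(doc, ds, "fom", "fom_corrected", processing="corrected",
         analyte="rna", obs_subset="clean", obs_unit="cell",
         parent_id=["fom_merged_lognorm"],
         parent_relationship="transformation", record_id="rec_correct")
    _add(doc, ds, "fom", "fom_integrated_pca", processing="reduction",
         analyte="rna", obs_subset="clean", obs_unit="cell",
         parent_id=["fom_corrected"], parent_relationship="reduction",
         record_id="rec_pca")
    _add(doc, ds, "fom", "fom_pseudobulk", processing="counts",
         analyte="rna", obs_unit="cell_pool", data_type="int",
         parent_id=["fom_s1_clean", "fom_s2_clean"],
         parent_relationship="aggregation", record_id="rec_pseudobulk")
    return doc


def _biological_subset() -> MamsDocument:
    doc = MamsDocument()
    ds = "tcell_reanalysis"
    tcell_desc = ("Clean observations restricted to the broad T-cell "
                  "cluster from the initial analysis")
    _rec(doc, ds, "rec_subset", "subset_by_label",
         {"label": "t_cell", "obs_column": "broad_cell_type"})
    _rec(doc, ds, "rec_pca", "run_pca", {"n_components": 20})
    _rec(doc, ds, "rec_umap", "run_umap", {"n_neighbors": 15})

    _add(doc, ds, "obs", "obs_celltypes",
         contents="broad cell-type labels from the initial clustering")
    _add(doc, ds, "fom", "fom_all_clean", processing="counts",
         analyte="rna", obs_subset="clean", obs_unit="cell",
         data_type="int", representation="sparse", obs=["obs_celltypes"])
    _add(doc, ds, "fom", "fom_tcell", processing="counts", analyte="rna",
         obs_subset="tcell", obs_subset_description=tcell_desc,
         obs_unit="cell", data_type="int", parent_id=["fom_all_clean"],
         parent_relationship="subset", record_id="rec_subset")
    _add(doc, ds, "fom", "fom_tcell_logcounts", processing="logcounts",
         analyte="rna", obs_subset="tcell",
         obs_subset_description=tcell_desc, obs_unit="cell",
         parent_id=["fom_tcell"], parent_relationship="transformation")
    _add(doc, ds, "fom", "fom_tcell_pca", processing="reduction",
         analyte="rna", obs_subset="tcell",
         obs_subset_description=tcell_desc, obs_unit="cell",
         parent_id=["fom_tcell_logcounts"],
         parent_relationship="reduction", record_id="rec_pca")
    _add(doc, ds, "fom", "fom_tcell_umap", processing="embedding",
         analyte="rna", obs_subset="tcell",
         obs_subset_description=tcell_desc, obs_unit="cell",
         parent_id=["fom_tcell_pca"], parent_relationship="reduction",
         record_id="rec_umap")
    _add(doc, ds, "fom", "fom_mito_af", processing="raw", analyte="dna",
         modality="dna", obs_unit="cell", data_type="double",
         representation="dense",
         analyte_description="mitochondrial variant allele frequencies")
    return doc


def _imaging_rois() -> MamsDocument:
    doc = MamsDocument()
    ds = "codex_tissue"
    _rec(doc, ds, "rec_segment", "segment_cells",
         {"model": "example_segmenter"})
    _rec(doc, ds, "rec_log", "log_transform", {"base": 10})
    _rec(doc, ds, "rec_roi", "aggregate_rois",
         {"definition": "functional_tissue_unit"})

    _add(doc, ds, "oid", "oid_cells", is_compound=True, delimiter="_",
         filepath="data/cell_ids.csv")
    _add(doc, ds, "fom", "fom_intensities", processing="intensities",
         analyte="protein", obs_subset="full", obs_unit="cell",
         data_type="double", representation="dense",
         record_id="rec_segment", oid="oid_cells",
         filepath="data/cell_intensities.csv")
    _add(doc, ds, "fom", "fom_logintensities",
         processing="logintensities", analyte="protein",
         obs_subset="full", obs_unit="cell",
         parent_id=["fom_intensities"],
         parent_relationship="transformation", record_id="rec_log",
         oid="oid_cells")
    _add(doc, ds, "fom", "fom_morphology", processing="raw",
         analyte="morphology", obs_subset="full", obs_unit="cell",
         data_type="mixed", representation="dataframe",
         record_id="rec_segment", oid="oid_cells")
    _add(doc, ds, "fom", "fom_roi_summary", processing="intensities",
         analyte="protein", obs_unit="roi",
         parent_id=["fom_intensities", "fom_morphology"],
         parent_relationship="aggregation", record_id="rec_roi")
    _add(doc, ds, "fom", "fom_maldi_lipid", processing="intensities",
         analyte="lipid", obs_unit="spot", data_type="double",
         filepath="data/maldi_lipid.csv")
    _add(doc, ds, "fom", "fom_maldi_metabolite", processing="intensities",
         analyte="metabolite", obs_unit="spot", data_type="double")
    _add(doc, ds, "fom", "fom_maldi_lograw", processing="lograw",
         analyte="lipid", obs_unit="spot",
         parent_id=["fom_maldi_lipid"],
         parent_relationship="transformation")
    _add(doc, ds, "fng", "fng_markers", parent_id=["fom_logintensities"],
         edge_metric="pearson", metric_type="similarity")
    return doc


_GENERATORS = {
    "simple_rnaseq": _simple_rnaseq,
    "multimodal_cite": _multimodal_cite,
    "multisample_integration": _multisample_integration,
    "biological_subset": _biological_subset,
    "imaging_rois": _imaging_rois,
}

#: Names of the curated use-case documents, in a stable order.
USE_CASES = tuple(_GENERATORS)


def generate_use_case(name: str) -> MamsDocument:
    """Generate one of the curated use-case documents (seedless, fixed)."""
    generator = _GENERATORS.get(name)
    if generator is None:
        raise MamsError(
            f"unknown use case {name!r}; available: "
            + ", ".join(USE_CASES)
        )
    return generator()


# --- seeded random documents ----------------------------------------------

_PROCESSING = ["raw", "counts", "normalized", "lognormalized", "scaled",
               "reduction", "embedding"]
_ANALYTES = ["rna", "protein", "chromatin", "dna"]
_OBS_SUBSETS = ["full", "filtered", "detected", "nonartifact", "clean"]
_SINGLE_REL = ["transformation", "subset", "reduction"]
_MULTI_REL = ["concatenation", "aggregation", "factorization"]


def _rand_word(rng: random.Random, length: int = 6) -> str:
    return "".join(rng.choice(string.ascii_lowercase)
                   for _ in range(length))


def _rand_value(rng: random.Random):
    kind = rng.randrange(4)
    if kind == 0:
        return _rand_word(rng, 8)
    if kind == 1:
        return rng.randrange(1000)
    if kind == 2:
        return round(rng.random(), 6)
    return [_rand_word(rng, 4) for _ in range(rng.randrange(1, 4))]


def random_document(seed: int, max_foms: int = 8,
                    max_datasets: int = 2) -> MamsDocument:
    """A structurally valid random document for property-based testing.

    References are sampled from ids that exist, parents are drawn only
    from earlier FOMs (so the parent relation is a DAG by construction),
    and the same seed always yields an identical document.
    """
    rng = random.Random(seed)
    doc = MamsDocument()
    for d in range(1, rng.randint(1, max_datasets) + 1):
        ds = f"ds{d}"
        rec_ids = [f"rec{i}" for i in range(1, rng.randint(1, 4) + 1)]
        for rec_id in rec_ids:
            _rec(doc, ds, rec_id, _rand_word(rng),
                 {_rand_word(rng, 4): _rand_value(rng)})
        compound = rng.random() < 0.5
        oid_fields = {"is_compound": compound}
        if compound:
            oid_fields["delimiter"] = rng.choice(["-", "_", ":"])
        _add(doc, ds, "oid", "oid1", **oid_fields)
        obs_ids = [f"obs{i}" for i in range(1, rng.randint(1, 3) + 1)]
        for obs_id in obs_ids:
            _add(doc, ds, "obs", obs_id,
                 record_id=rng.choice(rec_ids),
                 **{f"custom_{_rand_word(rng, 4)}": _rand_value(rng)})
        fom_ids: list[str] = []
        for i in range(1, rng.randint(2, max_foms) + 1):
            fom_id = f"fom{i}"
            fields = {
                "processing": rng.choice(_PROCESSING),
                "analyte": rng.choice(_ANALYTES),
                "obs_subset": rng.choice(_OBS_SUBSETS),
                "oid": "oid1",
                "obs": [rng.choice(obs_ids)],
                "record_id": rng.choice(rec_ids),
                f"custom_{_rand_word(rng, 5)}": _rand_value(rng),
            }
            if fom_ids and rng.random() < 0.7:
                n_parents = 2 if (len(fom_ids) > 1
                                  and rng.random() < 0.3) else 1
                parents = rng.sample(fom_ids, n_parents)
                fields["parent_id"] = sorted(parents)
                fields["parent_relationship"] = rng.choice(
                    _SINGLE_REL if n_parents == 1 else _MULTI_REL)
            _add(doc, ds, "fom", fom_id, **fields)
            fom_ids.append(fom_id)
        if rng.random() < 0.5:
            _add(doc, ds, "ong", "ong1",
                 parent_id=[rng.choice(fom_ids)],
                 edge_metric=rng.choice(["euclidean", "cosine"]),
                 metric_type=rng.choice(["distance", "similarity"]))
    return doc
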