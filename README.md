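# mams

A reference implementation of the **Matrix and Analysis Metadata
Standards (MAMS)** for single-cell data: a typed schema model, controlled
vocabularies, a validation engine, JSON/YAML serialization, and
provenance/lineage queries for metadata describing the
feature–observation matrices (FOMs) produced by analysis workflows.

## The problem

Single-cell workflows produce many related matrices from one dataset: raw
droplet counts, filtered and quality-controlled counts, normalized and
scaled values, PCA reductions, 2-D embeddings, neighborhood graphs, and
annotation frames with QC metrics and cluster labels. Tools store these
under inconsistent names ("data", "normcounts", ...), and the provenance
of each matrix — which tool, which parameters, derived from what — is
routinely lost when data moves between platforms. MAMS addresses this
with a platform-independent metadata schema. This package manages
metadata *about* matrices; it never opens the matrix files themselves.

## The model

Eight matrix classes organize a dataset's artifacts:

| class | contents |
|-------|----------|
| FOM   | feature–observation matrices at any processing stage, including reductions and embeddings |
| FEA / OBS | feature / observation annotation frames (QC metrics, cluster labels) |
| OID / FID | observation / feature identifier vectors, possibly compound (delimiter-joined) |
| ONG / FNG | observation / feature neighborhood graphs (distance or similarity) |
| REC   | provenance records: package, version, function, parameters, runtimes |

Each class has a registered field set. FOM fields describe the analyte
measured (`analyte`), the observation/feature subsets present
(`obs_subset`, `feature_subset`), the processing stage (`processing`),
and derivation (`parent_id`, `parent_relationship`). Suggested terms form
an open, hierarchical vocabulary — `counts` and `intensities` are
children of `raw`, `embedding` is a child of `reduction` — and any custom
term is conformant when its `<field>_description` twin describes it.
`parent_id` declarations form a provenance DAG whose roots are the most
raw, unfiltered matrices; `record_id` links any matrix to its REC entry.

Documents are stored in a list-like JSON/YAML layout:

```yaml
my_dataset:
  fom:
    fom_raw:
      processing: counts
      obs_subset: full
      analyte: rna
```

## Worked example

Emit the curated scRNA-seq example, validate it strictly, and query it:

```
$ mams example simple_rnaseq -o simple.json
$ mams validate simple.json --strict ; echo "exit=$?"
SEVERITY  RULE    LOCATION                               MESSAGE
info      FLD001  scrna_pbmc/fea/fea_gene_meta/contents  unknown field 'contents' preserved as extra
info      FLD001  scrna_pbmc/obs/obs_qc/contents         unknown field 'contents' preserved as extra
exit=0
```

Zero errors and zero warnings: the document is strictly conformant (the
two info lines note free-form annotation keys, which are legal extras).
The lineage of the UMAP embedding walks back to the raw-counts root:

```
$ mams lineage simple.json --dataset scrna_pbmc --ancestors-of fom_umap
fom_raw -> fom_filtered -> fom_detected -> fom_nonartifact -> fom_clean
-> fom_decontaminated -> fom_normalized -> fom_lognorm -> fom_scaled
-> fom_hvg -> fom_pca -> fom_umap
```

A hierarchical query for `processing=raw` retrieves the five matrices
whose `counts` term is a child of `raw` in the vocabulary:

```
$ mams query simple.json --where processing=raw --hierarchical
fom_clean
fom_detected
fom_filtered
fom_nonartifact
fom_raw
```

The same operations are available as library calls
(`mams.generate_use_case`, `mams.validate`, `mams.build_lineage`,
`mams.ancestry`, `mams.select_foms`, `mams.diff_documents`), and
`mams convert FILE --to yaml` / `mams diff A B` move documents between
formats losslessly.

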