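{
  "spec_version": "1.0",
  "tcell_reanalysis": {
    "fom": {
      "fom_all_clean": {
        "data_type": "int",
        "representation": "sparse",
        "obs_unit": "cell",
        "processing": "counts",
        "analyte": "rna",
        "obs_subset": "clean",
        "obs": [
          "obs_celltypes"
        ]
      },
      "fom_mito_af": {
        "data_type": "double",
        "representation": "dense",
        "obs_unit": "cell",
        "processing": "raw",
        "analyte": "dna",
        "modality": "dna",
        "analyte_description": "mitochondrial variant allele frequencies"
      },
      "fom_tcell": {
        "data_type": "int",
        "obs_unit": "cell",
        "processing": "counts",
        "analyte": "rna",
        "obs_subset": "tcell",
        "obs_subset_description": "Clean observations restricted to the broad T-cell cluster from the initial analysis",
        "parent_id": [
          "fom_all_clean"
        ],
        "parent_relationship": "subset",
        "record_id": "rec_subset"
      },
      "fom_tcell_logcounts": {
        "obs_unit": "cell",
        "processing": "logcounts",
        "analyte": "rna",
        "obs_subset": "tcell",
        "obs_subset_description": "Clean observations restricted to the broad T-cell cluster from the initial analysis",
        "parent_id": [
          "fom_tcell"
        ],
        "parent_relationship": "transformation"
      },
      "fom_tcell_pca": {
        "obs_unit": "cell",
        "processing": "reduction",
        "analyte": "rna",
        "obs_subset": "tcell",
        "obs_subset_description": "Clean observations restricted to the broad T-cell cluster from the initial analysis",
        "parent_id": [
          "fom_tcell_logcounts"
        ],
        "parent_relationship": "reduction",
        "record_id": "rec_pca"
      },
      "fom_tcell_umap": {
        "obs_unit": "cell",
        "processing": "embedding",
        "analyte": "rna",
        "obs_subset": "tcell",
        "obs_subset_description": "Clean observations restricted to the broad T-cell cluster from the initial analysis",
        "parent_id": [
          "fom_tcell_pca"
        ],
        "parent_relationship": "reduction",
        "record_id": "rec_umap"
      }
    },
    "obs": {
      "obs_celltypes": {
        "contents": "broad cell-type labels from the initial clustering"
      }
    },
    "rec": {
      "rec_pca": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "run_pca",
        "record_function_parameters": {
          "n_components": 20
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_subset": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "subset_by_label",
        "record_function_parameters": {
          "label": "t_cell",
          "obs_column": "broad_cell_type"
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_umap": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "run_umap",
        "record_function_parameters": {
          "n_neighbors": 15
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      }
    }
  }
}
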