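{
  "spec_version": "1.0",
  "lung_multisample": {
    "fom": {
      "fom_corrected": {
        "obs_unit": "cell",
        "processing": "corrected",
        "analyte": "rna",
        "obs_subset": "clean",
        "parent_id": [
          "fom_merged_lognorm"
        ],
        "parent_relationship": "transformation",
        "record_id": "rec_correct"
      },
      "fom_integrated_pca": {
        "obs_unit": "cell",
        "processing": "reduction",
        "analyte": "rna",
        "obs_subset": "clean",
        "parent_id": [
          "fom_corrected"
        ],
        "parent_relationship": "reduction",
        "record_id": "rec_pca"
      },
      "fom_merged": {
        "data_type": "int",
        "obs_unit": "cell",
        "processing": "counts",
        "analyte": "rna",
        "obs_subset": "clean",
        "parent_id": [
          "fom_s1_clean",
          "fom_s2_clean"
        ],
        "parent_relationship": "concatenation",
        "record_id": "rec_merge"
      },
      "fom_merged_lognorm": {
        "obs_unit": "cell",
        "processing": "lognormalized",
        "analyte": "rna",
        "obs_subset": "clean",
        "parent_id": [
          "fom_merged"
        ],
        "parent_relationship": "transformation"
      },
      "fom_pseudobulk": {
        "data_type": "int",
        "obs_unit": "cell_pool",
        "processing": "counts",
        "analyte": "rna",
        "parent_id": [
          "fom_s1_clean",
          "fom_s2_clean"
        ],
        "parent_relationship": "aggregation",
        "record_id": "rec_pseudobulk"
      },
      "fom_s1_clean": {
        "data_type": "int",
        "obs_unit": "cell",
        "processing": "counts",
        "analyte": "rna",
        "obs_subset": "clean",
        "parent_id": [
          "fom_s1_counts"
        ],
        "parent_relationship": "subset"
      },
      "fom_s1_counts": {
        "data_type": "int",
        "representation": "sparse",
        "obs_unit": "droplet",
        "processing": "counts",
        "analyte": "rna",
        "obs_subset": "full"
      },
      "fom_s2_clean": {
        "data_type": "int",
        "obs_unit": "cell",
        "processing": "counts",
        "analyte": "rna",
        "obs_subset": "clean",
        "parent_id": [
          "fom_s2_counts"
        ],
        "parent_relationship": "subset"
      },
      "fom_s2_counts": {
        "data_type": "int",
        "representation": "sparse",
        "obs_unit": "droplet",
        "processing": "counts",
        "analyte": "rna",
        "obs_subset": "full"
      }
    },
    "rec": {
      "rec_correct": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "batch_correction",
        "record_function_parameters": {
          "method": "example_integration",
          "batch_key": "sample"
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_merge": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "concatenate_samples",
        "record_function_parameters": {
          "samples": [
            "s1",
            "s2"
          ]
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_pca": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "run_pca",
        "record_function_parameters": {
          "n_components": 30
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_pseudobulk": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "aggregate_pseudobulk",
        "record_function_parameters": {
          "group_by": [
            "sample",
            "cell_type"
          ]
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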