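{
  "spec_version": "1.0",
  "cite_pbmc": {
    "fid": {
      "fid_adt": {
        "is_compound": false
      },
      "fid_rna": {
        "is_compound": false
      }
    },
    "fom": {
      "fom_adt_centered": {
        "obs_unit": "cell",
        "processing": "centered",
        "analyte": "protein",
        "modality": "protein",
        "obs_subset": "full",
        "parent_id": [
          "fom_adt_norm"
        ],
        "parent_relationship": "transformation",
        "oid": "oid_cells",
        "fid": "fid_adt"
      },
      "fom_adt_norm": {
        "obs_unit": "cell",
        "processing": "normalized",
        "analyte": "protein",
        "modality": "protein",
        "obs_subset": "full",
        "parent_id": [
          "fom_adt_raw"
        ],
        "parent_relationship": "transformation",
        "record_id": "rec_adt_norm",
        "oid": "oid_cells",
        "fid": "fid_adt"
      },
      "fom_adt_raw": {
        "data_type": "int",
        "obs_unit": "cell",
        "processing": "counts",
        "analyte": "protein",
        "modality": "protein",
        "obs_subset": "full",
        "oid": "oid_cells",
        "fid": "fid_adt"
      },
      "fom_atac_counts": {
        "data_type": "int",
        "representation": "sparse",
        "obs_unit": "cell",
        "processing": "counts",
        "analyte": "chromatin",
        "modality": "chromatin",
        "obs_subset": "full",
        "oid": "oid_cells"
      },
      "fom_joint": {
        "obs_unit": "cell",
        "analyte": [
          "rna",
          "protein"
        ],
        "modality": [
          "rna",
          "protein"
        ],
        "obs_subset": "full",
        "parent_id": [
          "fom_rna_lognorm",
          "fom_adt_centered"
        ],
        "parent_relationship": "concatenation",
        "record_id": "rec_concat",
        "oid": "oid_cells"
      },
      "fom_joint_factors": {
        "obs_unit": "cell",
        "processing": "reduction",
        "analyte": [
          "rna",
          "protein"
        ],
        "modality": [
          "rna",
          "protein"
        ],
        "obs_subset": "full",
        "parent_id": [
          "fom_rna_lognorm",
          "fom_adt_centered"
        ],
        "parent_relationship": "factorization",
        "record_id": "rec_factor",
        "oid": "oid_cells"
      },
      "fom_joint_umap": {
        "obs_unit": "cell",
        "processing": "embedding",
        "analyte": [
          "rna",
          "protein"
        ],
        "modality": [
          "rna",
          "protein"
        ],
        "obs_subset": "full",
        "parent_id": [
          "fom_joint_factors"
        ],
        "parent_relationship": "reduction",
        "record_id": "rec_umap",
        "oid": "oid_cells"
      },
      "fom_rna_lognorm": {
        "obs_unit": "cell",
        "processing": "lognormalized",
        "analyte": "rna",
        "modality": "rna",
        "obs_subset": "full",
        "parent_id": [
          "fom_rna_raw"
        ],
        "parent_relationship": "transformation",
        "record_id": "rec_rna_norm",
        "oid": "oid_cells",
        "fid": "fid_rna"
      },
      "fom_rna_raw": {
        "data_type": "int",
        "representation": "sparse",
        "obs_unit": "cell",
        "processing": "counts",
        "analyte": "rna",
        "modality": "rna",
        "obs_subset": "full",
        "oid": "oid_cells",
        "fid": "fid_rna"
      }
    },
    "oid": {
      "oid_cells": {
        "is_compound": false
      }
    },
    "ong": {
      "ong_joint": {
        "parent_id": [
          "fom_joint_factors"
        ],
        "edge_metric": "pearson",
        "metric_type": "similarity"
      }
    },
    "rec": {
      "rec_adt_norm": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "clr_normalize",
        "record_function_parameters": {
          "axis": "features"
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_concat": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "concatenate_modalities",
        "record_function_parameters": {
          "join": "inner"
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_factor": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "joint_factorization",
        "record_function_parameters": {
          "k": 30
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_rna_norm": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "log_normalize",
        "record_function_parameters": {
          "target_sum": 10000
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
          "n_neighbors": 20
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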