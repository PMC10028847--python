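{
  "spec_version": "1.0",
  "codex_tissue": {
    "fng": {
      "fng_markers": {
        "parent_id": [
          "fom_logintensities"
        ],
        "edge_metric": "pearson",
        "metric_type": "similarity"
      }
    },
    "fom": {
      "fom_intensities": {
        "data_type": "double",
        "representation": "dense",
        "obs_unit": "cell",
        "processing": "intensities",
        "analyte": "protein",
        "obs_subset": "full",
        "record_id": "rec_segment",
        "filepath": "data/cell_intensities.csv",
        "oid": "oid_cells"
      },
      "fom_logintensities": {
        "obs_unit": "cell",
        "processing": "logintensities",
        "analyte": "protein",
        "obs_subset": "full",
        "parent_id": [
          "fom_intensities"
        ],
        "parent_relationship": "transformation",
        "record_id": "rec_log",
        "oid": "oid_cells"
      },
      "fom_maldi_lipid": {
        "data_type": "double",
        "obs_unit": "spot",
        "processing": "intensities",
        "analyte": "lipid",
        "filepath": "data/maldi_lipid.csv"
      },
      "fom_maldi_lograw": {
        "obs_unit": "spot",
        "processing": "lograw",
        "analyte": "lipid",
        "parent_id": [
          "fom_maldi_lipid"
        ],
        "parent_relationship": "transformation"
      },
      "fom_maldi_metabolite": {
        "data_type": "double",
        "obs_unit": "spot",
        "processing": "intensities",
        "analyte": "metabolite"
      },
      "fom_morphology": {
        "data_type": "mixed",
        "representation": "dataframe",
        "obs_unit": "cell",
        "processing": "raw",
        "analyte": "morphology",
        "obs_subset": "full",
        "record_id": "rec_segment",
        "oid": "oid_cells"
      },
      "fom_roi_summary": {
        "obs_unit": "roi",
        "processing": "intensities",
        "analyte": "protein",
        "parent_id": [
          "fom_intensities",
          "fom_morphology"
        ],
        "parent_relationship": "aggregation",
        "record_id": "rec_roi"
      }
    },
    "oid": {
      "oid_cells": {
        "is_compound": true,
        "delimiter": "_",
        "filepath": "data/cell_ids.csv"
      }
    },
    "rec": {
      "rec_log": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "log_transform",
        "record_function_parameters": {
          "base": 10
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_roi": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "aggregate_rois",
        "record_function_parameters": {
          "definition": "functional_tissue_unit"
        },
        "record_workflow_link": "https://example.org/workflows/single-cell",
        "record_runtime_start": "2024-03-01T09:00:00",
        "record_runtime_end": "2024-03-01T09:02:00",
        "record_runtime_duration": "PT2M"
      },
      "rec_segment": {
        "record_package_name": "example_tool",
        "record_package_version": "0.1.0",
        "record_function_name": "segment_cells",
        "record_function_parameters": {
          "model": "example_segmenter"
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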