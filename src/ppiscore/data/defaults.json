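{
  "method_score": {
    "category_scores": {
      "biophysical": 1.0,
      "biochemical": 1.0,
      "protein complementation assay": 0.66,
      "imaging technique": 0.33,
      "post-transcriptional interference": 0.33,
      "unknown": 0.05
    },
    "type_scores": {
      "direct interaction": 1.0,
      "physical association": 0.75,
      "association": 0.33,
      "unknown": 0.05
    },
    "publication_saturation": 7,
    "high_confidence_cutoff": 0.485
  },
  "annotation_score": {
    "mode": "naive_bayes_product",
    "baseline_lr": 0.163,
    "present_lr": {
      "interacting_domains": 14.0,
      "shared_go_term": 3.0,
      "homologous_interaction": 4.0
    },
    "absent_lr": null,
    "explicit_table": null,
    "lr_score_table": null,
    "go_aspects": null,
    "high_confidence_cutoff": 0.5
  },
  "combined_score": {
    "high_confidence_cutoff": 0.281,
    "either_score_rule": false
  },
  "evaluation": {
    "small_scale_cutoff": 100
  },
  "vocabulary": {
    "detection_method_categories": {
      "x-ray crystallography": "biophysical",
      "nuclear magnetic resonance": "biophysical",
      "surface plasmon resonance": "biophysical",
      "isothermal titration calorimetry": "biophysical",
      "circular dichroism": "biophysical",
      "light scattering": "biophysical",
      "fluorescence polarization spectroscopy": "biophysical",
      "biophysical": "biophysical",
      "two hybrid": "protein complementation assay",
      "two hybrid array": "protein complementation assay",
      "two hybrid pooling approach": "protein complementation assay",
      "beta galactosidase complementation": "protein complementation assay",
      "bimolecular fluorescence complementation": "protein complementation assay",
      "protein complementation assay": "protein complementation assay",
      "affinity chromatography technology": "biochemical",
      "anti bait coimmunoprecipitation": "biochemical",
      "anti tag coimmunoprecipitation": "biochemical",
      "coimmunoprecipitation": "biochemical",
      "pull down": "biochemical",
      "tandem affinity purification": "biochemical",
      "cosedimentation": "biochemical",
      "cross-linking study": "biochemical",
      "enzymatic study": "biochemical",
      "far western blotting": "biochemical",
      "peptide array": "biochemical",
      "biochemical": "biochemical",
      "post transcriptional interference": "post-transcriptional interference",
      "post-transcriptional interference": "post-transcriptional interference",
      "fluorescence microscopy": "imaging technique",
      "confocal microscopy": "imaging technique",
      "electron microscopy": "imaging technique",
      "imaging technique": "imaging technique",
      "experimental interaction detection": "unknown",
      "genetic interference": "unknown",
      "unknown": "unknown"
    },
    "interaction_types": [
      "direct interaction",
      "physical association",
      "association",
      "colocalization",
      "genetic interaction",
      "predicted interaction",
      "unknown"
    ],
    "physical_types": [
      "association",
      "physical association",
      "direct interaction"
    ],
    "excluded_methods": ["genetic interference"]
  }
}
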