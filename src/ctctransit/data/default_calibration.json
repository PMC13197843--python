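{
  "description": "Default generator calibration: observed arm-level dissociation frequencies, cohort size mix, routing, per-cell death probabilities and cluster-volume model. Frequencies are targets that the generator inverts to per-junction break probabilities. Entries marked placeholder are not printed in the source measurements and are modelling conventions.",
  "size_mix": {"2": 0.76, "3": 0.16, "4+": 0.08},
  "tail": {"q": 0.5, "min_size": 4, "max_size": 10},
  "per_size_dissociation": {"2": 0.51, "3": 0.67, "4+": 0.91},
  "per_geometry_dissociation": {
    "equal_pooled": 0.83,
    "unequal_pooled": 0.27,
    "ENA_6.3/6.3": 0.8,
    "ENA_7/7": 0.733,
    "ENA_9/9": 0.424,
    "UNA_5.5/7": 0.453,
    "UNA_5/9": 0.089
  },
  "per_geometry_placeholders": ["ENA_6.3/6.3"],
  "cytod_dissociation": {
    "UNA_5/9": {"all": 0.667, "doublets": 0.577}
  },
  "death_probs": {
    "bifurcation_single_untreated": 0.15,
    "bifurcation_single_cytod": 0.32,
    "bifurcation_cluster_untreated": 0.046,
    "bifurcation_cluster_cytod": 0.273,
    "linear_single_untreated": 0.15,
    "linear_single_cytod": 0.32,
    "linear_cluster_untreated": 0.046,
    "linear_cluster_cytod": 0.273,
    "nonconstricted_single_untreated": 0.08,
    "nonconstricted_single_cytod": 0.16,
    "nonconstricted_cluster_untreated": 0.02,
    "nonconstricted_cluster_cytod": 0.1
  },
  "death_probs_placeholders": [
    "linear_single_untreated", "linear_single_cytod",
    "linear_cluster_untreated", "linear_cluster_cytod",
    "nonconstricted_single_untreated", "nonconstricted_single_cytod",
    "nonconstricted_cluster_untreated", "nonconstricted_cluster_cytod"
  ],
  "volume_model": {
    "sigma_log": 0.4,
    "cell_mean_pl": {"7": 2.0, "9": 3.0},
    "dissociating_multiplier": {"7": 1.41, "9": 1.8}
  },
  "routing": {"mode": "occlusion_alternating", "kappa": 6.295840735330156},
  "different_branch_target": 0.88
}
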