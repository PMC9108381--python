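{
  "_comment": "Default generator calibration: marginal distributions of a single-center supratentorial ICH registry (n=137, 2020-2021). Categorical entries are raw counts and are normalized to probabilities at load time so they sum to 1 exactly.",
  "n": 137,
  "age_mean": 69.0,
  "age_sd": 15.1,
  "male_frac": 0.591,
  "premorbid_mrs_counts": [90, 14, 18, 15, 0, 0],
  "gcs_band_counts": {"14-15": 76, "5-13": 47, "3-4": 14},
  "location_counts": {"basal_ganglia": 73, "subcortical": 15, "cortical": 46, "brainstem": 3},
  "antithrombotic_counts": {"none": 82, "oral_anticoagulant": 21, "heparin": 3, "antiplatelet": 29, "combination": 2},
  "mrs_discharge_counts": [4, 11, 22, 12, 23, 20, 44],
  "ivh_prob": 0.38,
  "expansion_prob": 0.336,
  "control_image_prob": 0.679,
  "rescue_surgery_prob": 0.131,
  "evd_prob": 0.146,
  "brainstem_dysfunction_prob": 0.10,
  "nihss_median": 12,
  "nihss_range": [0, 36],
  "volume_mean": 35.0,
  "volume_sd": 42.0,
  "los_icu_mean_sd": [2.0, 7.8],
  "los_stroke_mean_sd": [2.0, 2.6],
  "los_total_mean_sd": [15.0, 20.8],
  "onset_median_h": 5.0,
  "onset_sigma": 1.0,
  "triage_to_image_median_min": 19.0,
  "triage_to_image_sigma": 1.1,
  "midterm_missing_prob": 0.1,
  "severity_coupling": 0.6,
  "seed": 0
}
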