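{
  "_comment": "Per-arm resource-use and outcome summaries. The two *_intervention arms are transcribed from the published trial reports (MISTIE III randomized trial; Kellner 2020 endoscopic cohort). The two *_control arms summarize the conservative-management candidate subgroups of a single-center supratentorial ICH registry (2020-2021). Day counts are the values used in the cost lines; *_alt fields carry the reported LoS medians where the two differ. SD fields are rough dispersions derived from reported ranges (range/4) and feed only the probabilistic sensitivity analysis.",
  "mistie3_intervention": {
    "name": "mistie3_intervention",
    "n": 255,
    "or_minutes": 60.0,
    "or_minutes_sd": 0.0,
    "surgery_prob": 1.0,
    "icu_days": 10.0,
    "icu_days_sd": 2.5,
    "stroke_unit_days": 0.0,
    "ward_days": 45.0,
    "ward_days_sd": 17.75,
    "rehab_discharge_frac": null,
    "mortality_30d_deaths": 24,
    "mrs_midterm_counts": [1, 15, 30, 64, 60, 31, 48],
    "navigation_used": true,
    "specific_material_cost_key": "mistie_catheter"
  },
  "kellner_intervention": {
    "name": "kellner_intervention",
    "n": 100,
    "or_minutes": 150.0,
    "or_minutes_sd": 66.0,
    "surgery_prob": 1.0,
    "icu_days": 8.5,
    "icu_days_sd": 2.25,
    "icu_days_alt": 9.0,
    "stroke_unit_days": 0.0,
    "ward_days": 8.5,
    "ward_days_sd": 3.75,
    "ward_days_alt": 8.0,
    "rehab_discharge_frac": 0.93,
    "mortality_30d_deaths": 9,
    "mrs_midterm_counts": [1, 9, 19, 17, 25, 13, 16],
    "navigation_used": true,
    "specific_material_cost_key": "endoscope_consumables"
  },
  "catheter_control": {
    "name": "catheter_control",
    "n": 17,
    "or_minutes": 130.0,
    "or_minutes_sd": 63.0,
    "surgery_prob_numerator": 5,
    "icu_days": 4.0,
    "icu_days_sd": 8.0,
    "stroke_unit_days": 2.0,
    "ward_days": 18.0,
    "ward_days_sd": 10.0,
    "rehab_discharge_numerator": 12,
    "mortality_30d_deaths": 4,
    "mrs_midterm_counts": [0, 0, 0, 2, 2, 3, 7],
    "navigation_used": false,
    "specific_material_cost_key": null
  },
  "endoscopic_control": {
    "name": "endoscopic_control",
    "n": 59,
    "or_minutes": 136.9,
    "or_minutes_sd": 36.0,
    "surgery_prob_numerator": 10,
    "icu_days": 4.0,
    "icu_days_sd": 4.5,
    "stroke_unit_days": 2.5,
    "ward_days": 16.0,
    "ward_days_sd": 8.5,
    "rehab_discharge_numerator": 33,
    "mortality_30d_deaths": 14,
    "mrs_midterm_counts": [2, 1, 5, 6, 10, 6, 19],
    "navigation_used": false,
    "specific_material_cost_key": null
  }
}
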