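{
  "_comment": "Public health tariff of a Spanish tertiary center, 2020/2021 price year, EUR. rehab covers a secondary rehabilitation/social facility over a 3-month horizon.",
  "or_rate_per_min": 5.0,
  "surgical_pack": 1150.0,
  "navigation": 862.0,
  "specific_material": {
    "mistie_catheter": 200.0,
    "endoscope_consumables": 7000.0
  },
  "icu_per_diem": 1175.9,
  "stroke_unit_per_diem": 707.4,
  "ward_per_diem": 419.0,
  "rehab_per_diem": 97.8,
  "rehab_horizon_days": 90
}
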