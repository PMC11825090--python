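{
  "config": {
    "adult_cutoff_months": 24.0,
    "calibration_bounds": null,
    "criterion": "aicc",
    "date_window": [
      "2023-01-01",
      "2023-12-31"
    ],
    "in_year_only": true,
    "loess_degree": 1,
    "max_age_at_end_months": 180.0,
    "n_animals": 10000,
    "out_dir": "vetweight_out",
    "records_path": null,
    "require_invoice": true,
    "seed": 4,
    "species": [
      "dog"
    ],
    "years": [
      2023
    ]
  },
  "library_versions": {
    "numpy": "2.4.6",
    "pandas": "2.3.3",
    "scipy": "1.17.1",
    "statsmodels": "0.14.6"
  },
  "n_excluded_records": 0,
  "n_input_records": 24661,
  "n_retained_records": 24661,
  "package": "vetweight",
  "version": "0.1.0"
}
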