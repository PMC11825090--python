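{
  "age_months": 31.75,
  "criterion": "aicc",
  "n_points": 8747,
  "span": 0.166718,
  "species": "dog"
}
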