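{
  "coefficients": {
    "intercept": 0.36432014911347477,
    "age": -0.05955294755533629,
    "age2": 0.0016353284443110941,
    "age3": -1.2369556072912617e-05,
    "interval": 0.22349688066237217,
    "interval2": -0.023890183783192586,
    "interval3": 0.0010741771662397595,
    "age_x_interval": -0.0021082845092779863
  },
  "included_terms": {
    "age": true,
    "age2": true,
    "age3": true,
    "interval": true,
    "interval2": true,
    "interval3": true,
    "age_x_interval": true
  },
  "var_animal": 0.0,
  "var_resid": 0.02732411722252066,
  "aic": null,
  "n_pairs": 9180,
  "n_animals": 2892,
  "max_valid_age_months": 14.0
}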