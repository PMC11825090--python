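{
  "converged": true,
  "iterations": [
    [
      52,
      12.768394423397263
    ],
    [
      62,
      13.021261733537111
    ],
    [
      67,
      13.277778612171794
    ],
    [
      70,
      13.415104620978902
    ],
    [
      71,
      13.453
    ],
    [
      72,
      13.507388208860295
    ]
  ],
  "loess_target_months": 31.75,
  "max_dev_age_months": 72,
  "solved_cessation_months": 13.507388208860295
}
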