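[
  {
    "ci95_kg": [
      16.332446900944063,
      16.93998579591765
    ],
    "kruskal_wallis": {
      "group": {
        "n_groups": 5,
        "p": 0.03102166592217746,
        "statistic": 10.632369535578619
      },
      "practice": {
        "n_groups": 20,
        "p": 0.07207278818337777,
        "statistic": 28.627606894777273
      }
    },
    "n_animals": 10000,
    "n_juveniles": 965,
    "n_practices": 20,
    "pct_juveniles": 9.65,
    "period_mean_adults_only_kg": 16.77185482125509,
    "period_mean_full_kg": 16.358749406376482,
    "point_mean_kg": 16.636216348430857,
    "species": "dog",
    "year": 2023
  }
]
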