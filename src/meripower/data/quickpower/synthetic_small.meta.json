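{
  "config": {
    "delta": [
      1.5,
      2.0
    ],
    "depth_factor": [
      1.0
    ],
    "dmr_prop": 0.1,
    "effect_ceiling": 2.0,
    "effect_floor": 1.0,
    "nominal_fdr": [
      0.05,
      0.1
    ],
    "nsim": 4,
    "quantile_cut": 0.5,
    "sample_size": [
      2,
      3,
      5
    ],
    "strata_breaks": [
      0.0,
      10.0,
      30.0,
      50.0,
      70.0,
      90.0,
      100.0
    ]
  },
  "failures": {
    "2x1.0": 0,
    "3x1.0": 0,
    "5x1.0": 0
  },
  "recipe": {
    "assessment": {
      "delta": [
        1.5,
        2.0
      ],
      "depth_factor": [
        1.0
      ],
      "nominal_fdr": [
        0.05,
        0.1
      ],
      "nsim": 4,
      "sample_size": [
        2,
        3,
        5
      ]
    },
    "estimation_seed": 7,
    "grid_seed": 11,
    "pilot_spec": {
      "n_bins_per_region": 2,
      "n_per_group": 3,
      "n_regions": 150,
      "seed": 20240601
    }
  },
  "scenario": "synthetic_small",
  "seed": 11
}
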