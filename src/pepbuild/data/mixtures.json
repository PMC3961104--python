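{
  "comment": "Default torsion-sampling mixtures: von Mises components over (phi, psi) backbone pairs and chi vectors, degrees. Conventional Ramachandran basin and rotamer positions; replaceable by user-supplied files of the same shape.",
  "basins": {
    "alpha": [-63.0, -43.0],
    "beta": [-120.0, 135.0],
    "alphaL": [60.0, 45.0]
  },
  "backbone": {
    "default": {
      "components": [
        {"weight": 0.40, "mean": [-63.0, -43.0], "kappa": [8.0, 8.0]},
        {"weight": 0.50, "mean": [-120.0, 135.0], "kappa": [4.0, 3.0]},
        {"weight": 0.10, "mean": [60.0, 45.0], "kappa": [8.0, 8.0]}
      ]
    },
    "G": {
      "components": [
        {"weight": 0.15, "mean": [-63.0, -43.0], "kappa": [6.0, 6.0]},
        {"weight": 0.15, "mean": [63.0, 43.0], "kappa": [6.0, 6.0]},
        {"weight": 0.35, "mean": [-120.0, 135.0], "kappa": [3.0, 2.5]},
        {"weight": 0.35, "mean": [120.0, -135.0], "kappa": [3.0, 2.5]}
      ]
    },
    "P": {
      "components": [
        {"weight": 0.45, "mean": [-65.0, -35.0], "kappa": [50.0, 8.0]},
        {"weight": 0.55, "mean": [-65.0, 145.0], "kappa": [50.0, 4.0]}
      ]
    }
  },
  "chi_components": [
    {"weight": 0.45, "value": -60.0},
    {"weight": 0.35, "value": 180.0},
    {"weight": 0.20, "value": 60.0}
  ],
  "chi_kappa": 12.0,
  "bb_dependent_scale": {
    "alpha": [1.5, 0.8, 0.7],
    "beta": [0.8, 1.5, 0.7],
    "alphaL": [0.8, 0.8, 1.4]
  }
}
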