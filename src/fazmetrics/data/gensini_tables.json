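{
  "description": "Default Gensini scoring tables: severity points per stenosis category and coronary-segment multipliers, following the original Gensini scheme with the Ramus intermedius assigned multiplier 1.",
  "severity_points": {
    "25": 1,
    "50": 2,
    "75": 4,
    "90": 8,
    "99": 16,
    "100": 32
  },
  "segment_multipliers": {
    "left_main": 5.0,
    "lad_proximal": 2.5,
    "lad_mid": 1.5,
    "lad_distal": 1.0,
    "lad_apical": 1.0,
    "first_diagonal": 1.0,
    "second_diagonal": 0.5,
    "lcx_proximal": 2.5,
    "lcx_distal": 1.0,
    "obtuse_marginal": 1.0,
    "lcx_posterolateral": 0.5,
    "lcx_posterior_descending": 1.0,
    "rca_proximal": 1.0,
    "rca_mid": 1.0,
    "rca_distal": 1.0,
    "rca_posterior_descending": 1.0,
    "rca_posterolateral": 0.5,
    "ramus_intermedius": 1.0
  }
}
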