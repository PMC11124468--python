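{
  "description": "Linear-elastic tissue properties attached to exported model components: Young's modulus E in MPa and Poisson's ratio nu (dimensionless).",
  "materials": [
    {"tissue": "cortical bone", "youngs_modulus_E": 12000, "poisson_ratio_nu": 0.30},
    {"tissue": "trabecular bone", "youngs_modulus_E": 100, "poisson_ratio_nu": 0.20},
    {"tissue": "cartilage", "youngs_modulus_E": 10, "poisson_ratio_nu": 0.40},
    {"tissue": "nucleus pulposus", "youngs_modulus_E": 1, "poisson_ratio_nu": 0.49},
    {"tissue": "annulus fibrosus", "youngs_modulus_E": 4.2, "poisson_ratio_nu": 0.45}
  ]
}
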