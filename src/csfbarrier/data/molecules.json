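{
  "_comment": "Reference serum proteins. r_h: experimentally measured hydrodynamic radius in nm (monomeric IgA). aleph_fitted: dimensionless exchange coefficient obtained by fitting the connected steady-state saturation curve to the mean hyperbolic quotient relation, with the albumin anchor fixed at 2 and k/L = 1.",
  "molecules": {
    "albumin": {"r_h": 3.51, "aleph_fitted": 2.0},
    "IgG":     {"r_h": 5.29, "aleph_fitted": 1.23},
    "IgA":     {"r_h": 6.50, "aleph_fitted": 0.86},
    "IgM":     {"r_h": 12.65, "aleph_fitted": 0.55}
  }
}
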