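{
  "_comment": "Hyperbolic discrimination-curve parameters for the quotient diagrams (Reibergrams). Curves are Q_IgX(Q_Alb) = (a/b)*sqrt(Q_Alb^2 + b^2) - c. Values are stored as printed in the reference population study and rescaled on load: b_sq entries are in units of 1e-6, c entries in units of 1e-3, grid Q_Alb values in units of 1e-3. All quotients in memory are absolute dimensionless fractions.",
  "scales": {"b_sq": 1e-6, "c": 1e-3, "q_alb": 1e-3},
  "q_alb_range": [2.0, 150.0],
  "families": {
    "IgG": {
      "upper": {"a_over_b": 0.93, "b_sq": 6, "c": 1.7},
      "mean":  {"a_over_b": 0.65, "b_sq": 8, "c": 1.4},
      "lower": {"a_over_b": 0.33, "b_sq": 2, "c": 0.3}
    },
    "IgA": {
      "upper": {"a_over_b": 0.77, "b_sq": 23, "c": 3.1},
      "mean":  {"a_over_b": 0.47, "b_sq": 27, "c": 2.1},
      "lower": {"a_over_b": 0.17, "b_sq": 74, "c": 1.3}
    },
    "IgM": {
      "upper": {"a_over_b": 0.67, "b_sq": 120, "c": 7.1},
      "mean":  {"a_over_b": 0.33, "b_sq": 306, "c": 5.7},
      "lower": {"a_over_b": 0.04, "b_sq": 442, "c": 0.82}
    }
  },
  "variation_grid": {
    "_comment": "Published population variation coefficients (upper-lower)/mean at grid Q_Alb values (x1e-3).",
    "q_alb": [2.2, 3.5, 5, 8.2, 10, 15, 20, 50, 100, 140],
    "IgG": [0.86, 0.89, 0.9, 0.92, 0.91, 0.91, 0.91, 0.92, 0.92, 0.92],
    "IgA": [1.36, 1.41, 1.43, 1.42, 1.4, 1.38, 1.34, 1.31, 1.29, 1.29],
    "IgM": [3, 3, 3.1, 2.9, 2.9, 2.7, 2.6, 2.2, 2, 2]
  }
}
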