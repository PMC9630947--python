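{
  "description": "Head-and-neck-like registry cohort: squamous cell carcinoma patients over 70, binary treatment = combined-modality therapy (chemo within 14 days of radiation) vs radiation alone. Marginals echo the published cohort (n=4042, 63% treated, site split 50.4/35.5 with the printed 1% rounding residual assigned to hypopharynx); older age lowers the odds of combined treatment (-0.2 log-odds per year, calibrated so the unmatched group is ~3 years older than the matched group as in the published balance table). Intercept calibrated numerically so the mean assignment probability is 0.63.",
  "n": 4042,
  "covariates": [
    {"name": "age", "kind": "continuous", "lo": 71, "hi": 90, "mean": 76, "sd": 5, "integer": true},
    {"name": "sex", "kind": "categorical", "levels": ["male", "female"], "probabilities": [0.675, 0.325]},
    {"name": "race", "kind": "categorical", "levels": ["white", "black", "other"], "probabilities": [0.854, 0.123, 0.023]},
    {"name": "charlson", "kind": "categorical", "levels": ["0", "1", "2"], "probabilities": [0.712, 0.203, 0.085]},
    {"name": "site", "kind": "categorical", "levels": ["larynx", "oropharynx", "hypopharynx"], "probabilities": [0.504, 0.355, 0.141]},
    {"name": "tumor_stage", "kind": "categorical", "levels": ["T1", "T2", "T3", "T4"], "probabilities": [0.067, 0.229, 0.444, 0.26]},
    {"name": "nodal_stage", "kind": "categorical", "levels": ["N0", "N1", "N2", "N3"], "probabilities": [0.393, 0.239, 0.337, 0.031]}
  ],
  "treatment_coefficients": [
    15.6545,
    -0.2,
    -0.1,
    -0.2, -0.1,
    -0.15, -0.3,
    0.3, -0.2,
    0.1, 0.15, 0.05,
    0.3, 0.8, 0.9
  ],
  "seed": 0
}
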