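{
  "description": "Glioblastoma-like registry cohort for one pairwise arm of a 3-arm treatment comparison (radiation alone vs combined-modality therapy; treated = combined). Patients 65+, adds surgery and year-of-diagnosis covariates; n = 1693 + 8435 with treated fraction 0.833 per the published arm sizes. Surgery and later diagnosis year raise the odds of combined treatment, age lowers them. Intercept calibrated numerically to the 0.833 treated fraction.",
  "n": 10128,
  "covariates": [
    {"name": "age", "kind": "continuous", "lo": 65, "hi": 95, "mean": 74, "sd": 6, "integer": true},
    {"name": "sex", "kind": "categorical", "levels": ["female", "male"], "probabilities": [0.55, 0.45]},
    {"name": "race", "kind": "categorical", "levels": ["white", "black", "other"], "probabilities": [0.93, 0.04, 0.03]},
    {"name": "charlson", "kind": "categorical", "levels": ["0", "1", "2"], "probabilities": [0.69, 0.195, 0.115]},
    {"name": "year_dx", "kind": "categorical", "levels": ["2005-2008", "2009-2011"], "probabilities": [0.52, 0.48]},
    {"name": "surgery", "kind": "categorical", "levels": ["no", "yes"], "probabilities": [0.24, 0.76]}
  ],
  "treatment_coefficients": [
    6.7596,
    -0.08,
    0.2,
    -0.15, -0.1,
    0.1, 0.2,
    0.3,
    0.9
  ],
  "seed": 0
}
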