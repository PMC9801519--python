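{
  "primary_null": {
    "stage": "primary",
    "n": 8457,
    "covariates": [
      {"name": "exercise", "mean": 2.88, "sd": 1.02, "lower": 0, "upper": 7, "integer": true},
      {"name": "diet", "mean": 9.13, "sd": 1.41},
      {"name": "bullying", "mean": 10.78, "sd": 1.44},
      {"name": "sleep", "mean": 8.86, "sd": 1.10},
      {"name": "network", "mean": 9.00, "sd": 1.82}
    ],
    "true_beta": {},
    "intercept": 4.79,
    "noise_sd": 0.565,
    "seed": 2021
  },
  "junior_paper": {
    "stage": "junior",
    "n": 8191,
    "covariates": [
      {"name": "exercise", "mean": 2.72, "sd": 1.01, "lower": 0, "upper": 7, "integer": true},
      {"name": "bullying", "mean": 10.66, "sd": 1.35},
      {"name": "m_stress", "mean": 30.11, "sd": 8.68},
      {"name": "network", "mean": 17.43, "sd": 1.10},
      {"name": "diet", "mean": 9.43, "sd": 1.43}
    ],
    "true_beta": {"exercise": 0.0177},
    "intercept": 4.60,
    "noise_sd": 0.61,
    "seed": 2021
  },
  "senior_paper": {
    "stage": "senior",
    "n": 5901,
    "covariates": [
      {"name": "exercise", "mean": 2.31, "sd": 1.039, "lower": 0, "upper": 7, "integer": true},
      {"name": "bullying", "mean": 10.46, "sd": 1.08},
      {"name": "m_stress", "mean": 31.34, "sd": 8.95},
      {"name": "network", "mean": 17.2, "sd": 1.39},
      {"name": "diet", "mean": 9.67, "sd": 1.37}
    ],
    "true_beta": {"exercise": 0.0196},
    "intercept": 4.42,
    "noise_sd": 0.61,
    "seed": 2021
  },
  "strong_single": {
    "stage": "junior",
    "n": 8191,
    "covariates": [
      {"name": "exercise", "mean": 2.72, "sd": 1.01, "lower": 0, "upper": 7, "integer": true},
      {"name": "bullying", "mean": 10.66, "sd": 1.35},
      {"name": "m_stress", "mean": 30.11, "sd": 8.68},
      {"name": "network", "mean": 17.43, "sd": 1.10},
      {"name": "diet", "mean": 9.43, "sd": 1.43}
    ],
    "true_beta": {"m_stress": 0.03},
    "intercept": 3.70,
    "noise_sd": 0.61,
    "seed": 2021
  },
  "pure_null": {
    "stage": "junior",
    "n": 2000,
    "covariates": [
      {"name": "exercise", "mean": 2.72, "sd": 1.01, "lower": 0, "upper": 7, "integer": true},
      {"name": "bullying", "mean": 10.66, "sd": 1.35},
      {"name": "m_stress", "mean": 30.11, "sd": 8.68},
      {"name": "network", "mean": 17.43, "sd": 1.10},
      {"name": "diet", "mean": 9.43, "sd": 1.43}
    ],
    "true_beta": {},
    "intercept": 4.60,
    "noise_sd": 0.61,
    "seed": 2021
  }
}
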