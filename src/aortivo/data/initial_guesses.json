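{
  "description": "Common initial parameter guesses for the inverse algorithm. M02: the AD1 ex vivo coefficients (the subject closest to the cohort's median stiffness). M03: the same set with a 5% variation applied to each coefficient, probing sensitivity to the initial guess.",
  "M02": {"c1_kPa": 2.6970, "D1_kPa": 15.1322, "D2": 0.9272, "K1_kPa": 2.1722, "K2": 0.9338, "theta_deg": 5.56},
  "M03": {"c1_kPa": 2.6373, "D1_kPa": 15.2031, "D2": 0.9696, "K1_kPa": 2.2732, "K2": 0.9018, "theta_deg": 5.82}
}
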