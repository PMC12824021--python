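{
  "description": "Ex vivo anisotropic Mooney-Rivlin coefficients fitted to biaxial tensile tests, with the coefficient of determination of each fit.",
  "params": {
    "AD1": {"c1_kPa": 2.6970, "D1_kPa": 15.1322, "D2": 0.9272, "K1_kPa": 2.1722, "K2": 0.9338, "theta_deg": 5.56, "r_squared": 0.9898},
    "AD2": {"c1_kPa": 0.4730, "D1_kPa": 12.0210, "D2": 0.9184, "K1_kPa": 0.2379, "K2": 1.3761, "theta_deg": 12.43, "r_squared": 0.9684},
    "AD3": {"c1_kPa": 0.6100, "D1_kPa": 6.2073, "D2": 2.2917, "K1_kPa": 1.5853, "K2": 10.2653, "theta_deg": 8.07, "r_squared": 0.9795},
    "AD4": {"c1_kPa": 0.5100, "D1_kPa": 6.2066, "D2": 2.1138, "K1_kPa": 0.8650, "K2": 15.1746, "theta_deg": 7.79, "r_squared": 0.9629},
    "AD5": {"c1_kPa": 0.9800, "D1_kPa": 22.9048, "D2": 0.8946, "K1_kPa": 0.0100, "K2": 0.0105, "theta_deg": 40.01, "r_squared": 0.9188},
    "N1": {"c1_kPa": 0.0101, "D1_kPa": 29.3547, "D2": 0.5745, "K1_kPa": 1.3323, "K2": 1.0643, "theta_deg": 5.80, "r_squared": 0.9903},
    "N2": {"c1_kPa": 1.0000, "D1_kPa": 14.4936, "D2": 1.4818, "K1_kPa": 0.1000, "K2": 0.5000, "theta_deg": 39.56, "r_squared": 0.9478},
    "N3": {"c1_kPa": 0.5400, "D1_kPa": 12.1538, "D2": 1.5536, "K1_kPa": 0.0100, "K2": 0.0100, "theta_deg": 14.95, "r_squared": 0.9211},
    "N4": {"c1_kPa": 1.6478, "D1_kPa": 17.6785, "D2": 1.0153, "K1_kPa": 0.3353, "K2": 2.7247, "theta_deg": 12.00, "r_squared": 0.9829},
    "N5": {"c1_kPa": 18.3579, "D1_kPa": 5.1581, "D2": 1.9418, "K1_kPa": 1.1775, "K2": 4.5227, "theta_deg": 9.60, "r_squared": 0.9905}
  }
}
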