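{
  "description": "Published comparison of in vivo stiffness (subject-specific ex vivo initial guess) against ex vivo stiffness: circumferential shrinkage S (percent), stiffness scale k, effective Young's moduli (kPa), anisotropy indices and relative errors (percent). Used as inputs to the statistics layer; not regenerated by this package.",
  "rows": {
    "AD1": {"S_pct": 68.27, "k": 0.70, "YMc_invivo": 126.38, "YMa_invivo": 100.05, "AI_invivo": 0.23, "YMc_exvivo": 181.46, "YMa_exvivo": 142.92, "AI_exvivo": 0.24, "RE_YMc_pct": -30.35, "RE_YMa_pct": -30.00},
    "AD2": {"S_pct": 63.32, "k": 0.93, "YMc_invivo": 96.99, "YMa_invivo": 93.06, "AI_invivo": 0.04, "YMc_exvivo": 104.90, "YMa_exvivo": 100.06, "AI_exvivo": 0.05, "RE_YMc_pct": -7.54, "RE_YMa_pct": -7.00},
    "AD3": {"S_pct": 81.71, "k": 0.98, "YMc_invivo": 803.96, "YMa_invivo": 161.31, "AI_invivo": 1.33, "YMc_exvivo": 960.24, "YMa_exvivo": 160.14, "AI_exvivo": 1.43, "RE_YMc_pct": -16.28, "RE_YMa_pct": 0.73},
    "AD4": {"S_pct": 82.52, "k": 1.22, "YMc_invivo": 3247.44, "YMa_invivo": 179.87, "AI_invivo": 1.79, "YMc_exvivo": 3413.61, "YMa_exvivo": 142.87, "AI_exvivo": 1.84, "RE_YMc_pct": -4.87, "RE_YMa_pct": 25.90},
    "AD5": {"S_pct": 85.38, "k": 0.90, "YMc_invivo": 167.17, "YMa_invivo": 167.15, "AI_invivo": 0.00, "YMc_exvivo": 178.56, "YMa_exvivo": 178.51, "AI_exvivo": 0.00, "RE_YMc_pct": -6.38, "RE_YMa_pct": -6.37},
    "N1": {"S_pct": 57.76, "k": 0.67, "YMc_invivo": 108.67, "YMa_invivo": 92.67, "AI_invivo": 0.16, "YMc_exvivo": 163.27, "YMa_exvivo": 138.73, "AI_exvivo": 0.16, "RE_YMc_pct": -33.44, "RE_YMa_pct": -33.20},
    "N2": {"S_pct": 70.28, "k": 0.81, "YMc_invivo": 174.49, "YMa_invivo": 174.27, "AI_invivo": 0.00, "YMc_exvivo": 208.60, "YMa_exvivo": 208.35, "AI_exvivo": 0.00, "RE_YMc_pct": -16.35, "RE_YMa_pct": -16.35},
    "N3": {"S_pct": 80.98, "k": 0.96, "YMc_invivo": 181.07, "YMa_invivo": 180.96, "AI_invivo": 0.00, "YMc_exvivo": 219.94, "YMa_exvivo": 219.68, "AI_exvivo": 0.00, "RE_YMc_pct": -20.76, "RE_YMa_pct": -17.63},
    "N4": {"S_pct": 71.51, "k": 0.96, "YMc_invivo": 173.46, "YMa_invivo": 164.92, "AI_invivo": 0.05, "YMc_exvivo": 182.46, "YMa_exvivo": 171.96, "AI_exvivo": 0.06, "RE_YMc_pct": -4.93, "RE_YMa_pct": -4.09},
    "N5": {"S_pct": 82.41, "k": 0.90, "YMc_invivo": 270.60, "YMa_invivo": 217.57, "AI_invivo": 0.22, "YMc_exvivo": 310.02, "YMa_exvivo": 241.95, "AI_exvivo": 0.25, "RE_YMc_pct": -12.71, "RE_YMa_pct": -10.08}
  }
}
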