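{
 "description": "Clinical cohort: five type-A aortic dissection patients (AD1-AD5) and five donors with normal aortas (N1-N5). Cuff pressures, sample wall thickness and TEE lumen-perimeter extrema over one cardiac cycle.",
 "subjects": [
  {
   "id": "AD1",
   "group": "AD",
   "pressure_sys_mmHg": 133,
   "pressure_dia_mmHg": 76,
   "thickness_mm": 2.42,
   "perimeter_min_cm": 12.62,
   "perimeter_max_cm": 13.88,
   "perimeter_change_pct": 9.98
  },
  {
   "id": "AD2",
   "group": "AD",
   "pressure_sys_mmHg": 119,
   "pressure_dia_mmHg": 65,
   "thickness_mm": 1.74,
   "perimeter_min_cm": 13.43,
   "perimeter_max_cm": 14.48,
   "perimeter_change_pct": 7.82
  },
  {
   "id": "AD3",
   "group": "AD",
   "pressure_sys_mmHg": 136,
   "pressure_dia_mmHg": 91,
   "thickness_mm": 2.51,
   "perimeter_min_cm": 11.1,
   "perimeter_max_cm": 11.72,
   "perimeter_change_pct": 5.59
  },
  {
   "id": "AD4",
   "group": "AD",
   "pressure_sys_mmHg": 140,
   "pressure_dia_mmHg": 91,
   "thickness_mm": 2.8,
   "perimeter_min_cm": 9.6,
   "perimeter_max_cm": 9.89,
   "perimeter_change_pct": 3.02
  },
  {
   "id": "AD5",
   "group": "AD",
   "pressure_sys_mmHg": 113,
   "pressure_dia_mmHg": 60,
   "thickness_mm": 1.29,
   "perimeter_min_cm": 10.58,
   "perimeter_max_cm": 12.96,
   "perimeter_change_pct": 22.5
  },
  {
   "id": "N1",
   "group": "N",
   "pressure_sys_mmHg": 88,
   "pressure_dia_mmHg": 47,
   "thickness_mm": 1.66,
   "perimeter_min_cm": 8.5,
   "perimeter_max_cm": 9.69,
   "perimeter_change_pct": 14.0
  },
  {
   "id": "N2",
   "group": "N",
   "pressure_sys_mmHg": 117,
   "pressure_dia_mmHg": 61,
   "thickness_mm": 1.33,
   "perimeter_min_cm": 9.19,
   "perimeter_max_cm": 10.58,
   "perimeter_change_pct": 15.13
  },
  {
   "id": "N3",
   "group": "N",
   "pressure_sys_mmHg": 79,
   "pressure_dia_mmHg": 45,
   "thickness_mm": 1.31,
   "perimeter_min_cm": 9.16,
   "perimeter_max_cm": 10.33,
   "perimeter_change_pct": 12.77
  },
  {
   "id": "N4",
   "group": "N",
   "pressure_sys_mmHg": 111,
   "pressure_dia_mmHg": 61,
   "thickness_mm": 1.44,
   "perimeter_min_cm": 9.18,
   "perimeter_max_cm": 9.97,
   "perimeter_change_pct": 8.61
  },
  {
   "id": "N5",
   "group": "N",
   "pressure_sys_mmHg": 97,
   "pressure_dia_mmHg": 59,
   "thickness_mm": 1.2,
   "perimeter_min_cm": 9.94,
   "perimeter_max_cm": 10.89,
   "perimeter_change_pct": 9.56
  }
 ]
}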