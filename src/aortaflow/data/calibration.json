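{
  "kappa": 0.7920954534158965,
  "gamma_convention": "kgf",
  "pulse_rate": 72.0,
  "anchors_L_min": [
    5.23,
    7.95
  ],
  "calibrated_L_min": [
    4.744731682738531,
    8.763087731865587
  ],
  "residuals_percent": [
    -9.278552911309157,
    10.227518639818701
  ]
}
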