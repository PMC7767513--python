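{
  "features": [
    "XLogP", "Wlambda3.unity", "WTPT.4", "MW", "TopoPSA", "geomShape",
    "MLogP", "Kier1", "nHBAcc", "FPSA.3", "WPSA.1", "VP.7", "SPC.5",
    "BCUTc.1l", "ATSc4", "apol"
  ],
  "coefficients": [
    0.1863, 0.0425, -0.1608, 0.0856, -0.1178, 0.0224,
    0.0199, 0.0449, -0.1566, -0.0561, 0.0784, 0.2057, 0.0765,
    0.0864, -0.0978, 0.0975
  ],
  "intercept": 6.3243,
  "provenance": "fixture"
}
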