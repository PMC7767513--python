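{
  "features": ["XLogP", "ATSc4"],
  "coefficients": [0.8038, -0.4269],
  "intercept": 6.3243,
  "provenance": "fixture"
}
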