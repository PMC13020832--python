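{
  "statin": {
    "intercept": -1.65,
    "slope": 0.04,
    "predictor_name": "days covered at 90"
  },
  "antiplatelet": {
    "intercept": -1.52,
    "slope": 0.04,
    "predictor_name": "days covered at 90"
  }
}
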