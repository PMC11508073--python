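{
  "aberration_class": "dicentric_equivalents",
  "c": 0.008,
  "alpha": 0.088,
  "beta": 0.095,
  "se_c": 0.004,
  "se_alpha": 0.022,
  "se_beta": 0.009,
  "cov": null,
  "dose_unit": "Gy",
  "source": "laboratory FISH dicentric calibration (used for dose estimation)"
}
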