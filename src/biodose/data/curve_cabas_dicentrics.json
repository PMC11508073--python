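{
  "aberration_class": "dicentric_equivalents",
  "c": 0.0,
  "alpha": 0.021,
  "beta": 0.387,
  "se_c": null,
  "se_alpha": 0.002,
  "se_beta": 0.017,
  "cov": null,
  "dose_unit": "Gy",
  "source": "CABAS regression of G2-PCC dicentric yields (external; fit protocol unstated)"
}
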