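{
  "aberration_class": "centric_rings",
  "c": 0.0,
  "alpha": 0.001,
  "beta": 0.051,
  "se_c": null,
  "se_alpha": null,
  "se_beta": null,
  "cov": null,
  "dose_unit": "Gy",
  "source": "CABAS regression of G2-PCC total ring yields (external; fit protocol unstated)"
}
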