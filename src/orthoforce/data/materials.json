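{
  "S": {"name": "stainless steel", "E_Pa": 1.79e11, "poisson": 0.3},
  "A": {"name": "Australian", "E_Pa": 1.57e11, "poisson": 0.3}
}
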