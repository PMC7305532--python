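{
  "S": {"name": "stainless steel (effective)", "E_Pa": 7.92e10, "poisson": 0.3},
  "A": {"name": "Australian (effective)", "E_Pa": 6.97e10, "poisson": 0.3}
}
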