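{
  "E0": 21.8,
  "E1": 5.8,
  "H": 25.0,
  "G": 5.0,
  "d_nm": 0.56,
  "r0_nm": 1.7,
  "alpha_min_deg": 48.0,
  "alpha_c_deg": 53.0,
  "alpha_max_deg": 169.0,
  "phi_deg": 0.0
}
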