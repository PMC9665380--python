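{
  "n_ads": 4808,
  "raw_advertisers": 252,
  "raw_names": 386,
  "scaled_advertisers": 118.55833473279561,
  "scaled_workers": 208.47330754846658,
  "r_idchange": 0.015068712823112104,
  "p_relevant": 0.9841269841269841
}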