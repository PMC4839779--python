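{
  "drug": "ranibizumab",
  "f_price_eur": 9050,
  "tot_pt": 20000,
  "data_pairs": [[0, 9050], [20000, 6500]]
}
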