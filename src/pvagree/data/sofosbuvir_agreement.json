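{
  "drug": "sofosbuvir",
  "f_price_eur": 37500,
  "tot_pt": 60000,
  "data_pairs": [[0, 37500], [60000, 4000]]
}
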