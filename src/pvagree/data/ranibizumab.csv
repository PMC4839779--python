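n_treated,price_eur
0,9050
20000,6500
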