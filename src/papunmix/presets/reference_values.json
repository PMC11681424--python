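{
  "EY": 2.003,
  "H": 1.889,
  "LG": 2.550,
  "OG": 1.213
}
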