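{
  "name": "brs",
  "items": ["brs1", "brs2", "brs3", "brs4", "brs5", "brs6"],
  "response_range": [1, 5],
  "reverse_items": ["brs2", "brs4", "brs6"]
}
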