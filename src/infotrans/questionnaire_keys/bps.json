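{
  "name": "bps",
  "items": ["bps1", "bps2", "bps3", "bps4", "bps5", "bps6", "bps7", "bps8"],
  "response_range": [1, 7],
  "reverse_items": []
}
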