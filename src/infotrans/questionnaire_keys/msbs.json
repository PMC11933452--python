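{
  "name": "msbs",
  "items": ["msbs1", "msbs2", "msbs3", "msbs4", "msbs5", "msbs6", "msbs7", "msbs8"],
  "response_range": [1, 7],
  "reverse_items": []
}
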