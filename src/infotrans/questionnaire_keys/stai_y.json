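{
  "name": "stai_y",
  "items": ["stai1", "stai2", "stai3", "stai4", "stai5", "stai6", "stai7", "stai8", "stai9", "stai10",
            "stai11", "stai12", "stai13", "stai14", "stai15", "stai16", "stai17", "stai18", "stai19", "stai20"],
  "response_range": [1, 4],
  "reverse_items": ["stai1", "stai3", "stai6", "stai7", "stai10", "stai13", "stai14", "stai16", "stai19"]
}
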