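{
  "name": "bfi10",
  "items": ["bfi1", "bfi2", "bfi3", "bfi4", "bfi5", "bfi6", "bfi7", "bfi8", "bfi9", "bfi10"],
  "response_range": [1, 5],
  "reverse_items": ["bfi1", "bfi3", "bfi4", "bfi5", "bfi7"],
  "subscales": {
    "extraversion": ["bfi1", "bfi6"],
    "agreeableness": ["bfi2", "bfi7"],
    "conscientiousness": ["bfi3", "bfi8"],
    "neuroticism": ["bfi4", "bfi9"],
    "openness": ["bfi5", "bfi10"]
  }
}
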