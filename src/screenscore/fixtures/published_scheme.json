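{
  "version": "copd_eq_v1_published",
  "step": 0.5,
  "scores": {
    "item1": [0, 1, 1.5, 3],
    "item2": [0, 1.5, 1.5, 1.5],
    "item3": [0, 0.5],
    "item4": [0, 0.5, 0.5, 1.5, 2],
    "item5": [0, 0.5, 0.5, 0.5, 1],
    "item6": [0, 0],
    "item7": [0, 1, 1, 1, 1],
    "item8": [0, 0],
    "item9": [0, 0]
  }
}
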