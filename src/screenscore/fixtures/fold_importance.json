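{
  "note": "Published five-fold mean-|SHAP| attributions and within-fold ranks for the nine questionnaire items, used to reproduce the rank-sum ensembling arithmetic.",
  "items": ["item1", "item2", "item3", "item4", "item5", "item6", "item7", "item8", "item9"],
  "shap": [
    [0.45, 0.47, 0.49, 0.50, 0.49],
    [0.46, 0.31, 0.27, 0.35, 0.33],
    [0.17, 0.16, 0.23, 0.19, 0.17],
    [0.46, 0.50, 0.42, 0.39, 0.42],
    [0.03, 0.07, 0.08, 0.06, 0.00],
    [0.17, 0.15, 0.13, 0.12, 0.12],
    [0.07, 0.08, 0.06, 0.11, 0.07],
    [0.01, 0.02, 0.01, 0.01, 0.00],
    [0.00, 0.01, 0.03, 0.03, 0.02]
  ],
  "ranks": [
    [3, 2, 1, 1, 1],
    [2, 3, 3, 3, 3],
    [5, 4, 4, 4, 4],
    [1, 1, 2, 2, 2],
    [7, 7, 6, 7, 8],
    [4, 5, 5, 5, 5],
    [6, 6, 7, 6, 6],
    [8, 8, 9, 9, 9],
    [9, 9, 8, 8, 7]
  ],
  "published_final_rank": [1, 3, 4, 2, 7, 5, 6, 9, 8]
}
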