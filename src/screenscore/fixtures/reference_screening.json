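{
  "note": "Published per-threshold screening performance (percent) of the six-item scored questionnaire (copd_eq) and of the comparison instrument copd_ps. 'balanced' is the per-threshold (sensitivity+specificity)/2 column the source labels AUC.",
  "copd_eq": {
    "threshold": [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0],
    "balanced": [51.18, 51.29, 54.80, 57.75, 60.32, 64.07, 67.80, 71.37, 73.39, 69.27, 64.98, 60.95, 57.27, 54.62, 52.69, 51.76, 50.87, 50.00, 50.00],
    "sensitivity": [99.75, 99.00, 98.50, 95.26, 91.27, 86.53, 79.80, 72.82, 67.58, 51.62, 36.91, 26.18, 17.21, 10.22, 5.74, 3.74, 1.75, 0.00, 0.00],
    "specificity": [2.60, 3.58, 11.10, 20.24, 29.37, 41.60, 55.80, 69.92, 79.20, 86.93, 93.04, 95.71, 97.33, 99.02, 99.65, 99.79, 100.00, 100.00, 100.00]
  },
  "copd_ps": {
    "threshold": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0],
    "balanced": [53.51, 58.89, 65.04, 69.32, 68.51, 64.00, 61.55, 56.88, 52.40, 50.05],
    "sensitivity": [99.01, 96.32, 85.05, 74.27, 54.41, 36.28, 25.98, 14.95, 5.15, 0.25],
    "specificity": [8.00, 21.46, 45.02, 64.38, 82.61, 91.73, 97.13, 98.81, 99.65, 99.86]
  }
}
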