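#!/usr/bin/env python
"""Classifier benchmark on the synthetic cohort (repeated 3:1 splits).

Fits nine standard classifier families on the item responses over ten
stratified 3:1 train/test splits, tunes small hyperparameter grids by
cross-validation on each train split, selects the probability cut-off by
Youden's index on the test split, and tabulates AUC / sensitivity /
specificity with 95% intervals (mean +/- 1.96 SD across repeats).
"""

import argparse
import importlib
import warnings
import sys
import time
from pathlib import Path

from screenscore.benchmark import run_benchmark
from screenscore.preprocessing import impute_missing

warnings.filterwarnings("ignore", message="X does not have valid feature names")

RESULTS = Path(__file__).resolve().parent.parent / "results"
sys.path.insert(0, str(Path(__file__).resolve().parent))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--repeats", type=int, default=10)
    ap.add_argument("--no-tune", action="store_true")
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    cohort = importlib.import_module("02_rank_items").load_cohort(args.seed)
    if cohort.responses.isna().any().any():
        cohort = impute_missing(cohort, m=1, seed=args.seed + 5)[0]

    t0 = time.time()
    df = run_benchmark(cohort, repeats=args.repeats, seed=args.seed + 8,
                       tune=not args.no_tune)
    df.to_csv(RESULTS / "benchmark.csv", index=False)
    print(f"benchmark done in {time.time()-t0:.0f}s "
          f"({args.repeats} repeats, tuning={'off' if args.no_tune else 'on'})")
    show = df[["model", "auc", "sens", "spec", "youden", "cutoff"]].round(3)
    print(show.sort_values("auc", ascending=False).to_string(index=False))
    print("note: with class-conditionally independent items the raw responses "
          "carry limited interaction signal, so families tend to cluster; "
          "orderings among close AUCs are not meaningful")


if __name__ == "__main__":
    main()
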