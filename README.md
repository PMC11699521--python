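# screenscore

Construction and evaluation of additive screening scorecards for a
nine-item COPD self-evaluation questionnaire, built as an analysis project:
a library (`src/screenscore/`) that implements every step, numbered
narrative drivers (`analysis/`) that run the study end to end on synthetic
data, and a CLI (`screenscore`) for the individual stages.

## The problem

Spirometry (post-bronchodilator FEV1/FVC < 0.70) is the gold standard for
diagnosing chronic obstructive pulmonary disease, but most COPD goes
undiagnosed because lung-function testing is scarce. A practical screening
path is a short questionnaire whose answers map to points; a respondent
whose total exceeds a threshold is referred for spirometry. This package
implements a machine-learning-guided way to build such a scorecard from
class-labelled questionnaire data:

1. **Item ranking.** Each question (ordinal response code) is a feature of a
   gradient-boosted tree classifier fitted per fold of a stratified 5-fold
   cross-validation; an item's importance per fold is the held-out mean
   |SHAP| (Shapley attribution). Per-fold dense ranks are ensembled by
   summation: final ranks ascend in rank-sum, ties broken by the larger
   summed attribution.
2. **Tiered caps.** The top two items are capped at 3 points, ranks 3–5 at
   2, ranks 6–7 at 1, and the rest are eliminated (all-zero scores) —
   collapsing the unconstrained scoring problem to a tractable grid.
3. **Scorecard search.** Candidate schemes assign each response choice a
   score in {0, 0.5, …, cap}, zero for the least severe choice and weakly
   non-decreasing with medical severity. A scheme is judged by the best
   *balanced screening index* (sensitivity + specificity)/2 it attains over
   the 0.5-spaced threshold grid under the strict rule *positive ⇔ score >
   threshold*; the grid search returns the maximizer (exhaustive and exact
   branch-and-bound strategies for spaces up to ~10⁶ schemes, beam search
   beyond).
4. **Operating point & evaluation.** The threshold is chosen by Youden's
   index J = sensitivity + specificity − 1; evaluation covers ROC AUC,
   threshold sweep tables, comparison against a reference instrument's
   printed columns, test-retest reliability (Pearson and ICC(2,1)),
   discriminant validity against spirometry, and a nine-family classifier
   benchmark on repeated stratified 3:1 splits.

Because the development cohort is not publicly deposited, the package ships
a synthetic cohort generator that reproduces the published class-conditional
response distributions (404 cases / 1420 controls), pack-year bands,
spirometry consistent with the diagnostic rule, a configurable test-retest
agreement, and optional missingness with chained-equations multiple
imputation.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_rank_items.py --seed 1
python analysis/03_search_scorecard.py --seed 1
python analysis/04_screening_tables.py --seed 1
python analysis/05_reliability_validity.py --seed 1
python analysis/06_ml_benchmark.py --seed 1
```

Output from that run (abridged):

```
simulated 1824 subjects; 404 cases (22.1% prevalence)
published fold table re-ensembled; final ranks: {'item1': 1, 'item2': 3,
  'item3': 4, 'item4': 2, 'item5': 7, 'item6': 5, 'item7': 6, 'item8': 9,
  'item9': 8}
synthetic-cohort final ranks: {'item1': 1, 'item2': 2, ..., 'item8': 9, 'item9': 8}
space sizes: 2.178e+10 with zeros, 5.378e+08 without
beam search (512 wide): balanced index 0.7305 at threshold 2.0
published six-item scheme on the same cohort: balanced index 0.6953 at threshold 3.5
test-retest on n=96: Pearson r 0.886, ICC(2,1) 0.878
discriminant validity: fev1 r = -0.192, fev1pp r = -0.295, fev1_fvc r = -0.372
```

Reading this: the prevalence matches the development cohort (404/1824 =
22.1%). Re-ensembling the published five-fold importance table reproduces
the published final ranking exactly, including the rank-sum tie between
items 1 and 4 resolved by summed attribution (2.40 vs 2.19). On the
synthetic cohort the near-uninformative childhood-disease item (item 8,
whose case/control response frequencies almost coincide) lands in the
bottom two, as it should. The searched scorecard beats the published
six-item scheme on the synthetic cohort it was tuned to; the published
scheme's balanced index there (0.695) is close to, but below, its value on
the real cohort (0.734), since the generator assumes class-conditional
independence. Reliability coefficients at 90% simulated item agreement
land near the published 0.89/0.94, and all three score–lung-function
correlations are negative, as discriminant validity requires.

Each stage is also a CLI subcommand operating on CSV files, e.g.

```bash
screenscore simulate --n-case 404 --n-control 1420 --seed 1 --out cohort.csv
screenscore search --cohort cohort.csv --strategy beam --seed 1 \
    --out scheme.json --table sweep.csv
screenscore run --config run.yml
```

## Layout

```
src/screenscore/   library: schema, cohort, preprocessing, ranking, search,
                   evaluation, reliability, benchmark, pipeline, cli
analysis/          numbered narrative drivers writing tables to results/
tests/             pytest suite (unit, property, acceptance)
scripts/           acceptance.py
docs/methods.md    model, assumptions, parameters, numerical choices
```
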