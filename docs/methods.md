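# Methods

This note documents the models, parameters and numerical choices behind
`screenscore`, and what the synthetic-data results do and do not show.

## Data model

A questionnaire is an ordered list of items; each item has 2–5 response
choices indexed 0, 1, … in order of medical severity, with index 0 the
baseline. The packaged nine-item COPD questionnaire has choice counts
(4, 4, 2, 5, 5, 2, 5, 2, 2): age bands, smoking-amount bands, biomass
exposure, shortness-of-breath frequency, dyspnoea grade, chronic cough,
expectoration frequency, childhood respiratory disease, and family history.
A subject carries the nine response codes, continuous pack-years, a smoker
flag, optional spirometry (FEV1 in litres, FEV1 percent predicted, FEV1/FVC),
a case/control label defined by FEV1/FVC < 0.70, and optionally a second
(retest) copy of the responses.

## Synthetic cohort generator

The generator's default conditions are the development cohort's: 404 cases
and 1420 controls, item responses drawn class-conditionally from the
published per-choice frequencies. Where the source prints counts, the
fixture stores exact count-derived fractions (e.g. 387/404), not the rounded
percentages, to avoid compounding rounding in simulation.

**Smoking amount.** The smoking item is printed only as continuous
pack-year summaries (case mean 27.8, median 20.0, IQR 0.0–40.0; control
mean 12.0, median 0.0, IQR 0.0–20.0), not per-band counts. The fixture's
band probabilities are therefore synthetic values chosen once to be
consistent with those quantiles — case (0.28, 0.10, 0.12, 0.50), control
(0.55, 0.12, 0.08, 0.25) over the bands {0, (0,10), [10,20), ≥20}
packs/year: a zero first quartile forces P(band 0) ≥ 0.25 for cases and the
zero median forces P(band 0) ≥ 0.5 for controls, while the case median of
20 puts about half the cases at ≥20 packs/year. Continuous pack-years are
drawn within-band from log-normals truncated to the band (medians 5, 14, 35
packs/year), so re-discretising recovers the band exactly; any within-band
law consistent with the bands would serve, since downstream stages consume
the bands.

**Dependence.** By default items are independent given the class, because
the source publishes only marginals. A `dependence` parameter in [0, 1)
couples items through a one-factor Gaussian copula (a shared latent
severity) while preserving every marginal; it exists to stress-test the
ranking and search, not to match any published correlation structure.

**Spirometry.** FEV1/FVC is drawn from class-specific normals (case mean
0.55, control mean 0.78, SD 0.08) with rejection of draws on the wrong side
of 0.70, so the diagnostic rule holds by construction. FEV1 percent
predicted decreases linearly in the obstruction deficit max(0, 0.70 − ratio)
with Gaussian noise, and FEV1 in litres scales a predicted volume
(normal, mean 3.0 L) by that percentage. This yields the negative
score–lung-function correlations a valid severity score must show; the
magnitudes are not calibrated to the published ones.

**Retest.** Each item independently repeats the entry response with
probability `agreement` (default 0.9) and is otherwise resampled from the
subject's class-conditional item distribution; observed raw agreement
therefore slightly exceeds the nominal value because a resample can redraw
the entry answer.

**Missingness** is missing-completely-at-random only, at a configurable
rate, never touching the label; the source does not characterise its
missingness (a handful of missing smoking answers), so no richer mechanism
is asserted.

What passing tests on these cohorts show: the pipeline's arithmetic,
determinism, and its statistical behaviour under known marginals (e.g. the
near-uninformative childhood-disease item reliably ranks in the bottom
two). What they do not show: recovery of the published scorecard or its
exact performance numbers, which depend on the undeposited real cohort and
its inter-item correlations.

## Preprocessing

Smoking exposure discretises into bands 0 (never-smoker), then <200,
[200, 400), ≥400 cigarettes/year, closed on the left; the packs/year view
divides by 20 cigarettes per pack, giving <10, [10, 20), ≥20. Encodings are
ordinal (one integer column per item; used by tree models and the ranking,
so one attribution per question) or one-hot (one indicator per choice,
baseline included, exactly one active per item block; used by linear,
kernel and distance models).

Multiple imputation (default m = 5) uses chained equations over the
categorical items: missing entries are initialised from the observed
class-conditional marginal, then iteratively redrawn (4 sweeps) from a
multinomial-logistic model of each item given one-hot encodings of the
other items plus the label. Missing pack-years are redrawn from the
(completed) band. Downstream stages consume the first completed copy by
default; the source does not state how its imputations were pooled, so no
pooling rule is asserted.

## Item ranking

Per stratified fold (k = 5; each fold an 80/20 split), a LightGBM
gradient-boosted tree classifier (100 trees, depth 4, learning rate 0.1)
is fitted on the training split and each item's importance is the mean
absolute Shapley attribution over the held-out split, computed by the
library's exact TreeSHAP (`pred_contrib`). The statistic — mean
|attribution| over all held-out subjects, not over the positive class only
— is recorded in the report metadata. Within-fold dense ranks (1 = largest)
break ties by item order. The ensemble assigns final ranks ascending in
rank-sum, breaking rank-sum ties by the larger summed attribution and any
remaining ties by schema order; on the published fold table this reproduces
the printed final ranking, including the item-1/item-4 tie resolved by
summed attributions 2.40 vs 2.19. When k exceeds the minority class size
(e.g. leave-one-out), plain shuffled K-fold replaces stratification; every
training split must still contain both classes.

## Scorecard search

Caps follow the tier rule (ranks 1–2 → 3 points, 3–5 → 2, 6–7 → 1,
≥8 → 0). For an item with m non-baseline choices and v admissible values
per choice, the weakly non-decreasing score vectors are the m-multisets of
the value grid: C(v + m − 1, m). With the development-cohort caps the full
space holds 3 472 875 000 schemes when per-choice grids include zero and
56 448 000 when they do not. (Neither printed size — 2.19e16 before nor
1.29e7 after reduction — is derivable from the stated constraints; the
package computes and reports its own counts.) Zero-valued choice scores are
allowed by default because the published outcome itself contains items
whose choices all score zero; a strict mode excluding zeros is provided.

The objective is the best balanced index (sensitivity + specificity)/2
over thresholds 0, 0.5, …, max total under the strict decision rule
positive ⇔ score > threshold. The strict rule is forced by the published
threshold-0 row, where sensitivity is 99.75% rather than 100% — impossible
under a ≥ rule. "Consistency with medical severity" is implemented as weak
monotonicity, since the published scheme contains tied scores. The
objective is evaluated on the full supplied cohort (a split option exists);
it can never fall below 0.5, because some threshold always classifies
everything negative (sensitivity 0, specificity 1).

Internally scores are half-units, so a scheme's totals histogram indexes
the threshold grid directly; subjects collapse to weighted distinct
response patterns, and a batch of candidate extensions of a partial scheme
is evaluated with one offset bincount. Strategies:

* **exhaustive** — depth-first in lexicographic order (refused above a
  10⁸-scheme budget); the first strict improvement wins, so among
  equal-objective schemes the lexicographically smallest is returned, then
  the smallest optimal threshold.
* **pruned** — the same search with an admissible branch-and-bound bound:
  for a partial scheme, sensitivity is bounded by giving every case its
  maximal remaining points and specificity by giving every control its
  minimal remaining points; the maximum over thresholds of the average of
  these per-class relaxations bounds every completion, so pruning never
  removes a strict improvement and the argmax (with identical tie-breaks)
  equals exhaustive. A beam pass seeds the incumbent just below its value,
  which tightens pruning without affecting exactness. Practical to roughly
  10⁶ schemes on an 1824-subject cohort.
* **beam** — approximate: expands items in order, keeping the `beam_width`
  best prefixes by the same admissible bound. Used for the full-scale
  spaces; width 512 by default in the analysis driver.

## Evaluation, reliability, validity

ROC AUC is the trapezoidal area (scikit-learn), equal to tie-corrected
concordance; Youden's J = sensitivity + specificity − 1 = 2·balanced − 1.
The descriptive cohort table uses the chi-square test without continuity
correction (a corrected variant is a flag; neither reproduces the printed
statistics from the printed counts, so neither is privileged), switching to
Fisher's exact test for 2×2 tables with any expected cell ≤ 5, and a
Wilcoxon rank-sum test for pack-years.

Reliability is computed on total scores of the paired administrations
(complete cases), on a random subsample of 96 by default: Pearson r and the
intraclass correlation fixed to the two-way random-effects,
absolute-agreement, single-measure variant ICC(2,1) — the source names no
variant, and the published "0.89 in the first and 0.94 in the second round"
is ambiguous (two coefficients for one pair), so the report emits one
Pearson and one ICC. ICC(2,1) is estimated from the two-way ANOVA mean
squares and cross-checked in tests against an independent implementation.
Discriminant validity reports Pearson r (with two-sided p) of the total
score against FEV1, FEV1 percent predicted and FEV1/FVC.

## Classifier benchmark

Nine families — SVM, Gaussian naive Bayes, random forest, k-NN, logistic
regression, AdaBoost and three gradient-boosted tree implementations
(XGBoost, LightGBM, scikit-learn's histogram GBDT) — are evaluated on
repeated (default 10) stratified 3:1 splits. Hyperparameters may be tuned
per repeat by 3-fold grid search on the training split over small
published-range grids (depth, iterations, learning rate, L2 regularisation;
SVM cost/kernel; logistic penalty strength); exact grids live in the model
registry. The probability cut-off maximizes Youden's index on the test
split (smallest cut-off on ties) — optimistic by construction, as the
wording of the original procedure implies; a train-side option exists.
Intervals are mean ± 1.96·SD across repeats; the Youden column is exactly
sens + spec − 1 of the mean operating point. On independence-generated
cohorts the families cluster closely and their ordering is not meaningful;
a boosted-over-linear advantage only emerges when the generator plants
item interactions.

## Problem sizes and defaults

Analysis drivers default to the development-cohort scale (1824 subjects),
5-fold ranking, beam width 512 for the full search space, an exact
branch-and-bound demonstration on a reduced-cap space (~5·10⁴ schemes),
96-subject reliability subsample, and 10 benchmark repeats. Tests use
smaller cohorts (a few hundred subjects) and toy scorecard spaces
(≤ 500 schemes) where an independent brute-force oracle is feasible, plus
one 50 000-per-class draw for marginal fidelity.

## Known limitations

* Item-2 band probabilities are quantile-consistent constructions, not
  published counts; cohort-level pack-year moments match the published ones
  only approximately.
* Class-conditional independence understates real inter-item correlation;
  absolute screening indices on synthetic cohorts run a few points below
  the published real-data values.
* Exact search beyond ~10⁶ schemes is impractical on one CPU; the
  full-scale space is searched approximately (beam), so the analysis
  driver's "best" scheme is a lower bound on the space's optimum.
* The ICC variant and the imputation pooling rule are package choices where
  the source is silent; both are recorded in report metadata/config.
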