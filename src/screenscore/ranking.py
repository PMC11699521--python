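"""Item importance ranking: cross-validated Shapley attributions, rank-sum ensemble.

Each question (one ordinal feature per item) is ranked by the mean absolute
Shapley attribution of a gradient-boosted decision-tree classifier, computed
on the held-out split of each of K stratified cross-validation folds
(every fold is an 80/20 train/test split at K = 5).  A single fold's ranking
is noisy, so the per-fold dense ranks are ensembled by summation: final
ranks are assigned ascending in rank-sum, ties broken by the larger total
attribution, remaining ties by schema order.

Attributions are exact TreeSHAP values computed by the boosting library
itself (``pred_contrib``); the statistic is the mean |attribution| over
held-out subjects, recorded in the report metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import Cohort
from .preprocessing import encode

__all__ = ["ImportanceReport", "crossval_attributions", "ensemble_ranks", "rank_items"]

_DEFAULT_MODEL_PARAMS = dict(
    n_estimators=100, max_depth=4, learning_rate=0.1, min_child_samples=20, verbose=-1
)


class StratificationError(ValueError):
    """A cross-validation fold lost one of the classes."""


def _dense_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..Q, 1 = largest value; ties broken by item (column) order."""
    order = np.lexsort((np.arange(len(values)), -values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


@dataclass
class ImportanceReport:
    """Per-fold attributions and ranks plus the ensembled final ranking."""

    item_ids: tuple[str, ...]
    fold_attributions: np.ndarray  # (k, Q) mean |Shapley attribution|
    fold_ranks: np.ndarray  # (k, Q) dense ranks, 1 = most important
    rank_sum: np.ndarray  # (Q,)
    attribution_sum: np.ndarray  # (Q,)
    final_rank: np.ndarray  # (Q,) permutation of 1..Q
    metadata: dict = field(default_factory=dict)

    def final_rank_of(self, item_id: str) -> int:
        return int(self.final_rank[self.item_ids.index(item_id)])

    def to_frame(self) -> pd.DataFrame:
        """Wide table: item, per-fold (attribution, rank) pairs, sums, final rank."""
        k = self.fold_ranks.shape[0]
        cols: dict[str, object] = {"item": list(self.item_ids)}
        for f in range(k):
            cols[f"fold{f + 1}_shap"] = self.fold_attributions[f]
            cols[f"fold{f + 1}_rank"] = self.fold_ranks[f]
        cols["rank_sum"] = self.rank_sum
        cols["shap_sum"] = self.attribution_sum
        cols["final_rank"] = self.final_rank
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def crossval_attributions(
    cohort: Cohort,
    k: int = 5,
    seed: int = 0,
    model_params: dict | None = None,
) -> np.ndarray:
    """Held-out mean |Shapley attribution| per item for each of k CV folds.

    Returns an array of shape ``(k, Q)``.  Folds are stratified by label when
    k allows it (k at most the minority class size), otherwise plain shuffled
    K-fold is used (e.g. leave-one-out); either way every *training* split
    must contain both classes.
    """
    fm = encode(cohort, mode="ordinal")
    X = fm.X.astype(float)
    y = fm.y
    n_minority = int(min(np.sum(y == 1), np.sum(y == 0)))
    if n_minority == 0:
        raise StratificationError("cohort contains a single class")
    params = {**_DEFAULT_MODEL_PARAMS, **(model_params or {})}
    if k <= n_minority:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    out = np.empty((k, X.shape[1]))
    for f, (tr, te) in enumerate(splitter.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise StratificationError(f"fold {f + 1}: a class is absent from the train split")
        clf = LGBMClassifier(random_state=seed + f, **params)
        clf.fit(X.iloc[tr], y[tr])
        contrib = clf.predict(X.iloc[te], pred_contrib=True)
        # last column is the expected-value offset, not a feature attribution
        out[f] = np.abs(contrib[:, :-1]).mean(axis=0)
    return out


def ensemble_ranks(
    fold_ranks: np.ndarray,
    fold_attributions: np.ndarray,
    item_ids: tuple[str, ...] | None = None,
) -> ImportanceReport:
    """Combine per-fold ranks by summation into a final consensus ranking.

    Final ranks are ascending in rank-sum; a rank-sum tie goes to the item
    with the larger summed attribution, and any remaining tie to the earlier
    item in schema order.
    """
    fold_ranks = np.asarray(fold_ranks)
    fold_attributions = np.asarray(fold_attributions, dtype=float)
    if fold_ranks.shape != fold_attributions.shape:
        raise ValueError(
            f"rank matrix {fold_ranks.shape} and attribution matrix "
            f"{fold_attributions.shape} disagree"
        )
    k, q = fold_ranks.shape
    for f in range(k):
        if sorted(fold_ranks[f]) != list(range(1, q + 1)):
            raise ValueError(f"fold {f + 1} ranks are not a permutation of 1..{q}")
    item_ids = tuple(item_ids) if item_ids is not None else tuple(f"item{i+1}" for i in range(q))
    rank_sum = fold_ranks.sum(axis=0)
    attr_sum = fold_attributions.sum(axis=0)
    order = np.lexsort((np.arange(q), -attr_sum, rank_sum))
    final = np.empty(q, dtype=int)
    final[order] = np.arange(1, q + 1)
    return ImportanceReport(
        item_ids=item_ids,
        fold_attributions=fold_attributions,
        fold_ranks=fold_ranks,
        rank_sum=rank_sum,
        attribution_sum=attr_sum,
        final_rank=final,
        metadata={"statistic": "mean_abs_shap", "k": k},
    )


def rank_items(
    cohort: Cohort, k: int = 5, seed: int = 0, model_params: dict | None = None
) -> ImportanceReport:
    """End-to-end: cross-validated attributions, per-fold ranks, ensembled final rank."""
    attrs = crossval_attributions(cohort, k=k, seed=seed, model_params=model_params)
    ranks = np.vstack([_dense_ranks(a) for a in attrs])
    return ensemble_ranks(ranks, attrs, item_ids=tuple(cohort.item_columns))
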