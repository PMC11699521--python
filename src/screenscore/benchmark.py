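"""Classifier benchmark on questionnaire responses (repeated 3:1 splits).

Nine standard classifier families are fitted on the item responses and
evaluated on stratified random 3:1 train/test splits, repeated with
different seeds.  Per repeat, hyperparameters may be tuned by
cross-validated grid search on the train split; the probability cut-off is
the one maximizing Youden's index on the test split (as an optimistic
screening-oriented operating point; a train-side option exists).  Rows
aggregate the repeats as mean and a 95% interval of mean +/- 1.96 SD.

Tree-based families consume ordinal item codes; linear/kernel/distance
families consume the one-hot choice encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from lightgbm import LGBMClassifier
from xgboost import XGBClassifier

from .cohort import Cohort
from .evaluation import roc_auc
from .preprocessing import encode
from .search import _as_case_mask

__all__ = ["MODEL_REGISTRY", "BenchmarkRow", "youden_optimal_cutoff", "run_benchmark"]


def _registry(seed: int) -> dict[str, dict]:
    """Model factories, encoding mode and small tuning grids per family."""
    return {
        "svm": dict(
            est=SVC(probability=True, random_state=seed),
            mode="onehot",
            grid={"C": [0.5, 1.0, 4.0], "kernel": ["rbf", "linear"]},
        ),
        "naive_bayes": dict(est=GaussianNB(), mode="onehot", grid={}),
        "random_forest": dict(
            est=RandomForestClassifier(random_state=seed, n_estimators=200),
            mode="ordinal",
            grid={"max_depth": [4, 8, None]},
        ),
        "knn": dict(
            est=KNeighborsClassifier(),
            mode="onehot",
            grid={"n_neighbors": [15, 31, 63]},
        ),
        "logistic_regression": dict(
            est=LogisticRegression(max_iter=500),
            mode="onehot",
            grid={"C": [0.1, 1.0, 10.0]},
        ),
        "adaboost": dict(
            est=AdaBoostClassifier(random_state=seed),
            mode="ordinal",
            grid={"n_estimators": [50, 200], "learning_rate": [0.5, 1.0]},
        ),
        "xgboost": dict(
            est=XGBClassifier(
                random_state=seed, eval_metric="logloss", n_estimators=200
            ),
            mode="ordinal",
            grid={"max_depth": [3, 5], "learning_rate": [0.05, 0.1], "reg_lambda": [1.0, 5.0]},
        ),
        "lightgbm": dict(
            est=LGBMClassifier(random_state=seed, verbose=-1, n_estimators=200),
            mode="ordinal",
            grid={"max_depth": [3, 5], "learning_rate": [0.05, 0.1], "reg_lambda": [0.0, 5.0]},
        ),
        "hist_gradient_boosting": dict(
            est=HistGradientBoostingClassifier(random_state=seed),
            mode="ordinal",
            grid={"max_depth": [3, 5], "learning_rate": [0.05, 0.1], "l2_regularization": [0.0, 5.0]},
        ),
    }


def youden_optimal_cutoff(probabilities, labels) -> tuple[float, float, float]:
    """Probability cut-off maximizing Youden's index under the strict rule.

    Scans the unique predicted probabilities as cut-offs (positive iff
    probability > cut-off) and returns ``(cutoff, sensitivity, specificity)``;
    ties go to the smallest cut-off.
    """
    p = np.asarray(probabilities, dtype=float)
    is_case = _as_case_mask(labels)
    if is_case.all() or not is_case.any():
        raise ValueError("both classes required to select a cut-off")
    best = None
    for c in np.unique(p):
        sens = float(np.mean(p[is_case] > c))
        spec = float(np.mean(p[~is_case] <= c))
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, float(c), sens, spec)
    return best[1], best[2], best[3]


@dataclass
class BenchmarkRow:
    model: str
    auc: float
    auc_lo: float
    auc_hi: float
    sens: float
    sens_lo: float
    sens_hi: float
    spec: float
    spec_lo: float
    spec_hi: float
    youden: float
    cutoff: float


def _interval(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def run_benchmark(
    cohort: Cohort,
    repeats: int = 10,
    seed: int = 0,
    tune: bool = True,
    models: list[str] | None = None,
    test_size: float = 0.25,
    point_only: bool = False,
    cutoff_on_train: bool = False,
) -> pd.DataFrame:
    """Benchmark the classifier families on repeated stratified 3:1 splits.

    Returns one row per model with mean AUC / sensitivity / specificity and
    their 95% intervals across repeats, the Youden index of the mean
    operating point, and the mean selected probability cut-off.
    """
    if repeats < 2 and not point_only:
        raise ValueError("repeats < 2 gives no spread; pass point_only=True for a single run")
    registry = _registry(seed)
    names = models or list(registry)
    unknown = set(names) - set(registry)
    if unknown:
        raise KeyError(f"unknown model(s): {sorted(unknown)}")
    encoded = {mode: encode(cohort, mode=mode) for mode in ("ordinal", "onehot")}
    y = encoded["ordinal"].y
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes required")
    results: dict[str, dict[str, list[float]]] = {
        n: {"auc": [], "sens": [], "spec": [], "cutoff": []} for n in names
    }
    for r in range(repeats):
        split_seed = seed + 1000 * r
        idx = np.arange(len(y))
        tr, te = train_test_split(
            idx, test_size=test_size, stratify=y, random_state=split_seed
        )
        for name in names:
            spec_entry = registry[name]
            X = encoded[spec_entry["mode"]].X.to_numpy(dtype=float)
            est = spec_entry["est"]
            if tune and spec_entry["grid"]:
                cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=split_seed)
                gs = GridSearchCV(est, spec_entry["grid"], cv=cv, scoring="roc_auc", n_jobs=1)
                gs.fit(X[tr], y[tr])
                model = gs.best_estimator_
            else:
                from sklearn.base import clone

                model = clone(est)
                model.fit(X[tr], y[tr])
            proba_te = model.predict_proba(X[te])[:, 1]
            auc = roc_auc(proba_te, y[te]).value
            if cutoff_on_train:
                proba_tr = model.predict_proba(X[tr])[:, 1]
                cut, _, _ = youden_optimal_cutoff(proba_tr, y[tr])
                sens = float(np.mean(proba_te[y[te] == 1] > cut))
                spec = float(np.mean(proba_te[y[te] == 0] <= cut))
            else:
                cut, sens, spec = youden_optimal_cutoff(proba_te, y[te])
            results[name]["auc"].append(auc)
            results[name]["sens"].append(sens)
            results[name]["spec"].append(spec)
            results[name]["cutoff"].append(cut)
    rows = []
    for name in names:
        auc, auc_lo, auc_hi = _interval(np.array(results[name]["auc"]))
        sens, sens_lo, sens_hi = _interval(np.array(results[name]["sens"]))
        spec, spec_lo, spec_hi = _interval(np.array(results[name]["spec"]))
        rows.append(
            BenchmarkRow(
                model=name,
                auc=auc, auc_lo=auc_lo, auc_hi=auc_hi,
                sens=sens, sens_lo=sens_lo, sens_hi=sens_hi,
                spec=spec, spec_lo=spec_lo, spec_hi=spec_hi,
                youden=sens + spec - 1,
                cutoff=float(np.mean(results[name]["cutoff"])),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
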