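"""Feature engineering: smoking discretisation, encodings, multiple imputation.

Questionnaire responses become model features in one of two layouts:

* ``ordinal`` — one integer column per item (tree models, and the layout the
  item-importance ranking operates on, one attribution per question);
* ``onehot`` — one indicator column per choice named ``{item}_{choiceIndex}``
  including the baseline, so each item block has exactly one active column
  (linear models).

Smoking exposure is discretised into four severity bands: never-smoker, then
<200, [200, 400) and >=400 cigarettes per year (equivalently <10, [10, 20)
and >=20 packs/year at 20 cigarettes per pack).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort, attach_pack_years
from .schema import QuestionnaireSchema

__all__ = [
    "CIGARETTES_PER_PACK",
    "FeatureMatrix",
    "discretise_smoking",
    "encode",
    "decode",
    "impute_missing",
    "MissingDataError",
]

CIGARETTES_PER_PACK = 20


class MissingDataError(ValueError):
    """Raised when an operation that requires complete data meets a missing value."""


def discretise_smoking(
    smoker: bool, cigarettes_per_year: float, packs: bool = False
) -> int:
    """Map smoking exposure to the four-band smoking-amount category.

    Never-smokers are band 0 regardless of the numeric value.  Smokers fall
    in band 1 below 200 cigarettes/year, band 2 in [200, 400) and band 3 at
    >=400; bands are closed on the left.  With ``packs=True`` the numeric
    input is packs/year and is converted at 20 cigarettes per pack.
    """
    if cigarettes_per_year < 0:
        raise ValueError(f"negative smoking amount: {cigarettes_per_year}")
    if not smoker:
        return 0
    cigs = cigarettes_per_year * CIGARETTES_PER_PACK if packs else cigarettes_per_year
    if cigs < 200:
        return 1
    if cigs < 400:
        return 2
    return 3


@dataclass
class FeatureMatrix:
    """Subjects-by-features design matrix with aligned labels."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = case
    mode: str  # "onehot" | "ordinal"
    schema: QuestionnaireSchema

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("feature matrix and labels are misaligned")


def encode(cohort: Cohort, mode: str = "ordinal") -> FeatureMatrix:
    """Encode questionnaire responses as a design matrix.

    Column order is deterministic: schema order, then choice index within an
    item block for one-hot.  Missing responses are rejected; run
    :func:`impute_missing` first.
    """
    if mode not in ("ordinal", "onehot"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    resp = cohort.responses
    if resp.isna().any().any():
        bad = [c for c in resp.columns if resp[c].isna().any()]
        raise MissingDataError(
            f"missing responses in {bad}; impute first (preprocessing.impute_missing)"
        )
    y = cohort.labels.astype(int)
    if mode == "ordinal":
        X = resp.astype(int)
        return FeatureMatrix(X, y, mode, cohort.schema)
    cols = {}
    for it in cohort.schema:
        codes = resp[it.id].to_numpy(dtype=int)
        for i in range(it.n_choices):
            cols[f"{it.id}_{i}"] = (codes == i).astype(int)
    return FeatureMatrix(pd.DataFrame(cols), y, mode, cohort.schema)


def decode(fm: FeatureMatrix) -> pd.DataFrame:
    """Invert :func:`encode`, recovering the response codes per item."""
    if fm.mode == "ordinal":
        return fm.X.copy()
    out = {}
    for it in fm.schema:
        block = fm.X[[f"{it.id}_{i}" for i in range(it.n_choices)]].to_numpy()
        if not (block.sum(axis=1) == 1).all():
            raise ValueError(f"item {it.id!r}: one-hot block does not have exactly one active column")
        out[it.id] = block.argmax(axis=1)
    return pd.DataFrame(out)


def _mice_items(
    df: pd.DataFrame, schema: QuestionnaireSchema, rng: np.random.Generator, n_iter: int = 4
) -> pd.DataFrame:
    """One stochastic chained-equations completion of the item columns.

    Each missing entry is initialised from its observed class-conditional
    marginal, then iteratively redrawn from a multinomial-logistic model of
    the item given the other items (one-hot) and the label.
    """
    item_ids = [it.id for it in schema]
    work = df[item_ids].copy()
    is_case = (df["label"] == "case").to_numpy()
    miss = {i: work[i].isna().to_numpy() for i in item_ids}
    for it in schema:
        m = miss[it.id]
        if m.all():
            raise ValueError(f"item {it.id!r} is missing for every subject; conditional inestimable")
        if not m.any():
            continue
        obs = work[it.id].dropna().to_numpy(dtype=int)
        for cls_mask in (is_case, ~is_case):
            cm = m & cls_mask
            if not cm.any():
                continue
            cls_obs = work[it.id][~m & cls_mask]
            pool = cls_obs.to_numpy(dtype=int) if len(cls_obs) else obs
            counts = np.bincount(pool, minlength=it.n_choices).astype(float)
            work.loc[cm, it.id] = rng.choice(it.n_choices, size=int(cm.sum()), p=counts / counts.sum())
    work = work.astype(int)

    needs_model = [it for it in schema if miss[it.id].any()]
    for _ in range(n_iter):
        for it in needs_model:
            m = miss[it.id]
            others = [j for j in item_ids if j != it.id]
            X_parts = [pd.get_dummies(work[j], prefix=j) for j in others]
            X = pd.concat(X_parts, axis=1).to_numpy(dtype=float)
            X = np.column_stack([X, is_case.astype(float)])
            y = work[it.id].to_numpy()
            if len(np.unique(y[~m])) < 2:
                continue  # observed part is constant; keep marginal draws
            model = LogisticRegression(max_iter=300, C=1.0)
            model.fit(X[~m], y[~m])
            proba = model.predict_proba(X[m])
            cum = proba.cumsum(axis=1)
            u = rng.random(len(proba))[:, None]
            draws = (u > cum).sum(axis=1)
            work.loc[m, it.id] = model.classes_[draws]
    return work


def impute_missing(cohort: Cohort, m: int = 5, seed: int = 0) -> list[Cohort]:
    """Multiple imputation: return ``m`` stochastically completed cohort copies.

    Item responses are completed by chained equations (multinomial logistic
    conditionals given the other items and the label).  Pack-years and the
    smoker flag are then re-derived from the (possibly imputed) smoking band;
    missing spirometry stays missing (it is never a model feature).
    With no missing values the copies equal the input.
    """
    if "label" not in cohort.data.columns or cohort.data["label"].isna().any():
        raise ValueError("every subject must retain a label")
    completed: list[Cohort] = []
    base_rng = np.random.default_rng(seed)
    any_missing = cohort.responses.isna().any().any()
    py_missing = "pack_years" in cohort.data.columns and cohort.data["pack_years"].isna().any()
    for copy_idx in range(m):
        out = cohort.copy()
        sub_seed = int(base_rng.integers(0, 2**31 - 1))
        if any_missing:
            filled = _mice_items(out.data, out.schema, np.random.default_rng(sub_seed))
            for col in filled.columns:
                out.data[col] = pd.array(filled[col].to_numpy(), dtype="Int64")
        else:
            for col in cohort.item_columns:
                out.data[col] = out.data[col].astype("Int64")
        if py_missing:
            # redraw only the missing pack-year values; the smoker flag is
            # derived from the (now complete) smoking band either way
            observed = cohort.data["pack_years"].notna().to_numpy()
            kept = cohort.data.loc[observed, "pack_years"].astype(float)
            out = attach_pack_years(out, seed=sub_seed)
            out.data.loc[observed, "pack_years"] = kept
        out.provenance["imputation_copy"] = copy_idx
        out.provenance["imputation_seed"] = sub_seed
        completed.append(out)
    return completed
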