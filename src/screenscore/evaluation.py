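"""Conventional screening metrics and descriptive cohort summaries.

Covers the trapezoidal ROC AUC (equal to the tie-corrected concordance
probability), Youden's index, side-by-side comparison of two instruments'
threshold sweeps, and a class-stratified descriptive table with chi-square /
Fisher tests for categorical items and a Wilcoxon rank-sum test for
pack-years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort import Cohort
from .search import ScreeningTable, _as_case_mask

__all__ = ["MetricResult", "roc_auc", "youden", "compare_instruments", "cohort_summary"]


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    lower: float | None = None
    upper: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not (self.lower <= self.value <= self.upper):
                raise ValueError(
                    f"{self.name}: point {self.value} outside [{self.lower}, {self.upper}]"
                )


def roc_auc(scores, labels) -> MetricResult:
    """Trapezoidal area under the ROC curve.

    Equals the concordance probability P(score_case > score_control) with
    ties counted half.
    """
    is_case = _as_case_mask(labels)
    if is_case.all() or not is_case.any():
        raise ValueError("both classes required for ROC AUC")
    return MetricResult("roc_auc", float(roc_auc_score(is_case, scores)), method="trapezoidal")


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return sensitivity + specificity - 1


def compare_instruments(
    table_a: ScreeningTable,
    table_b: ScreeningTable,
    names: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Align two per-threshold sweeps on threshold and flag each instrument's best row.

    Grids may differ; unmatched thresholds produce NaN cells for the absent
    instrument.  Columns are suffixed with the instrument names; boolean
    ``best_<name>`` columns mark the row maximizing that instrument's
    balanced index.
    """
    a = table_a.frame.add_suffix(f"_{names[0]}").rename(
        columns={f"threshold_{names[0]}": "threshold"}
    )
    b = table_b.frame.add_suffix(f"_{names[1]}").rename(
        columns={f"threshold_{names[1]}": "threshold"}
    )
    merged = a.merge(b, on="threshold", how="outer").sort_values("threshold")
    merged = merged.reset_index(drop=True)
    for name in names:
        col = f"balanced_index_{name}"
        best = merged[col].to_numpy()
        flag = np.zeros(len(merged), dtype=bool)
        if np.isfinite(np.nanmax(best)):
            flag[int(np.nanargmax(best))] = True
        merged[f"best_{name}"] = flag
    return merged


def _categorical_test(case_counts: np.ndarray, ctrl_counts: np.ndarray) -> tuple[str, float, float]:
    """Chi-square test, or Fisher's exact for 2x2 tables with a small expected cell."""
    table = np.vstack([case_counts, ctrl_counts])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return "none", np.nan, 1.0
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected <= 5).any():
        _, p = stats.fisher_exact(table)
        return "fisher", np.nan, float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi2", float(chi2), float(p)


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Descriptive class-stratified table: per-item counts (%) with a chi-square
    (or Fisher) p-value, plus a pack-years row with median (IQR) and a
    Wilcoxon rank-sum p-value."""
    is_case = cohort.labels
    if is_case.all() or not is_case.any():
        raise ValueError("both classes required for a cohort summary")
    rows = []
    for it in cohort.schema:
        resp = cohort.data[it.id].to_numpy(dtype=float)
        ok = ~np.isnan(resp)
        codes = resp[ok].astype(int)
        cls = is_case[ok]
        case_counts = np.bincount(codes[cls], minlength=it.n_choices)
        ctrl_counts = np.bincount(codes[~cls], minlength=it.n_choices)
        test, statistic, p = _categorical_test(case_counts, ctrl_counts)
        for i, choice in enumerate(it.choices):
            rows.append(
                {
                    "variable": it.id,
                    "level": choice,
                    "case": f"{case_counts[i]} ({100 * case_counts[i] / max(cls.sum(), 1):.1f})",
                    "control": f"{ctrl_counts[i]} ({100 * ctrl_counts[i] / max((~cls).sum(), 1):.1f})",
                    "test": test if i == 0 else "",
                    "statistic": statistic if i == 0 else np.nan,
                    "p_value": p if i == 0 else np.nan,
                }
            )
    if "pack_years" in cohort.data.columns:
        py = cohort.data["pack_years"].to_numpy(dtype=float)
        ok = ~np.isnan(py)
        case_py, ctrl_py = py[ok & is_case], py[ok & ~is_case]
        stat, p = stats.mannwhitneyu(case_py, ctrl_py, alternative="two-sided")

        def fmt(v: np.ndarray) -> str:
            q1, md, q3 = np.percentile(v, [25, 50, 75])
            return f"{md:.1f} ({q1:.1f}-{q3:.1f})"

        rows.append(
            {
                "variable": "pack_years",
                "level": "median (IQR)",
                "case": fmt(case_py),
                "control": fmt(ctrl_py),
                "test": "wilcoxon_rank_sum",
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
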