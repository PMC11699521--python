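"""Test-retest reliability and discriminant validity against spirometry.

Reliability is computed on total scores of the entry and retest
administrations: the Pearson product-moment correlation and the intraclass
correlation coefficient.  The ICC variant is fixed to the two-way
random-effects, absolute-agreement, single-measure coefficient (ICC(2,1) in
the Shrout-Fleiss nomenclature), estimated from the standard two-way ANOVA
mean squares; the variant is recorded in the report metadata.

Discriminant validity correlates the total score with FEV1 (litres), FEV1
percent predicted, and the FEV1/FVC ratio; for a valid severity score all
three correlations are negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .schema import ScoringScheme
from .search import score_subjects

__all__ = [
    "ReliabilityReport",
    "pearson_r",
    "icc_absolute_agreement",
    "discriminant_validity",
    "reliability_report",
]


def pearson_r(x, y) -> float:
    """Standard product-moment correlation; rejects degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def icc_absolute_agreement(entry_scores, retest_scores) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    From the two-way ANOVA decomposition with n subjects and k=2 occasions:

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    where MS_R, MS_C, MS_E are the subject, occasion and residual mean
    squares.  Unlike the Pearson correlation, a systematic shift between
    occasions lowers this coefficient (absolute agreement, not consistency).
    """
    x = np.asarray(entry_scores, dtype=float)
    y = np.asarray(retest_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired score vectors required")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    occ_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_occ = n * np.sum((occ_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_occ
    ms_r = ss_subj / (n - 1)
    ms_c = ss_occ / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
    if denom <= 0:
        raise ValueError("ICC undefined: no variance between subjects or occasions")
    return float((ms_r - ms_e) / denom)


@dataclass
class ReliabilityReport:
    n: int
    pearson: float
    icc: float
    per_item_agreement: dict[str, float]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"measure": "pearson_r_total", "value": self.pearson},
            {"measure": "icc_2_1_absolute_agreement", "value": self.icc},
        ]
        rows += [
            {"measure": f"agreement_{item}", "value": v}
            for item, v in self.per_item_agreement.items()
        ]
        return pd.DataFrame(rows)


def reliability_report(
    cohort: Cohort, scheme: ScoringScheme, subsample: int | None = None, seed: int = 0
) -> ReliabilityReport:
    """Test-retest reliability of total scores (optionally on a random subsample).

    Requires retest responses (see ``cohort.make_retest``).  Reliability is
    reported on total scores; per-item raw agreement fractions are
    supplementary.
    """
    retest_cols = [f"retest_{it.id}" for it in cohort.schema]
    missing = [c for c in retest_cols if c not in cohort.data.columns]
    if missing:
        raise ValueError(f"cohort has no retest responses ({missing[0]} absent)")
    needed = [it.id for it in cohort.schema] + retest_cols
    complete = cohort.data[needed].notna().all(axis=1)
    if not complete.all():
        # reliability is a complete-case analysis of the paired administrations
        cohort = Cohort(
            cohort.schema, cohort.data[complete].reset_index(drop=True), dict(cohort.provenance)
        )
    work = cohort
    if subsample is not None and subsample < len(cohort):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(cohort), size=subsample, replace=False))
        work = Cohort(cohort.schema, cohort.data.iloc[idx].reset_index(drop=True))
    entry_total = score_subjects(scheme, work)
    retest_data = work.data.copy()
    for it in work.schema:
        retest_data[it.id] = retest_data[f"retest_{it.id}"]
    retest_cohort = Cohort(work.schema, retest_data)
    retest_total = score_subjects(scheme, retest_cohort)
    agreement = {
        it.id: float(
            (work.data[it.id].to_numpy() == work.data[f"retest_{it.id}"].to_numpy()).mean()
        )
        for it in work.schema
    }
    return ReliabilityReport(
        n=len(work),
        pearson=pearson_r(entry_total, retest_total),
        icc=icc_absolute_agreement(entry_total, retest_total),
        per_item_agreement=agreement,
        metadata={"icc_variant": "two-way random, absolute agreement, single measure"},
    )


def discriminant_validity(cohort: Cohort, scheme: ScoringScheme) -> pd.DataFrame:
    """Pearson correlations of total score with FEV1, FEV1%pred and FEV1/FVC.

    Returns one row per spirometric measure with ``r`` and the two-sided
    p-value.  All subjects must carry spirometry.
    """
    for col in ("fev1", "fev1pp", "fev1_fvc"):
        if col not in cohort.data.columns:
            raise ValueError(f"cohort lacks spirometry column {col!r}")
        if cohort.data[col].isna().any():
            bad = cohort.data.loc[cohort.data[col].isna(), "subject_id"].tolist()
            raise ValueError(f"spirometry missing for subjects {bad[:5]}{'...' if len(bad) > 5 else ''}")
    totals = score_subjects(scheme, cohort)
    if np.std(totals) == 0:
        raise ValueError("correlation undefined: total score is constant")
    rows = []
    for col in ("fev1", "fev1pp", "fev1_fvc"):
        res = stats.pearsonr(totals, cohort.data[col].to_numpy(dtype=float))
        rows.append({"measure": col, "r": float(res.statistic), "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)
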