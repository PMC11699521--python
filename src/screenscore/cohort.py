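"""Synthetic cohort generation with the statistical structure the analysis assumes.

A cohort is a table of subjects: nine categorical questionnaire responses
(0-based codes in severity order), continuous smoking exposure (pack-years),
optional spirometry, a case/control label defined by the spirometric rule
FEV1/FVC < 0.70, and an optional two-week retest copy of the responses.

Responses are drawn class-conditionally from a :class:`ClassConditionalTable`
(the packaged development-cohort marginals by default).  With
``dependence = 0`` items are independent given the class; a positive
``dependence`` couples them through a shared Gaussian-copula latent severity
while preserving every marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import ClassConditionalTable, QuestionnaireSchema, SchemaError

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "sample_cohort",
    "attach_pack_years",
    "attach_spirometry",
    "make_retest",
    "apply_mcar_mask",
    "read_cohort_csv",
    "DIAGNOSTIC_RATIO_CUTOFF",
]

DIAGNOSTIC_RATIO_CUTOFF = 0.70

#: pack-year band edges matching the smoking-amount item: 0 / (0,10) / [10,20) / >=20
PACK_YEAR_EDGES = (0.0, 10.0, 20.0)
#: within-band log-normal medians and log-sd for continuous pack-years per band 1..3
_BAND_LOGNORM = {1: (5.0, 0.5), 2: (14.0, 0.15), 3: (35.0, 0.6)}
_BAND_RANGE = {1: (0.25, 10.0), 2: (10.0, 20.0), 3: (20.0, 365.0)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling parameters for a synthetic cohort.

    ``dependence`` in [0,1) is the Gaussian-copula correlation between the
    items' latent severities (0 = class-conditional independence).
    """

    n_case: int = 404
    n_control: int = 1420
    seed: int = 0
    dependence: float = 0.0
    retest_agreement: float = 0.9
    mcar_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_case < 0 or self.n_control < 0 or self.n_case + self.n_control == 0:
            raise ValueError("need a positive total number of subjects")
        if not 0 <= self.dependence < 1:
            raise ValueError("dependence must be in [0, 1)")
        if not 0 <= self.retest_agreement <= 1:
            raise ValueError("retest_agreement must be in [0, 1]")
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate must be in [0, 1)")


@dataclass
class Cohort:
    """A schema plus one row per subject, with generation provenance."""

    schema: QuestionnaireSchema
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("cohort is empty")
        for it in self.schema:
            col = self.data[it.id]
            bad = col.dropna() >= it.n_choices
            if bad.any():
                raise ValueError(f"item {it.id!r}: response code out of range")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def item_columns(self) -> list[str]:
        return [it.id for it in self.schema]

    @property
    def labels(self) -> np.ndarray:
        """Boolean case indicator per subject."""
        return (self.data["label"] == "case").to_numpy()

    @property
    def responses(self) -> pd.DataFrame:
        return self.data[self.item_columns]

    def copy(self) -> "Cohort":
        return Cohort(self.schema, self.data.copy(), dict(self.provenance))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def read_cohort_csv(path: str | Path, schema: QuestionnaireSchema) -> Cohort:
    df = pd.read_csv(path)
    for it in schema:
        if it.id not in df.columns:
            raise SchemaError(f"cohort file missing column {it.id!r}")
        df[it.id] = df[it.id].astype("Int64")
    for col in df.columns:
        if col.startswith("retest_"):
            df[col] = df[col].astype("Int64")
    return Cohort(schema, df, provenance={"source": str(path)})


def _copula_categorical(
    rng: np.random.Generator, probs: list[np.ndarray], n: int, rho: float
) -> np.ndarray:
    """Draw n subjects over len(probs) items with given marginals.

    rho = 0: independent draws.  rho > 0: a one-factor Gaussian copula
    (latent severity) whose uniform margins are inverted through each item's
    CDF, preserving the categorical marginals exactly.
    """
    q = len(probs)
    out = np.empty((n, q), dtype=np.int64)
    if rho == 0.0:
        for j, p in enumerate(probs):
            out[:, j] = rng.choice(len(p), size=n, p=p)
        return out
    shared = rng.standard_normal(n)
    for j, p in enumerate(probs):
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
        u = stats.norm.cdf(z)
        out[:, j] = np.searchsorted(np.cumsum(p), u, side="right")
        np.clip(out[:, j], 0, len(p) - 1, out=out[:, j])
    return out


def sample_cohort(dists: ClassConditionalTable, config: GeneratorConfig) -> Cohort:
    """Draw questionnaire responses class-conditionally from ``dists``.

    Reproducible given ``config.seed``; identical configs yield identical
    cohorts.  Pack-years, spirometry and retest responses are attached by the
    dedicated operations below.
    """
    schema = dists.schema
    for it in schema:
        if it.id not in dists.probs:
            raise SchemaError(f"distribution table missing item {it.id!r}")
    rng = np.random.default_rng(config.seed)
    blocks = []
    for cls, n in (("case", config.n_case), ("control", config.n_control)):
        if n == 0:
            continue
        probs = [dists.prob(it.id, cls) for it in schema]
        codes = _copula_categorical(rng, probs, n, config.dependence)
        block = pd.DataFrame(codes, columns=[it.id for it in schema])
        block["label"] = cls
        blocks.append(block)
    df = pd.concat(blocks, ignore_index=True)
    df.insert(0, "subject_id", [f"s{i:06d}" for i in range(len(df))])
    for it in schema:
        df[it.id] = df[it.id].astype("Int64")
    prov = {
        "seed": config.seed,
        "n_case": config.n_case,
        "n_control": config.n_control,
        "dependence": config.dependence,
    }
    return Cohort(schema, df, provenance=prov)


def _sample_band_pack_years(rng: np.random.Generator, band: int, size: int) -> np.ndarray:
    """Log-normal pack-years truncated to the band's range (rejection sampling)."""
    median, sigma = _BAND_LOGNORM[band]
    lo, hi = _BAND_RANGE[band]
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mean=np.log(median), sigma=sigma, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw < hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def attach_pack_years(cohort: Cohort, seed: int = 0) -> Cohort:
    """Draw continuous pack-years consistent with each subject's smoking band.

    Band 0 subjects are never-smokers (pack_years = 0, smoker = False); bands
    1-3 draw from band-truncated log-normals on (0,10), [10,20) and >=20
    packs/year, so re-discretising the continuous value recovers the band.
    """
    if "item2" not in cohort.data.columns:
        raise SchemaError("cohort has no smoking-amount item (item2)")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    band = out.data["item2"].to_numpy(dtype=float)
    if np.isnan(band).any():
        raise ValueError("smoking band missing for some subjects; impute first")
    band = band.astype(int)
    py = np.zeros(len(out.data))
    for b in (1, 2, 3):
        mask = band == b
        py[mask] = _sample_band_pack_years(rng, b, int(mask.sum()))
    out.data["pack_years"] = py
    out.data["smoker"] = band > 0
    out.provenance["pack_years_seed"] = seed
    return out


def attach_spirometry(
    cohort: Cohort,
    seed: int = 0,
    case_ratio_mean: float = 0.55,
    control_ratio_mean: float = 0.78,
    ratio_sd: float = 0.08,
) -> Cohort:
    """Sample spirometry consistent with the diagnostic rule.

    FEV1/FVC is drawn from a class-specific normal truncated to the correct
    side of the 0.70 cutoff (rejection of wrong-side draws), so
    ``label == case`` iff ``fev1_fvc < 0.70`` by construction.  FEV1 percent
    predicted decreases in (0.70 - ratio), giving the negative score/lung
    function correlations expected of a valid severity score.
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    n = len(out.data)
    is_case = out.labels
    ratio = np.empty(n)
    for cls_mask, mean, low, high in (
        (is_case, case_ratio_mean, 0.2, DIAGNOSTIC_RATIO_CUTOFF - 1e-9),
        (~is_case, control_ratio_mean, DIAGNOSTIC_RATIO_CUTOFF, 1.0),
    ):
        m = int(cls_mask.sum())
        vals = np.empty(m)
        filled = 0
        while filled < m:
            draw = rng.normal(mean, ratio_sd, size=2 * (m - filled) + 8)
            ok = draw[(draw >= low) & (draw < high)] if low < high else draw
            take = min(len(ok), m - filled)
            vals[filled : filled + take] = ok[:take]
            filled += take
        ratio[cls_mask] = vals
    deficit = np.clip(DIAGNOSTIC_RATIO_CUTOFF - ratio, 0, None)
    fev1pp = np.clip(98 - 160 * deficit + rng.normal(0, 8, n), 15, 140)
    predicted_fev1 = np.clip(rng.normal(3.0, 0.45, n), 1.2, None)  # litres
    out.data["fev1"] = fev1pp / 100.0 * predicted_fev1
    out.data["fev1pp"] = fev1pp
    out.data["fev1_fvc"] = ratio
    out.provenance["spirometry_seed"] = seed
    return out


def make_retest(cohort: Cohort, agreement: float, seed: int = 0) -> Cohort:
    """Attach a two-week retest copy of the responses.

    Each item independently repeats the entry response with probability
    ``agreement``; otherwise it is resampled from the subject's
    class-conditional item distribution (estimated from the cohort itself).
    """
    if not 0 <= agreement <= 1:
        raise ValueError("agreement must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    is_case = out.labels
    for it in out.schema:
        entry = out.data[it.id].to_numpy(dtype=int)
        retest = entry.copy()
        flip = rng.random(len(entry)) > agreement
        for cls_mask in (is_case, ~is_case):
            m = flip & cls_mask
            if not m.any():
                continue
            counts = np.bincount(entry[cls_mask], minlength=it.n_choices).astype(float)
            p = counts / counts.sum()
            retest[m] = rng.choice(it.n_choices, size=int(m.sum()), p=p)
        out.data[f"retest_{it.id}"] = pd.array(retest, dtype="Int64")
    out.provenance["retest_agreement"] = agreement
    out.provenance["retest_seed"] = seed
    return out


def apply_mcar_mask(cohort: Cohort, rate: float, seed: int = 0) -> Cohort:
    """Set each non-label field missing independently with probability ``rate``.

    The label, subject id and schema are never masked.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return cohort.copy()
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    protected = {"subject_id", "label"}
    for col in out.data.columns:
        if col in protected:
            continue
        mask = rng.random(len(out.data)) < rate
        if out.data[col].dtype == bool:
            out.data[col] = out.data[col].astype(object)
        out.data.loc[mask, col] = pd.NA
    out.provenance["mcar_rate"] = rate
    return out
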