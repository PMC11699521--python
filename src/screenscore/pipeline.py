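"""End-to-end pipeline: simulate -> preprocess -> rank -> search -> evaluate.

A single :class:`RunConfig` drives every stage; every run writes its resolved
configuration, a stage log, and one artifact per stage into the output
directory, so a rerun with the same configuration is reproducible
stage-for-stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .benchmark import run_benchmark
from .cohort import (
    GeneratorConfig,
    apply_mcar_mask,
    attach_pack_years,
    attach_spirometry,
    make_retest,
    sample_cohort,
)
from .evaluation import cohort_summary
from .preprocessing import impute_missing
from .ranking import rank_items
from .reliability import discriminant_validity, reliability_report
from .schema import load_schema, table2_distributions
from .search import (
    DEFAULT_TIER_RULE,
    SearchSpace,
    assign_caps,
    count_schemes,
    grid_search,
    score_subjects,
    screening_table,
)

log = logging.getLogger("screenscore")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    n_case: int = 404
    n_control: int = 1420
    dependence: float = 0.0
    retest_agreement: float = 0.9
    mcar_rate: float = 0.0
    imputations: int = 5
    cv_folds: int = 5
    step: float = 0.5
    zero_allowed: bool = True
    strategy: str = "beam"
    beam_width: int = 128
    budget: int = 10**8
    reliability_subsample: int = 96
    benchmark_repeats: int = 10
    benchmark_tune: bool = False
    benchmark_models: list[str] | None = None
    outdir: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, writing one artifact per stage into ``config.outdir``.

    Returns the run directory.  Any stage failure aborts with the stage name;
    artifacts of completed stages persist.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yml")
    (outdir / "provenance.json").write_text(
        json.dumps({"config_digest": config.digest(), "package_version": __version__}, indent=2)
    )
    stage = "simulate"
    t0 = time.time()
    try:
        schema = load_schema("copd_eq_v1")
        dists = table2_distributions(schema)
        gen = GeneratorConfig(
            n_case=config.n_case,
            n_control=config.n_control,
            seed=config.seed,
            dependence=config.dependence,
            retest_agreement=config.retest_agreement,
            mcar_rate=config.mcar_rate,
        )
        cohort = sample_cohort(dists, gen)
        cohort = attach_pack_years(cohort, seed=config.seed + 1)
        cohort = attach_spirometry(cohort, seed=config.seed + 2)
        cohort = make_retest(cohort, agreement=config.retest_agreement, seed=config.seed + 3)
        if config.mcar_rate > 0:
            cohort = apply_mcar_mask(cohort, rate=config.mcar_rate, seed=config.seed + 4)
        cohort.to_csv(outdir / "cohort.csv")
        log.info("simulate: %d subjects (%.1fs)", len(cohort), time.time() - t0)

        stage = "preprocess"
        if cohort.responses.isna().any().any():
            completed = impute_missing(cohort, m=config.imputations, seed=config.seed + 5)
            cohort = completed[0]  # downstream stages consume the first completed copy
        cohort_summary(cohort).to_csv(outdir / "cohort_summary.csv", index=False)

        stage = "rank"
        report = rank_items(cohort, k=config.cv_folds, seed=config.seed + 6)
        report.to_csv(outdir / "importance.csv")
        final_rank = dict(zip(report.item_ids, (int(r) for r in report.final_rank)))
        log.info("rank: final ranks %s", final_rank)

        stage = "caps"
        caps = assign_caps(final_rank, DEFAULT_TIER_RULE)
        (outdir / "caps.json").write_text(json.dumps(caps.caps, indent=2))

        stage = "search"
        space = SearchSpace.from_caps(
            schema, caps, step=config.step, zero_allowed=config.zero_allowed
        )
        log.info("search: space holds %.4g schemes (strategy=%s)", count_schemes(space), config.strategy)
        result = grid_search(
            cohort,
            space,
            strategy=config.strategy,
            budget=config.budget,
            beam_width=config.beam_width,
        )
        result.scheme.to_json(outdir / "scheme.json")
        result.table.to_csv(outdir / "screening_table.csv")
        log.info(
            "search: best balanced index %.4f at threshold %.1f (%d schemes evaluated)",
            result.objective, result.threshold, result.n_evaluated,
        )

        stage = "reliability"
        rel = reliability_report(
            cohort, result.scheme, subsample=config.reliability_subsample, seed=config.seed + 7
        )
        rel.to_frame().to_csv(outdir / "reliability.csv", index=False)
        from .cohort import Cohort as _Cohort

        spiro_ok = cohort.data[["fev1", "fev1pp", "fev1_fvc"]].notna().all(axis=1)
        validity_cohort = (
            cohort
            if spiro_ok.all()
            else _Cohort(cohort.schema, cohort.data[spiro_ok].reset_index(drop=True))
        )
        discriminant_validity(validity_cohort, result.scheme).to_csv(
            outdir / "discriminant_validity.csv", index=False
        )

        stage = "benchmark"
        bench = run_benchmark(
            cohort,
            repeats=config.benchmark_repeats,
            seed=config.seed + 8,
            tune=config.benchmark_tune,
            models=config.benchmark_models,
        )
        bench.to_csv(outdir / "benchmark.csv", index=False)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    log.info("pipeline complete in %.1fs -> %s", time.time() - t0, outdir)
    return outdir
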