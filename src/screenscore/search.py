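"""Monotone scorecard search: tiered caps, enumeration, and grid search.

The scorecard assigns each response choice a score that is a non-negative
integer multiple of 0.5, zero for the baseline choice, weakly non-decreasing
along the severity order, and bounded by a per-item cap.  Caps come from the
item importance ranking through a tier rule: the top-two items are capped at
3 points, ranks 3-5 at 2, ranks 6-7 at 1, and the remaining items are
eliminated (cap 0, all-zero scores).

A candidate scorecard is judged by the best balanced screening index
(sensitivity + specificity)/2 it attains over the 0.5-spaced threshold grid
under the strict decision rule *screen positive iff total score > threshold*.
The grid search returns the scheme maximizing that objective; ties go to the
lexicographically smallest score vector, then to the smallest optimal
threshold.

Internally all scores are half-units (integers), so totals index directly
into threshold histograms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .schema import QuestionnaireSchema, ScoringScheme, SCORE_STEP

__all__ = [
    "DEFAULT_TIER_RULE",
    "CapAssignment",
    "SearchSpace",
    "ScreeningTable",
    "GridSearchResult",
    "SearchBudgetError",
    "assign_caps",
    "count_schemes",
    "enumerate_schemes",
    "score_subjects",
    "screening_table",
    "objective",
    "grid_search",
]

#: (lowest rank, highest rank or None for open-ended, cap in points)
DEFAULT_TIER_RULE: tuple[tuple[int, int | None, float], ...] = (
    (1, 2, 3.0),
    (3, 5, 2.0),
    (6, 7, 1.0),
    (8, None, 0.0),
)


class SearchBudgetError(RuntimeError):
    """Exhaustive enumeration would exceed the configured scheme budget."""


@dataclass(frozen=True)
class CapAssignment:
    """Per-item maximum score implied by the tier rule applied to final ranks."""

    caps: Mapping[str, float]
    tier_rule: tuple[tuple[int, int | None, float], ...] = DEFAULT_TIER_RULE

    def __getitem__(self, item_id: str) -> float:
        return self.caps[item_id]


def assign_caps(
    final_rank: Mapping[str, int],
    tier_rule: Sequence[tuple[int, int | None, float]] = DEFAULT_TIER_RULE,
) -> CapAssignment:
    """Map final importance ranks to per-item score caps via the tier rule."""
    q = len(final_rank)
    if sorted(final_rank.values()) != list(range(1, q + 1)):
        raise ValueError("final_rank must be a permutation of 1..Q")
    caps = {}
    for item_id, rank in final_rank.items():
        matches = [
            cap
            for lo, hi, cap in tier_rule
            if lo <= rank and (hi is None or rank <= hi)
        ]
        if len(matches) != 1:
            raise ValueError(
                f"tier rule does not uniquely cover rank {rank} (item {item_id!r})"
            )
        caps[item_id] = matches[0]
    return CapAssignment(caps=dict(caps), tier_rule=tuple(tuple(t) for t in tier_rule))


@dataclass(frozen=True)
class _ItemSpace:
    item_id: str
    n_choices: int
    cap_half: int  # cap in half-units
    values: tuple[int, ...]  # allowed half-unit values per non-baseline choice

    @property
    def m(self) -> int:
        return self.n_choices - 1

    def candidates(self) -> list[tuple[int, ...]]:
        """All weakly non-decreasing non-baseline score vectors, lexicographic."""
        if self.cap_half == 0:
            return [(0,) * self.m]
        return list(itertools.combinations_with_replacement(self.values, self.m))

    @property
    def n_candidates(self) -> int:
        if self.cap_half == 0:
            return 1
        return math.comb(len(self.values) + self.m - 1, self.m)


@dataclass(frozen=True)
class SearchSpace:
    """The constrained grid of admissible scorecards for a schema."""

    items: tuple[_ItemSpace, ...]
    step: float = SCORE_STEP
    zero_allowed: bool = True

    @classmethod
    def from_caps(
        cls,
        schema: QuestionnaireSchema,
        caps: CapAssignment | Mapping[str, float],
        step: float = SCORE_STEP,
        zero_allowed: bool = True,
    ) -> "SearchSpace":
        """Build the per-choice value grids {0 or step, ..., cap} for each item."""
        cap_map = caps.caps if isinstance(caps, CapAssignment) else caps
        items = []
        for it in schema:
            cap = cap_map.get(it.id, 0.0)
            cap_half = int(round(cap / step))
            if abs(cap / step - cap_half) > 1e-9:
                raise ValueError(f"cap {cap} for {it.id!r} is not a multiple of step {step}")
            lo = 0 if zero_allowed else 1
            values = tuple(range(lo, cap_half + 1)) if cap_half > 0 else ()
            items.append(_ItemSpace(it.id, it.n_choices, cap_half, values))
        return cls(tuple(items), step=step, zero_allowed=zero_allowed)

    @property
    def max_total_half(self) -> int:
        return sum(sp.cap_half for sp in self.items)


def count_schemes(space: SearchSpace) -> int:
    """Closed-form size of the search space.

    Per item with m non-baseline choices and v allowed values, the number of
    weakly non-decreasing score vectors is the multiset count C(v + m - 1, m);
    the space size is the product over items (cap-0 items contribute 1).
    """
    n = 1
    for sp in space.items:
        n *= sp.n_candidates
    return n


def enumerate_schemes(space: SearchSpace) -> Iterator[ScoringScheme]:
    """Yield every admissible scorecard exactly once, in lexicographic order."""
    per_item = [sp.candidates() for sp in space.items]
    ids = [sp.item_id for sp in space.items]
    for combo in itertools.product(*per_item):
        scores = {
            i: (0.0,) + tuple(v * space.step for v in vec) for i, vec in zip(ids, combo)
        }
        yield ScoringScheme(scores=scores, step=space.step)


def score_subjects(scheme: ScoringScheme, cohort: Cohort) -> np.ndarray:
    """Total additive score per subject under ``scheme``."""
    totals = np.zeros(len(cohort))
    for item_id in scheme.item_ids:
        if item_id not in cohort.data.columns:
            raise KeyError(f"cohort has no responses for {item_id!r}")
        resp = cohort.data[item_id].to_numpy(dtype=float)
        if np.isnan(resp).any():
            raise ValueError(f"item {item_id!r}: missing responses; impute first")
        vec = np.asarray(scheme[item_id])
        codes = resp.astype(int)
        if codes.max() >= len(vec):
            raise ValueError(
                f"item {item_id!r}: response code {codes.max()} outside score vector"
            )
        totals += vec[codes]
    return totals


def _as_case_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels
    if labels.dtype.kind in "iuf":
        return labels.astype(bool)
    return labels == "case"


@dataclass
class ScreeningTable:
    """Per-threshold screening performance under the strict (>) decision rule."""

    frame: pd.DataFrame  # columns: threshold, sensitivity, specificity, balanced_index, youden

    def best_row(self) -> pd.Series:
        """Row maximizing the balanced index (smallest threshold on ties)."""
        idx = int(self.frame["balanced_index"].to_numpy().argmax())
        return self.frame.iloc[idx]

    def to_csv(self, path, percent: bool = False) -> None:
        df = self.frame.copy()
        if percent:
            for c in ("sensitivity", "specificity", "balanced_index", "youden"):
                df[c] = (100 * df[c]).round(2)
        else:
            for c in ("sensitivity", "specificity", "balanced_index", "youden"):
                df[c] = df[c].round(4)
        df.to_csv(path, index=False)


def screening_table(
    scores,
    labels,
    thresholds: Sequence[float] | None = None,
    step: float = SCORE_STEP,
) -> ScreeningTable:
    """Sweep thresholds and tabulate sensitivity, specificity, balanced index, Youden.

    A subject screens positive iff score > threshold (strict).  The default
    grid runs from 0 to the maximum score in ``step`` increments.
    """
    scores = np.asarray(scores, dtype=float)
    is_case = _as_case_mask(labels)
    n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
    if n_case == 0:
        raise ValueError("no case subjects in input")
    if n_ctrl == 0:
        raise ValueError("no control subjects in input")
    if thresholds is None:
        top = max(scores.max(), 0.0)
        thresholds = np.arange(0.0, np.floor(top / step) * step + step / 2, step)
        if len(thresholds) == 0:
            thresholds = np.array([0.0])
    thresholds = np.asarray(thresholds, dtype=float)
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    case_scores = scores[is_case]
    ctrl_scores = scores[~is_case]
    for i, t in enumerate(thresholds):
        sens[i] = np.mean(case_scores > t)
        spec[i] = np.mean(ctrl_scores <= t)
    frame = pd.DataFrame(
        {
            "threshold": thresholds,
            "sensitivity": sens,
            "specificity": spec,
            "balanced_index": (sens + spec) / 2,
            "youden": sens + spec - 1,
        }
    )
    return ScreeningTable(frame)


def objective(scheme: ScoringScheme, cohort: Cohort) -> tuple[float, float]:
    """Best balanced index over the threshold grid, with its (smallest) argmax threshold."""
    scores = score_subjects(scheme, cohort)
    table = screening_table(scores, cohort.labels, step=scheme.step)
    best = table.best_row()
    return float(best["balanced_index"]), float(best["threshold"])


# ---------------------------------------------------------------------------
# grid search engine (half-unit integer arithmetic over collapsed patterns)
# ---------------------------------------------------------------------------


@dataclass
class GridSearchResult:
    scheme: ScoringScheme
    objective: float
    threshold: float
    table: ScreeningTable
    reduced_schema: QuestionnaireSchema
    strategy: str
    n_evaluated: int
    space_size: int
    metadata: dict = field(default_factory=dict)


class _Engine:
    """Shared state for the exhaustive / branch-and-bound / beam strategies."""

    def __init__(self, cohort: Cohort, space: SearchSpace):
        self.space = space
        self.step = space.step
        ids = [sp.item_id for sp in space.items]
        resp = cohort.data[ids].to_numpy(dtype=float)
        if np.isnan(resp).any():
            raise ValueError("missing responses; impute first")
        resp = resp.astype(np.int64)
        is_case = _as_case_mask(cohort.labels)
        # collapse duplicate response patterns into weighted rows
        patterns, inverse = np.unique(resp, axis=0, return_inverse=True)
        p = len(patterns)
        self.case_w = np.bincount(inverse[is_case], minlength=p).astype(float)
        self.ctrl_w = np.bincount(inverse[~is_case], minlength=p).astype(float)
        if self.case_w.sum() == 0:
            raise ValueError("no case subjects in input")
        if self.ctrl_w.sum() == 0:
            raise ValueError("no control subjects in input")
        self.n_case = self.case_w.sum()
        self.n_ctrl = self.ctrl_w.sum()
        self.patterns = patterns
        self.L = space.max_total_half + 1  # histogram length (totals 0..max)
        # per item: candidate list and per-candidate additions for each pattern
        self.cands: list[list[tuple[int, ...]]] = []
        self.adds: list[np.ndarray] = []  # (n_cands, p) int
        for j, sp in enumerate(space.items):
            cands = sp.candidates()
            lut = np.array([(0,) + c for c in cands], dtype=np.int64)  # (n_cands, n_choices)
            self.cands.append(cands)
            self.adds.append(lut[:, patterns[:, j]])
        # suffix min/max achievable additions per pattern for bounding
        q = len(space.items)
        self.max_suffix = np.zeros((q + 1, p), dtype=np.int64)
        self.min_suffix = np.zeros((q + 1, p), dtype=np.int64)
        for j in range(q - 1, -1, -1):
            self.max_suffix[j] = self.max_suffix[j + 1] + self.adds[j].max(axis=0)
            self.min_suffix[j] = self.min_suffix[j + 1] + self.adds[j].min(axis=0)
        self.n_evaluated = 0

    def _balanced_rows(self, hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
        """Balanced-index curves for a batch of total vectors.

        ``hi`` feeds the sensitivity term and ``lo`` the specificity term
        (they coincide for exact evaluation and differ for bounding); both
        are (batch, p) integer arrays.  Returns (batch, L) curves over the
        half-unit threshold grid.  A single offset bincount histograms the
        whole batch at once.
        """
        b = hi.shape[0]
        offs = np.arange(b, dtype=np.int64)[:, None] * self.L
        case_hist = np.bincount(
            (hi + offs).ravel(), weights=np.tile(self.case_w, b), minlength=b * self.L
        ).reshape(b, self.L)
        ctrl_hist = np.bincount(
            (lo + offs).ravel(), weights=np.tile(self.ctrl_w, b), minlength=b * self.L
        ).reshape(b, self.L)
        case_cum = np.cumsum(case_hist, axis=1)
        ctrl_cum = np.cumsum(ctrl_hist, axis=1)
        return (1 - case_cum / self.n_case + ctrl_cum / self.n_ctrl) / 2

    def evaluate_batch(self, totals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Best balanced index and its (smallest) argmax threshold per row."""
        self.n_evaluated += totals.shape[0]
        bal = self._balanced_rows(totals, totals)
        t = bal.argmax(axis=1)
        return bal[np.arange(len(t)), t], t

    def evaluate(self, totals: np.ndarray) -> tuple[float, int]:
        obj, t = self.evaluate_batch(totals[None, :])
        return float(obj[0]), int(t[0])

    def bound_batch(self, depth: int, totals: np.ndarray) -> np.ndarray:
        """Admissible upper bound on the objective for any completion of each prefix.

        Sensitivity can at best count cases given their maximal remaining
        additions; specificity at best counts controls given their minimal
        remaining additions.  Both relaxations are per-class independent, so
        the maximum over thresholds of their average bounds every descendant.
        """
        hi = np.minimum(totals + self.max_suffix[depth], self.L - 1)
        lo = totals + self.min_suffix[depth]
        return self._balanced_rows(hi, lo).max(axis=1)

    def bound(self, depth: int, totals: np.ndarray) -> float:
        return float(self.bound_batch(depth, totals[None, :])[0])

    def scheme_from(self, combo: Sequence[tuple[int, ...]]) -> ScoringScheme:
        scores = {
            sp.item_id: (0.0,) + tuple(v * self.step for v in vec)
            for sp, vec in zip(self.space.items, combo)
        }
        return ScoringScheme(scores=scores, step=self.step)


def _search_dfs(
    engine: _Engine, prune: bool, seed_objective: float | None = None
) -> tuple[float, int, list]:
    """Depth-first search in lexicographic order; first strict improvement wins,
    so the incumbent is always the lexicographically smallest optimum.

    ``seed_objective`` (e.g. from a beam pass) primes the branch-and-bound
    incumbent value slightly below itself, so subtrees that cannot reach it
    are pruned while every scheme attaining it is still visited in order.
    """
    q = len(engine.space.items)
    floor = (seed_objective - 1e-9) if seed_objective is not None else -1.0
    best = [floor, engine.L, None]  # objective, threshold, combo

    def recurse(depth: int, totals: np.ndarray, prefix: list):
        cands = engine.cands[depth]
        child_totals = totals[None, :] + engine.adds[depth]
        if depth == q - 1:
            objs, ts = engine.evaluate_batch(child_totals)
            for ci in range(len(cands)):
                if objs[ci] > best[0] + 1e-12:
                    best[0], best[1], best[2] = float(objs[ci]), int(ts[ci]), prefix + [cands[ci]]
            return
        bounds = engine.bound_batch(depth + 1, child_totals) if prune else None
        for ci, cand in enumerate(cands):
            if prune and bounds[ci] <= best[0] + 1e-12:
                continue
            prefix.append(cand)
            recurse(depth + 1, child_totals[ci], prefix)
            prefix.pop()

    recurse(0, np.zeros(len(engine.patterns), dtype=np.int64), [])
    if best[2] is None:
        # seed floor was never strictly beaten (can only happen with a seed);
        # fall back to an unseeded exact pass
        return _search_dfs(engine, prune=prune)
    return best[0], best[1], best[2]


def _search_beam(engine: _Engine, width: int) -> tuple[float, int, list]:
    """Approximate beam search: keep the ``width`` best prefixes by admissible bound."""
    beams: list[tuple[np.ndarray, tuple]] = [
        (np.zeros(len(engine.patterns), dtype=np.int64), ())
    ]
    q = len(engine.space.items)
    for depth in range(q):
        expanded = []
        for totals, prefix in beams:
            adds = engine.adds[depth]
            for ci, cand in enumerate(engine.cands[depth]):
                expanded.append((totals + adds[ci], prefix + (cand,)))
        if depth < q - 1 and len(expanded) > width:
            scored = [
                (engine.bound(depth + 1, t), -i) for i, (t, _) in enumerate(expanded)
            ]
            order = sorted(range(len(expanded)), key=lambda i: scored[i], reverse=True)
            expanded = [expanded[i] for i in order[:width]]
        beams = expanded
    best = (-1.0, engine.L, None)
    for totals, prefix in beams:
        obj, t = engine.evaluate(totals)
        if obj > best[0] + 1e-12 or (
            abs(obj - best[0]) <= 1e-12 and best[2] is not None and list(prefix) < best[2]
        ):
            best = (obj, t, list(prefix))
    return best


def grid_search(
    cohort: Cohort,
    space: SearchSpace,
    strategy: str = "exhaustive",
    budget: int = 10**8,
    beam_width: int = 128,
) -> GridSearchResult:
    """Search the constrained scorecard space for the best balanced screening index.

    Strategies: ``exhaustive`` visits every scheme (refused above ``budget``);
    ``pruned`` is branch-and-bound with an admissible per-class bound and
    returns the same argmax; ``beam`` is an approximate beam search of the
    given width.  Ties are broken by the lexicographically smallest score
    vector, then by the smallest optimal threshold.
    """
    size = count_schemes(space)
    if strategy == "exhaustive" and size > budget:
        raise SearchBudgetError(
            f"space holds {size:.3g} schemes (> budget {budget:.3g}); "
            "use strategy='pruned' or 'beam'"
        )
    engine = _Engine(cohort, space)
    if strategy in ("exhaustive", "pruned"):
        seed_obj = None
        if strategy == "pruned" and size > 10_000:
            # a cheap beam pass primes the incumbent; exactness is unaffected
            seed_obj, _, _ = _search_beam(engine, width=beam_width)
        obj, t_half, combo = _search_dfs(
            engine, prune=(strategy == "pruned"), seed_objective=seed_obj
        )
    elif strategy == "beam":
        obj, t_half, combo = _search_beam(engine, width=beam_width)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    scheme = engine.scheme_from(combo)
    scores = score_subjects(scheme, cohort)
    table = screening_table(scores, cohort.labels, step=space.step)
    retained = scheme.nonzero_items()
    # an all-zero winner (degenerate cohorts) retains nothing; keep the full schema then
    reduced = (
        cohort.schema.subset(retained, version=cohort.schema.version + "_reduced")
        if retained
        else cohort.schema
    )
    return GridSearchResult(
        scheme=scheme,
        objective=obj,
        threshold=t_half * space.step,
        table=table,
        reduced_schema=reduced,
        strategy=strategy,
        n_evaluated=engine.n_evaluated,
        space_size=size,
        metadata={"zero_allowed": space.zero_allowed, "beam_width": beam_width},
    )
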