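"""Questionnaire data model and packaged fixtures.

The package ships the nine-item COPD self-evaluation questionnaire as its
default schema: each item has an ordered list of response choices, index 0
being the least medically severe (the scoring baseline).  Alongside the
schema, packaged fixtures provide the published class-conditional response
distributions of the development cohort (404 COPD cases / 1420 controls),
the published six-item scoring scheme, and the published five-fold item
importance table used by the rank-ensembling arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "QuestionItem",
    "QuestionnaireSchema",
    "ClassConditionalTable",
    "ScoringScheme",
    "SchemaError",
    "load_schema",
    "published_scheme",
    "table2_distributions",
    "fold_importance_fixture",
    "reference_screening_fixture",
]

SCORE_STEP = 0.5


class SchemaError(ValueError):
    """Raised when a schema, distribution table or scoring scheme is invalid."""


def _fixture_text(name: str) -> str:
    return resources.files("screenscore.fixtures").joinpath(name).read_text()


@dataclass(frozen=True)
class QuestionItem:
    """A single questionnaire item with severity-ordered choices."""

    id: str
    text: str
    choices: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.choices) < 2:
            raise SchemaError(
                f"item {self.id!r} has {len(self.choices)} choice(s); at least 2 required"
            )

    @property
    def n_choices(self) -> int:
        return len(self.choices)


@dataclass(frozen=True)
class QuestionnaireSchema:
    """An ordered collection of items; the structural object shared by all stages."""

    items: tuple[QuestionItem, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise SchemaError(f"duplicate item id(s): {sorted(dupes)}")
        if not self.items:
            raise SchemaError("schema has no items")

    def __iter__(self) -> Iterator[QuestionItem]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.id for it in self.items)

    @property
    def choice_counts(self) -> tuple[int, ...]:
        return tuple(it.n_choices for it in self.items)

    def __getitem__(self, item_id: str) -> QuestionItem:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "items": [
                {"id": it.id, "name": it.name, "text": it.text, "choices": list(it.choices)}
                for it in self.items
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def subset(self, item_ids: tuple[str, ...], version: str | None = None) -> "QuestionnaireSchema":
        """Schema restricted to the given items, preserving order."""
        keep = [it for it in self.items if it.id in set(item_ids)]
        return QuestionnaireSchema(tuple(keep), version or self.version + "_subset")


def _schema_from_payload(payload: Mapping, source: str) -> QuestionnaireSchema:
    try:
        raw_items = payload["items"]
    except KeyError as exc:
        raise SchemaError(f"{source}: missing 'items' key") from exc
    items = []
    for raw in raw_items:
        try:
            items.append(
                QuestionItem(
                    id=raw["id"],
                    text=raw.get("text", ""),
                    choices=tuple(raw["choices"]),
                    name=raw.get("name", ""),
                )
            )
        except SchemaError:
            raise
        except Exception as exc:  # malformed entry: name the offender
            raise SchemaError(f"{source}: malformed item entry {raw!r}: {exc}") from exc
    return QuestionnaireSchema(tuple(items), version=payload.get("version", "unversioned"))


def load_schema(source: str | Path = "copd_eq_v1") -> QuestionnaireSchema:
    """Load a questionnaire schema from a packaged fixture name or a JSON file.

    Parameters
    ----------
    source
        Either the name of a packaged fixture (``"copd_eq_v1"``) or a path to
        a JSON schema file with keys ``version`` and ``items``
        (``id`` / ``text`` / ordered ``choices``).
    """
    if isinstance(source, str) and not source.endswith(".json") and "/" not in source:
        payload = json.loads(_fixture_text(f"{source}.json"))
        return _schema_from_payload(payload, source=f"fixture {source!r}")
    path = Path(source)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    return _schema_from_payload(payload, source=str(path))


@dataclass(frozen=True)
class ClassConditionalTable:
    """Per-item, per-class probability vectors over response choices.

    Probabilities are stored from printed counts where counts exist, so they
    carry no rounding beyond the source counts themselves.
    """

    schema: QuestionnaireSchema
    probs: Mapping[str, Mapping[str, np.ndarray]]  # item id -> {"case","control"} -> probs
    n_case: int = 0
    n_control: int = 0

    def __post_init__(self) -> None:
        for it in self.schema:
            if it.id not in self.probs:
                raise SchemaError(f"distribution table missing item {it.id!r}")
            for cls in ("case", "control"):
                p = np.asarray(self.probs[it.id][cls], dtype=float)
                if p.shape != (it.n_choices,):
                    raise SchemaError(
                        f"item {it.id!r} class {cls!r}: {p.size} probabilities for "
                        f"{it.n_choices} choices"
                    )
                if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                    raise SchemaError(f"item {it.id!r} class {cls!r}: not a probability vector")

    def prob(self, item_id: str, cls: str) -> np.ndarray:
        return np.asarray(self.probs[item_id][cls], dtype=float)


def table2_distributions(schema: QuestionnaireSchema | None = None) -> ClassConditionalTable:
    """The packaged class-conditional response distributions of the development cohort.

    Vectors are normalised from the printed per-choice counts (exact
    fractions such as 387/404).  The smoking-amount item is printed only as
    continuous pack-year summaries; its band probabilities are synthetic
    values consistent with the printed medians and interquartile ranges (see
    the fixture file note and docs/methods.md).
    """
    schema = schema or load_schema("copd_eq_v1")
    raw = json.loads(_fixture_text("class_conditional_counts.json"))
    probs: dict[str, dict[str, np.ndarray]] = {}
    for it in schema:
        probs[it.id] = {}
        for cls in ("case", "control"):
            w = np.asarray(raw[cls][it.id], dtype=float)
            probs[it.id][cls] = w / w.sum()
    return ClassConditionalTable(
        schema=schema, probs=probs, n_case=raw["n_case"], n_control=raw["n_control"]
    )


@dataclass(frozen=True)
class ScoringScheme:
    """An additive scorecard: one real score per response choice of each item.

    Invariants: the baseline (index-0) choice scores 0; scores are weakly
    non-decreasing along the severity order; every score is an integer
    multiple of ``step``.
    """

    scores: Mapping[str, tuple[float, ...]]
    step: float = SCORE_STEP
    caps: Mapping[str, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for item_id, vec in self.scores.items():
            if not vec:
                raise SchemaError(f"item {item_id!r}: empty score vector")
            if vec[0] != 0:
                raise SchemaError(f"item {item_id!r}: baseline score must be 0, got {vec[0]}")
            if any(b < a for a, b in zip(vec, vec[1:])):
                raise SchemaError(f"item {item_id!r}: scores must be weakly non-decreasing: {vec}")
            for s in vec:
                if abs(s / self.step - round(s / self.step)) > 1e-9:
                    raise SchemaError(
                        f"item {item_id!r}: score {s} is not a multiple of step {self.step}"
                    )
            if self.caps is not None and item_id in self.caps:
                if max(vec) > self.caps[item_id] + 1e-9:
                    raise SchemaError(
                        f"item {item_id!r}: score {max(vec)} exceeds cap {self.caps[item_id]}"
                    )

    def __getitem__(self, item_id: str) -> tuple[float, ...]:
        return tuple(self.scores[item_id])

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.scores.keys())

    @property
    def max_total(self) -> float:
        return float(sum(max(v) for v in self.scores.values()))

    def nonzero_items(self) -> tuple[str, ...]:
        """Items carrying at least one non-zero score (the retained questionnaire)."""
        return tuple(i for i, v in self.scores.items() if max(v) > 0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "step": self.step,
            "scores": {i: [float(s) for s in v] for i, v in self.scores.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoringScheme":
        payload = json.loads(Path(path).read_text())
        return cls(
            scores={i: tuple(v) for i, v in payload["scores"].items()},
            step=payload.get("step", SCORE_STEP),
        )


def published_scheme() -> ScoringScheme:
    """The published six-item scoring scheme.

    Items 6, 8 and 9 received all-zero scores in the published search and are
    represented as all-zero vectors, so the nine-item and six-item views are
    interconvertible via :meth:`ScoringScheme.nonzero_items`.
    """
    payload = json.loads(_fixture_text("published_scheme.json"))
    return ScoringScheme(
        scores={i: tuple(v) for i, v in payload["scores"].items()}, step=payload["step"]
    )


def fold_importance_fixture() -> dict:
    """Published per-fold mean-|SHAP| values and ranks for the nine items.

    Returns a dict with keys ``items`` (list of ids), ``shap`` and ``ranks``
    (both shaped items x folds) and ``published_final_rank``.
    """
    raw = json.loads(_fixture_text("fold_importance.json"))
    return {
        "items": list(raw["items"]),
        "shap": np.asarray(raw["shap"], dtype=float),
        "ranks": np.asarray(raw["ranks"], dtype=int),
        "published_final_rank": np.asarray(raw["published_final_rank"], dtype=int),
    }


def reference_screening_fixture(instrument: str = "copd_ps"):
    """Published per-threshold screening columns (percent) for ``copd_eq`` or ``copd_ps``."""
    import pandas as pd

    raw = json.loads(_fixture_text("reference_screening.json"))
    if instrument not in raw or instrument == "note":
        raise KeyError(f"unknown instrument {instrument!r}")
    return pd.DataFrame(raw[instrument])
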