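import itertools

import numpy as np
import pandas as pd
import pytest

from screenscore.cohort import Cohort
from screenscore.schema import ScoringScheme, published_scheme
from screenscore.search import (
    DEFAULT_TIER_RULE,
    SearchBudgetError,
    SearchSpace,
    assign_caps,
    count_schemes,
    enumerate_schemes,
    grid_search,
    objective,
    score_subjects,
    screening_table,
)

from conftest import make_toy_cohort

TABLE3_FINAL_RANKS = {
    "item1": 1, "item2": 3, "item3": 4, "item4": 2, "item5": 7,
    "item6": 5, "item7": 6, "item8": 9, "item9": 8,
}


def random_space(rng, max_items=3, max_schemes=500):
    """Random small space over a random toy schema; resamples until small enough."""
    from screenscore.schema import QuestionItem, QuestionnaireSchema

    while True:
        q = rng.integers(1, max_items + 1)
        counts = rng.integers(2, 5, size=q)
        caps = rng.choice([0.0, 0.5, 1.0, 1.5, 2.0], size=q)
        zero_allowed = bool(rng.integers(0, 2))
        items = tuple(
            QuestionItem(f"it{i}", "", tuple("abcde"[:k])) for i, k in enumerate(counts)
        )
        sch = QuestionnaireSchema(items, "rand")
        space = SearchSpace.from_caps(
            sch, {f"it{i}": c for i, c in enumerate(caps)}, zero_allowed=zero_allowed
        )
        if count_schemes(space) <= max_schemes:
            return sch, space


class TestCaps:
    def test_published_ranks_give_published_caps(self):
        caps = assign_caps(TABLE3_FINAL_RANKS, DEFAULT_TIER_RULE)
        assert caps.caps == {
            "item1": 3.0, "item4": 3.0, "item2": 2.0, "item3": 2.0, "item6": 2.0,
            "item7": 1.0, "item5": 1.0, "item9": 0.0, "item8": 0.0,
        }

    def test_two_item_questionnaire_truncates_tiers(self):
        caps = assign_caps({"a": 1, "b": 2}, DEFAULT_TIER_RULE)
        assert caps.caps == {"a": 3.0, "b": 3.0}

    def test_eliminating_rule_slice(self):
        caps = assign_caps({"a": 1, "b": 2}, tier_rule=((1, None, 0.0),))
        assert set(caps.caps.values()) == {0.0}

    def test_uncovered_rank_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            assign_caps({"a": 1, "b": 2, "c": 3}, tier_rule=((1, 2, 3.0),))

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            assign_caps({"a": 1, "b": 1})


class TestCounting:
    @pytest.mark.parametrize(
        "n_choices, cap, zero_allowed, expected",
        [
            (2, 1.0, False, 2),     # {0.5},{1.0}
            (2, 1.0, True, 3),      # {0},{0.5},{1.0}
            (4, 3.0, False, 56),    # C(8,3)
            (5, 3.0, False, 126),   # C(9,4)
            (3, 0.0, True, 1),      # cap-0 admits only the zero vector
        ],
    )
    def test_closed_form_examples(self, n_choices, cap, zero_allowed, expected):
        from screenscore.schema import QuestionItem, QuestionnaireSchema

        sch = QuestionnaireSchema(
            (QuestionItem("a", "", tuple("abcde"[:n_choices])),), "t"
        )
        space = SearchSpace.from_caps(sch, {"a": cap}, zero_allowed=zero_allowed)
        assert count_schemes(space) == expected
        assert len(list(enumerate_schemes(space))) == expected

    def test_closed_form_equals_enumeration_on_random_spaces(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, space = random_space(rng)
            schemes = [tuple(sorted(s.scores.items())) for s in enumerate_schemes(space)]
            assert count_schemes(space) == len(schemes) == len(set(schemes))

    def test_full_questionnaire_space_sizes(self, schema):
        caps = assign_caps(TABLE3_FINAL_RANKS, DEFAULT_TIER_RULE)
        with_zero = SearchSpace.from_caps(schema, caps, zero_allowed=True)
        without = SearchSpace.from_caps(schema, caps, zero_allowed=False)
        assert count_schemes(with_zero) == 3_472_875_000
        assert count_schemes(without) == 56_448_000


class TestEnumeration:
    def test_deterministic_order_and_validity(self):
        rng = np.random.default_rng(1)
        _, space = random_space(rng)
        first = [s.scores for s in enumerate_schemes(space)]
        second = [s.scores for s in enumerate_schemes(space)]
        assert first == second
        for s in enumerate_schemes(space):
            for item_space in space.items:
                vec = s[item_space.item_id]
                assert vec[0] == 0
                assert all(b >= a for a, b in zip(vec, vec[1:]))
                assert max(vec) <= item_space.cap_half * space.step + 1e-9


class TestScoring:
    def test_all_baseline_scores_zero(self, cohort_small):
        c = cohort_small.copy()
        for it in c.schema:
            c.data[it.id] = 0
        assert (score_subjects(published_scheme(), c) == 0).all()

    def test_worked_example_totals_eight(self, schema):
        # age>=70, >20 packs, biomass yes, breath most of the time,
        # dyspnoea strenuous, cough up every day; rest baseline
        df = pd.DataFrame(
            [{"item1": 3, "item2": 3, "item3": 1, "item4": 3, "item5": 1,
              "item6": 0, "item7": 4, "item8": 0, "item9": 0,
              "subject_id": "w", "label": "case"}]
        )
        c = Cohort(schema, df)
        assert score_subjects(published_scheme(), c)[0] == pytest.approx(8.0)

    def test_max_severity_totals_nine(self, schema):
        df = pd.DataFrame(
            [{it.id: it.n_choices - 1 for it in schema} | {"subject_id": "m", "label": "case"}]
        )
        c = Cohort(schema, df)
        assert score_subjects(published_scheme(), c)[0] == pytest.approx(9.0)

    def test_out_of_range_response_rejected(self, schema):
        df = pd.DataFrame(
            [{it.id: 0 for it in schema} | {"subject_id": "x", "label": "case"}]
        )
        df["item3"] = 5
        with pytest.raises(ValueError, match="item3"):
            score_subjects(published_scheme(), Cohort(schema, df))


def brute_force_table(scores, labels, thresholds):
    """Confusion-matrix oracle for the strict decision rule."""
    rows = []
    is_case = np.asarray(labels) == "case"
    for t in thresholds:
        pos = np.asarray(scores) > t
        tp = (pos & is_case).sum()
        fn = (~pos & is_case).sum()
        tn = (~pos & ~is_case).sum()
        fp = (pos & ~is_case).sum()
        rows.append((t, tp / (tp + fn), tn / (tn + fp)))
    return rows


class TestScreeningTable:
    def test_tiny_example(self):
        t = screening_table([0, 4.5, 5.0], ["control", "case", "case"], thresholds=[4.0])
        assert t.frame.loc[0, "sensitivity"] == 1.0
        assert t.frame.loc[0, "specificity"] == 1.0

    def test_perfect_separation_reaches_unit_balanced_index(self):
        t = screening_table([1, 1, 8, 9], ["control", "control", "case", "case"])
        assert t.frame["balanced_index"].max() == 1.0

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            scores = rng.choice(np.arange(0, 5.5, 0.5), size=60)
            labels = rng.choice(["case", "control"], size=60)
            if len(set(labels)) < 2:
                continue
            t = screening_table(scores, labels)
            oracle = brute_force_table(scores, labels, t.frame["threshold"])
            for (_, s, sp), row in zip(oracle, t.frame.itertuples()):
                assert row.sensitivity == pytest.approx(s)
                assert row.specificity == pytest.approx(sp)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        scores = rng.choice(np.arange(0, 9.5, 0.5), size=300)
        labels = rng.choice(["case", "control"], size=300)
        t = screening_table(scores, labels).frame
        assert (np.diff(t["sensitivity"]) <= 1e-12).all()
        assert (np.diff(t["specificity"]) >= -1e-12).all()

    def test_one_class_input_names_missing_class(self):
        with pytest.raises(ValueError, match="control"):
            screening_table([1, 2], ["case", "case"])
        with pytest.raises(ValueError, match="case"):
            screening_table([1, 2], ["control", "control"])


class TestObjective:
    def test_all_zero_scheme_scores_half(self, cohort_small):
        scheme = ScoringScheme(scores={it: (0.0, 0.0) for it in ("item3", "item6")})
        obj, t = objective(scheme, cohort_small)
        assert obj == pytest.approx(0.5)

    def test_balanced_index_arithmetic(self):
        assert (0.6758 + 0.7920) / 2 == pytest.approx(0.7339)

    def test_objective_never_below_half(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            c = make_toy_cohort(rng, n=120)
            sch, space = None, None
            caps = {it: 1.0 for it in c.item_columns}
            space = SearchSpace.from_caps(c.schema, caps, zero_allowed=True)
            for s in itertools.islice(enumerate_schemes(space), 10):
                obj, _ = objective(s, c)
                assert obj >= 0.5 - 1e-12


def oracle_argmax(cohort, space):
    best = None
    for s in enumerate_schemes(space):
        obj, t = objective(s, cohort)
        if best is None or obj > best[0] + 1e-12:
            best = (obj, t, s)
    return best


class TestGridSearch:
    def test_exhaustive_and_pruned_match_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(8):
            c = make_toy_cohort(rng, n=150)
            _, space = random_space(rng)
            space = SearchSpace.from_caps(
                c.schema,
                {it: sp.cap_half * 0.5 for it, sp in zip(c.item_columns, space.items)},
                zero_allowed=space.zero_allowed,
            )
            obj_o, t_o, s_o = oracle_argmax(c, space)
            r_ex = grid_search(c, space, strategy="exhaustive")
            r_pr = grid_search(c, space, strategy="pruned")
            assert r_ex.objective == pytest.approx(obj_o, abs=1e-12)
            assert r_pr.objective == pytest.approx(obj_o, abs=1e-12)
            assert r_ex.scheme == s_o == r_pr.scheme
            assert r_ex.threshold == pytest.approx(t_o)

    def test_budget_guard_refuses_and_suggests(self, schema):
        caps = assign_caps(TABLE3_FINAL_RANKS, DEFAULT_TIER_RULE)
        space = SearchSpace.from_caps(schema, caps, zero_allowed=True)
        rng = np.random.default_rng(11)
        c = make_toy_cohort(rng, choice_counts=schema.choice_counts, n=50)
        with pytest.raises(SearchBudgetError, match="pruned"):
            grid_search(c, space, strategy="exhaustive", budget=10**6)

    def test_planted_scorecard_not_beaten_by_argmax(self):
        rng = np.random.default_rng(12)
        c = make_toy_cohort(rng, choice_counts=(3, 2), n=400, signal=0.45)
        space = SearchSpace.from_caps(
            c.schema, {"it0": 1.0, "it1": 1.0}, zero_allowed=True
        )
        planted = ScoringScheme(scores={"it0": (0.0, 0.5, 1.0), "it1": (0.0, 1.0)})
        planted_obj, _ = objective(planted, c)
        result = grid_search(c, space, strategy="exhaustive")
        assert result.objective >= planted_obj - 1e-12

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(13)
        c = make_toy_cohort(rng, n=200)
        space = SearchSpace.from_caps(
            c.schema, {it: 1.0 for it in c.item_columns}, zero_allowed=True
        )
        r1 = grid_search(c, space)
        shuffled = Cohort(
            c.schema, c.data.sample(frac=1, random_state=0).reset_index(drop=True)
        )
        r2 = grid_search(shuffled, space)
        assert r1.scheme == r2.scheme and r1.objective == r2.objective

    def test_beam_returns_valid_scheme(self):
        rng = np.random.default_rng(14)
        c = make_toy_cohort(rng, n=200)
        space = SearchSpace.from_caps(
            c.schema, {it: 1.5 for it in c.item_columns}, zero_allowed=True
        )
        r_ex = grid_search(c, space, strategy="exhaustive")
        r_beam = grid_search(c, space, strategy="beam", beam_width=16)
        assert r_beam.objective <= r_ex.objective + 1e-12
        assert r_beam.objective >= 0.5

    def test_reduced_schema_drops_zero_items(self, schema, cohort_small):
        caps = assign_caps(TABLE3_FINAL_RANKS, DEFAULT_TIER_RULE)
        # shrink to a tractable sub-search: only two items free, rest eliminated
        caps_small = {k: (v if k in ("item1", "item3") else 0.0) for k, v in caps.caps.items()}
        space = SearchSpace.from_caps(schema, caps_small, zero_allowed=True)
        result = grid_search(cohort_small, space, strategy="exhaustive")
        assert set(result.reduced_schema.item_ids) == set(result.scheme.nonzero_items())
        assert "item8" not in result.reduced_schema.item_ids


from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    scores=st.lists(
        st.integers(min_value=0, max_value=18).map(lambda h: h * 0.5),
        min_size=4, max_size=60,
    ),
    labels=st.lists(st.booleans(), min_size=4, max_size=60),
)
def test_screening_table_properties_hold_for_arbitrary_inputs(scores, labels):
    """Threshold sweep invariants: sens non-increasing, spec non-decreasing,
    everything in [0,1], youden = 2*balanced - 1."""
    n = min(len(scores), len(labels))
    scores, labels = scores[:n], np.array(labels[:n])
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    t = screening_table(scores, labels).frame
    assert (np.diff(t["sensitivity"]) <= 1e-12).all()
    assert (np.diff(t["specificity"]) >= -1e-12).all()
    assert t[["sensitivity", "specificity", "balanced_index"]].to_numpy().min() >= 0
    assert t[["sensitivity", "specificity", "balanced_index"]].to_numpy().max() <= 1
    np.testing.assert_allclose(t["youden"], 2 * t["balanced_index"] - 1, atol=1e-12)
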