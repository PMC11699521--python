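import numpy as np
import pytest
from scipy import stats

from screenscore.evaluation import cohort_summary, compare_instruments, roc_auc, youden
from screenscore.search import screening_table

from conftest import make_toy_cohort


def pair_counting_auc(scores, labels):
    """Concordance oracle: P(case > control) + 0.5 P(tie) over all pairs."""
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(labels).astype(bool)
    cases, ctrls = scores[is_case], scores[~is_case]
    wins = (cases[:, None] > ctrls[None, :]).sum()
    ties = (cases[:, None] == ctrls[None, :]).sum()
    return (wins + 0.5 * ties) / (len(cases) * len(ctrls))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 8, 9], [0, 0, 1, 1]).value == 1.0

    def test_constant_scores(self):
        assert roc_auc([3, 3, 3, 3], [0, 1, 0, 1]).value == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(10, 60)
            scores = rng.choice(np.arange(0, 5, 0.5), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            assert roc_auc(scores, labels).value == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).value
        b = roc_auc(np.exp(3 * scores), labels).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])


class TestYouden:
    @pytest.mark.parametrize(
        "sens, spec, expected",
        [(0.812, 0.709, 0.521), (0.828, 0.671, 0.499), (1, 1, 1), (0.5, 0.5, 0.0)],
    )
    def test_examples(self, sens, spec, expected):
        assert youden(sens, spec) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            youden(1.2, 0.5)

    def test_twice_balanced_minus_one_identity(self):
        rng = np.random.default_rng(2)
        scores = rng.choice(np.arange(0, 9.5, 0.5), size=200)
        labels = rng.choice(["case", "control"], size=200)
        t = screening_table(scores, labels).frame
        np.testing.assert_allclose(t["youden"], 2 * t["balanced_index"] - 1, atol=1e-12)


class TestCompareInstruments:
    def test_identical_inputs_have_zero_difference(self):
        rng = np.random.default_rng(3)
        scores = rng.choice(np.arange(0, 5, 0.5), size=100)
        labels = rng.choice(["case", "control"], size=100)
        t = screening_table(scores, labels)
        merged = compare_instruments(t, t, names=("x", "y"))
        np.testing.assert_allclose(merged["sensitivity_x"], merged["sensitivity_y"])
        np.testing.assert_allclose(merged["balanced_index_x"], merged["balanced_index_y"])

    def test_printed_reference_row_balanced_index(self):
        # the comparison instrument's threshold-1.0 row
        assert (0.9632 + 0.2146) / 2 == pytest.approx(0.5889)

    def test_best_flag_matches_scan(self):
        rng = np.random.default_rng(4)
        a = screening_table(rng.choice(np.arange(0, 5, 0.5), 80), rng.choice(["case", "control"], 80))
        b = screening_table(rng.choice(np.arange(0, 7, 0.5), 80), rng.choice(["case", "control"], 80))
        merged = compare_instruments(a, b, names=("a", "b"))
        best_row = merged.loc[merged["best_a"]]
        assert best_row["balanced_index_a"].item() == pytest.approx(
            np.nanmax(merged["balanced_index_a"])
        )
        assert merged["best_a"].sum() == 1 and merged["best_b"].sum() == 1


class TestCohortSummary:
    def test_null_distributions_give_large_p(self):
        rng = np.random.default_rng(5)
        c = make_toy_cohort(rng, n=4000, signal=0.0)
        summary = cohort_summary(c)
        p = summary.loc[summary["variable"] == "it0", "p_value"].dropna().item()
        assert p > 0.05

    def test_extreme_two_by_two_uses_exact_test(self, schema):
        import pandas as pd
        from screenscore.cohort import Cohort

        rows = []
        for i in range(20):
            rec = {it.id: 0 for it in schema}
            rec["item8"] = 1 if i < 10 else 0
            rec["label"] = "case" if i < 10 else "control"
            rec["subject_id"] = f"s{i}"
            rows.append(rec)
        c = Cohort(schema, pd.DataFrame(rows))
        summary = cohort_summary(c)
        row = summary[(summary["variable"] == "item8") & (summary["test"] != "")]
        assert row["test"].item() == "fisher"
        # exact hypergeometric: P = 2 / C(20,10)
        assert row["p_value"].item() == pytest.approx(2 / 184756, rel=1e-6)

    def test_row_count_items_plus_pack_years(self, cohort_small):
        summary = cohort_summary(cohort_small)
        expected = sum(it.n_choices for it in cohort_small.schema) + 1
        assert len(summary) == expected

    def test_single_class_rejected(self, cohort_small):
        from screenscore.cohort import Cohort

        df = cohort_small.data[cohort_small.data["label"] == "case"].reset_index(drop=True)
        with pytest.raises(ValueError):
            cohort_summary(Cohort(cohort_small.schema, df))
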