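import numpy as np
import pandas as pd
import pytest

from screenscore.cohort import (
    GeneratorConfig,
    apply_mcar_mask,
    attach_pack_years,
    attach_spirometry,
    make_retest,
    read_cohort_csv,
    sample_cohort,
)
from screenscore.preprocessing import discretise_smoking
from screenscore.schema import published_scheme
from screenscore.search import score_subjects


class TestSampling:
    def test_same_config_gives_identical_cohort(self, dists):
        cfg = GeneratorConfig(n_case=50, n_control=150, seed=42)
        a = sample_cohort(dists, cfg)
        b = sample_cohort(dists, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_cases_only_cohort(self, dists):
        c = sample_cohort(dists, GeneratorConfig(n_case=30, n_control=0, seed=1))
        assert len(c) == 30
        assert c.labels.all()

    def test_marginals_approach_fixture(self, schema, dists):
        c = sample_cohort(dists, GeneratorConfig(n_case=8000, n_control=8000, seed=5))
        for it in ("item3", "item8"):
            emp = np.bincount(
                c.data[it][c.labels].astype(int), minlength=schema[it].n_choices
            ) / c.labels.sum()
            assert np.abs(emp - dists.prob(it, "case")).max() < 0.02

    def test_copula_dependence_preserves_marginals(self, schema, dists):
        cfg = GeneratorConfig(n_case=15000, n_control=0, seed=6, dependence=0.6)
        c = sample_cohort(dists, cfg)
        for it in schema:
            emp = np.bincount(c.data[it.id].astype(int), minlength=it.n_choices) / len(c)
            assert np.abs(emp - dists.prob(it.id, "case")).max() < 0.02

    def test_copula_dependence_induces_positive_association(self, dists):
        cfg = GeneratorConfig(n_case=15000, n_control=0, seed=6, dependence=0.8)
        c = sample_cohort(dists, cfg)
        r = np.corrcoef(c.data["item4"].astype(float), c.data["item5"].astype(float))[0, 1]
        assert r > 0.3


class TestPackYears:
    def test_band_membership(self, cohort_small):
        band = cohort_small.data["item2"].astype(int).to_numpy()
        py = cohort_small.data["pack_years"].to_numpy()
        smoker = cohort_small.data["smoker"].to_numpy()
        assert (py[band == 0] == 0).all()
        assert (~smoker[band == 0]).all()
        assert (py[band == 3] > 20).all()
        assert smoker[band > 0].all()

    def test_rediscretisation_recovers_band(self, cohort_small):
        band = cohort_small.data["item2"].astype(int).to_numpy()
        rec = np.array(
            [
                discretise_smoking(bool(s), float(p), packs=True)
                for s, p in zip(cohort_small.data["smoker"], cohort_small.data["pack_years"])
            ]
        )
        assert (band == rec).all()


class TestSpirometry:
    def test_diagnostic_rule_holds_everywhere(self, cohort_full):
        ratio = cohort_full.data["fev1_fvc"].to_numpy()
        assert ((ratio < 0.70) == cohort_full.labels).all()
        assert (ratio > 0).all() and (ratio <= 1).all()

    def test_score_correlates_negatively_with_obstruction(self, cohort_full):
        totals = score_subjects(published_scheme(), cohort_full)
        r = np.corrcoef(totals, cohort_full.data["fev1_fvc"])[0, 1]
        assert r < 0


class TestRetest:
    def test_full_agreement_copies_entry(self, cohort_small):
        c = make_retest(cohort_small, agreement=1.0, seed=0)
        for it in c.schema:
            assert (c.data[it.id] == c.data[f"retest_{it.id}"]).all()

    def test_observed_agreement_matches_requested(self, dists):
        c = sample_cohort(dists, GeneratorConfig(n_case=48, n_control=48, seed=13))
        c = make_retest(c, agreement=0.9, seed=14)
        for it in c.schema:
            same = (c.data[it.id] == c.data[f"retest_{it.id}"]).mean()
            # resampling can re-draw the entry value, so observed >= nominal
            assert same == pytest.approx(0.9, abs=0.06) or same > 0.9

    def test_invalid_agreement_rejected(self, cohort_small):
        with pytest.raises(ValueError):
            make_retest(cohort_small, agreement=1.2)


class TestMcar:
    def test_zero_rate_is_identity(self, cohort_small):
        m = apply_mcar_mask(cohort_small, rate=0.0, seed=1)
        pd.testing.assert_frame_equal(m.data, cohort_small.data)

    def test_rate_recovered_and_labels_protected(self, dists):
        c = sample_cohort(dists, GeneratorConfig(n_case=5000, n_control=5000, seed=21))
        m = apply_mcar_mask(c, rate=0.05, seed=22)
        frac = m.responses.isna().to_numpy().mean()
        assert frac == pytest.approx(0.05, abs=0.01)
        assert not m.data["label"].isna().any()
        assert not m.data["subject_id"].isna().any()


def test_csv_round_trip(tmp_path, schema, cohort_full):
    path = tmp_path / "cohort.csv"
    cohort_full.to_csv(path)
    again = read_cohort_csv(path, schema)
    assert len(again) == len(cohort_full)
    pd.testing.assert_frame_equal(
        again.responses.astype("int64"), cohort_full.responses.astype("int64")
    )
    assert (again.labels == cohort_full.labels).all()
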