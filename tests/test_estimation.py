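"""Design-based estimation: eligibility rules, weighted rates vs brute
force, transformed uncertainty intervals, and disaggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from equimeasure.datamodel import CHILD_SEX, WEALTH, cmc
from equimeasure.estimation import (NATIONAL_LABEL, SurveyDisaggregator,
                                    disaggregate, neonatal_death,
                                    sba_eligible, uncertainty_interval,
                                    weighted_rate)
from equimeasure.exceptions import EstimationError
from equimeasure.synthetic import (ProbabilityMap, SampleDesignConfig,
                                   draw_survey_sample, generate_population,
                                   guinea_like_population)

from conftest import make_microdata


class TestEligibility:
    @pytest.mark.parametrize("months_before,window,expected",
                             [(35, 3, True), (36, 3, False), (30, 2, False),
                              (23, 2, True), (0, 3, True)])
    def test_half_open_window(self, months_before, window, expected):
        df = make_microdata(1)
        df["birth_cmc"] = df["interview_cmc"] - months_before
        assert sba_eligible(df, window).iloc[0] is np.bool_(expected)

    def test_shrinking_window_never_grows_denominator(self):
        df = make_microdata(200, seed=3)
        n = [sba_eligible(df, w).sum() for w in (1, 2, 3, 4, 5)]
        assert n == sorted(n)

    @pytest.mark.parametrize("age,expected", [(0, 1), (27, 1), (28, 0),
                                              (None, 0)])
    def test_neonatal_death_is_strictly_under_28_days(self, age, expected):
        df = make_microdata(1, age_at_death=[age])
        assert neonatal_death(df).iloc[0] == expected


class TestWeightedRate:
    def test_unit_weight_percent(self):
        df = make_microdata(4, sba=[1, 1, 1, 0])
        est, _ = weighted_rate(df, "sba", "percent")
        assert est == pytest.approx(75.0)

    def test_weighted_mean_hand_computed(self):
        df = make_microdata(2, weights=[1, 3], sba=[0, 1])
        est, _ = weighted_rate(df, "sba", "percent")
        assert est == pytest.approx(75.0)

    def test_mortality_per_1000(self):
        ages = [0, 5] + [None] * 38
        df = make_microdata(40, age_at_death=ages)
        est, _ = weighted_rate(df, neonatal_death(df), "per_1000")
        assert est == pytest.approx(50.0)

    @given(st.lists(st.tuples(st.floats(0.01, 50), st.integers(0, 1)),
                    min_size=1, max_size=30))
    def test_matches_brute_force(self, rows):
        w = [r[0] for r in rows]
        y = [r[1] for r in rows]
        df = make_microdata(len(rows), weights=w, sba=y)
        est, _ = weighted_rate(df, "sba", "percent")
        brute = 100 * sum(wi * yi for wi, yi in rows) / sum(w)
        assert est == pytest.approx(brute, rel=1e-10, abs=1e-10)

    @given(st.floats(0.01, 1000))
    def test_weight_scale_invariance(self, c):
        df = make_microdata(30, seed=5,
                            weights=np.linspace(0.5, 4, 30))
        est1, se1 = weighted_rate(df, "sba", "percent")
        df2 = df.assign(weight=df["weight"] * c)
        est2, se2 = weighted_rate(df2, "sba", "percent")
        assert est2 == pytest.approx(est1, rel=1e-10)
        assert se2 == pytest.approx(se1, rel=1e-9)

    def test_empty_records_rejected(self):
        with pytest.raises(EstimationError):
            weighted_rate(make_microdata(3).iloc[:0], "sba", "percent")

    def test_srs_se_matches_textbook_formula(self):
        # unit weights, no design columns: SE^2 = s_u^2 * n/(n-1) / n^2
        df = make_microdata(50, seed=1).drop(columns=["stratum_id"])
        df["stratum"] = "all"
        y = df["sba"].to_numpy(float)
        est, se = weighted_rate(df.drop(columns=["cluster_id", "stratum"]),
                                "sba", "percent")
        p = y.mean()
        expected = np.sqrt(p * (1 - p) / (len(y) - 1))
        assert se == pytest.approx(100 * expected, rel=1e-9)


class TestUncertaintyInterval:
    def test_zero_se_degenerates_to_point(self):
        assert uncertainty_interval(42.0, 0.0, "percent") == (42.0, 42.0)

    def test_logit_interval_closed_form(self):
        """p = 0.5 under unit-weight SRS with n = 100: the back-transformed
        logit interval sits near the Wald (40.2, 59.8)."""
        se = 100 * np.sqrt(0.5 * 0.5 / 99)  # the estimator's SRS SE
        lo, hi = uncertainty_interval(50.0, se, "percent")
        z = stats.norm.ppf(0.975)
        se_t = (se / 100) / 0.25
        expect_lo = 100 / (1 + np.exp(z * se_t))
        assert lo == pytest.approx(expect_lo, abs=1e-9)
        assert (lo, hi) == pytest.approx((40.2, 59.8), abs=0.35)

    def test_bounds_respected_near_extremes(self):
        lo, hi = uncertainty_interval(2.0, 1.8, "percent")
        assert 0 <= lo <= 2.0 <= hi <= 100
        lo, hi = uncertainty_interval(980.0, 30.0, "per_1000")
        assert lo <= 980 <= hi <= 1000

    def test_boundary_uses_exact_binomial(self):
        lo, hi = uncertainty_interval(0.0, 1.0, "percent", n=50)
        assert lo == 0.0
        assert hi == pytest.approx(100 * (1 - 0.025 ** (1 / 50)), rel=1e-6)
        lo, hi = uncertainty_interval(100.0, 1.0, "percent", n=50)
        assert hi == 100.0
        assert lo == pytest.approx(100 * 0.025 ** (1 / 50), rel=1e-6)

    def test_nominal_coverage_on_clustered_data(self):
        """95% logit intervals cover the true proportion in 90-98% of
        replicated two-stage samples."""
        rng = np.random.default_rng(2024)
        p_true, n_clusters, m = 0.3, 40, 25
        covered = 0
        reps = 500
        for _ in range(reps):
            y = rng.random((n_clusters, m)) < p_true
            df = pd.DataFrame({
                "weight": 1.0,
                "stratum_id": "s0",
                "cluster_id": np.repeat(np.arange(n_clusters), m),
                "y": y.ravel().astype(int)})
            est, se = weighted_rate(df, "y", "percent")
            lo, hi = uncertainty_interval(est, se, "percent")
            covered += lo <= 100 * p_true <= hi
        assert 0.90 <= covered / reps <= 0.98


class TestDisaggregate:
    def test_single_region_national_equals_subgroup(self):
        df = make_microdata(30, seed=2)
        from equimeasure.datamodel import region_dimension
        frame = disaggregate(df, "sba", region_dimension(2012))
        conakry = frame.loc[frame["subgroup"] == "Conakry", "estimate"].iloc[0]
        national = frame.loc[frame["subgroup"] == NATIONAL_LABEL,
                             "estimate"].iloc[0]
        assert conakry == pytest.approx(national)

    def test_national_lies_within_subgroup_range(self, small_population):
        sample = draw_survey_sample(
            small_population, SampleDesignConfig(n_clusters=30, seed=7))
        frame = disaggregate(sample, "sba", WEALTH)
        sub = frame[frame["subgroup"] != NATIONAL_LABEL]["estimate"]
        nat = frame.loc[frame["subgroup"] == NATIONAL_LABEL, "estimate"].iloc[0]
        assert sub.min() - 1e-9 <= nat <= sub.max() + 1e-9

    def test_recovers_configured_gradient(self):
        probs = {"Q1": 0.1, "Q2": 0.3, "Q3": 0.5, "Q4": 0.7, "Q5": 0.9}
        cfg = guinea_like_population(
            n_women=12_000,
            sba_prob=ProbabilityMap(by={"wealth_quintile": probs}))
        pop = generate_population(cfg, seed=21)
        frame = disaggregate(pop.births, "sba", WEALTH)
        sub = frame[frame["subgroup"] != NATIONAL_LABEL]
        assert list(sub.sort_values("estimate")["subgroup"]) == [
            "Q1", "Q2", "Q3", "Q4", "Q5"]
        for q, p in probs.items():
            est = sub.loc[sub["subgroup"] == q, "estimate"].iloc[0]
            assert est == pytest.approx(100 * p, abs=4)

    def test_zero_level_flagged_absent(self):
        df = make_microdata(20)
        df["wealth_quintile"] = "Q1"
        with pytest.warns(UserWarning, match="flagged absent"):
            frame = disaggregate(df, "sba", WEALTH)
        q2 = frame[frame["subgroup"] == "Q2"]
        assert np.isnan(q2["estimate"].iloc[0])
        assert q2["pop_n"].iloc[0] == 0

    def test_male_excess_mortality_detected_reliably(self):
        """With configured male risk above female risk, the disaggregated
        male NMR exceeds the female NMR in at least 95% of 200 replicate
        surveys."""
        cfg = guinea_like_population(
            n_women=40_000, births_per_woman=1.2,
            nmr_prob=ProbabilityMap(by={"child_sex": {"male": 0.060,
                                                      "female": 0.035}}))
        pop = generate_population(cfg, seed=77)
        wins = 0
        reps = 200
        for r in range(reps):
            sample = draw_survey_sample(
                pop, SampleDesignConfig(n_clusters=80, seed=1000 + r))
            frame = disaggregate(sample, "nmr", CHILD_SEX)
            est = dict(zip(frame["subgroup"], frame["estimate"]))
            wins += est["male"] > est["female"]
        assert wins / reps >= 0.95

    def test_last_birth_denominator_one_per_woman(self):
        df = make_microdata(12, seed=9)
        df["woman_id"] = [f"w{i // 3}" for i in range(12)]  # 3 births each
        frame = disaggregate(df, "sba", WEALTH, denominator="last_birth")
        nat_n = frame.loc[frame["subgroup"] == NATIONAL_LABEL, "pop_n"].iloc[0]
        eligible_women = df.loc[sba_eligible(df, 3), "woman_id"].nunique()
        assert nat_n == eligible_women


class TestSurveyDisaggregatorEstimator:
    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone
        est = SurveyDisaggregator(indicator="nmr", dimension=CHILD_SEX,
                                  window_years=5)
        params = est.get_params()
        assert params["indicator"] == "nmr"
        est2 = clone(est).set_params(indicator="sba", dimension=WEALTH)
        assert est2.get_params()["dimension"] is WEALTH

    def test_fit_exposes_tables(self, small_population):
        sample = draw_survey_sample(
            small_population, SampleDesignConfig(n_clusters=25, seed=3))
        est = SurveyDisaggregator(indicator="sba", dimension=WEALTH).fit(sample)
        assert set(est.estimates_["subgroup"]) == {
            "Q1", "Q2", "Q3", "Q4", "Q5", NATIONAL_LABEL}
        assert est.national_.pop_n == est.n_used_
        assert (est.estimates_["ui_low"].dropna()
                <= est.estimates_["ui_high"].dropna()).all()

    def test_fit_requires_dimension(self):
        with pytest.raises(ValueError):
            SurveyDisaggregator().fit(make_microdata(5))
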