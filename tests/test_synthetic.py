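"""Synthetic population generator: determinism, marginals, PCA wealth,
two-stage PPS sampling, and design-truth summary measures."""

import numpy as np
import pandas as pd
import pytest

from equimeasure.datamodel import RESIDENCE, WEALTH
from equimeasure.exceptions import (ConfigurationError, DegenerateInputError,
                                    EmptyInputError)
from equimeasure.synthetic import (PopulationConfig, ProbabilityMap,
                                   RegionConfig, SampleDesignConfig,
                                   _pps_systematic, compute_wealth_index,
                                   draw_survey_sample, generate_population,
                                   guinea_like_population,
                                   measures_from_values,
                                   pps_inclusion_probabilities,
                                   true_summary_measures)


class TestGeneratePopulation:
    def test_same_seed_is_byte_identical(self):
        cfg = guinea_like_population(n_women=1500)
        a = generate_population(cfg, seed=5)
        b = generate_population(cfg, seed=5)
        assert a.births.to_csv(index=False) == b.births.to_csv(index=False)
        assert a.ground_truth.to_csv(index=False) == b.ground_truth.to_csv(index=False)

    def test_different_seed_differs(self):
        cfg = guinea_like_population(n_women=1500)
        a = generate_population(cfg, seed=5)
        b = generate_population(cfg, seed=6)
        assert a.births.to_csv(index=False) != b.births.to_csv(index=False)

    def test_uniform_probability_recovered_within_3_se(self):
        cfg = guinea_like_population(
            n_women=10_000, sba_prob=ProbabilityMap(base=0.5))
        pop = generate_population(cfg, seed=11)
        n = pop.n_births
        frac = pop.births["sba"].mean()
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_zero_mortality_means_zero_deaths(self):
        cfg = guinea_like_population(
            n_women=2000, nmr_prob=ProbabilityMap(base=0.0))
        pop = generate_population(cfg, seed=2)
        assert pop.births["age_at_death_days"].notna().sum() == 0

    def test_empty_population_rejected(self):
        cfg = guinea_like_population(n_women=10)
        cfg = PopulationConfig(**{**cfg.__dict__, "n_women": 0})
        with pytest.raises(EmptyInputError):
            generate_population(cfg, seed=0)

    def test_configured_quintile_probabilities_recovered(self):
        """Generated subgroup frequencies converge on the configured
        probabilities (within 4 binomial SEs at n >= 1e4 women)."""
        probs = {"Q1": 0.1, "Q2": 0.3, "Q3": 0.5, "Q4": 0.7, "Q5": 0.9}
        cfg = guinea_like_population(
            n_women=12_000,
            sba_prob=ProbabilityMap(by={"wealth_quintile": probs}))
        pop = generate_population(cfg, seed=4)
        for q, g in pop.births.groupby("wealth_quintile"):
            p = probs[q]
            se = np.sqrt(p * (1 - p) / len(g))
            assert abs(g["sba"].mean() - p) < 4 * se, q

    def test_births_dated_inside_recall_window(self):
        pop = generate_population(guinea_like_population(n_women=1000), seed=1)
        age = pop.births["interview_cmc"] - pop.births["birth_cmc"]
        assert ((age >= 0) & (age < 60)).all()

    def test_probabilities_validated(self):
        with pytest.raises(ConfigurationError):
            ProbabilityMap(base=1.2)
        with pytest.raises(ConfigurationError):
            guinea_like_population(regions=(RegionConfig("A", 0.6, 0.5),
                                            RegionConfig("B", 0.5, 0.5)))


class TestWealthIndex:
    def test_matches_correlation_eigenvector_oracle(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=200)
        X = np.column_stack([z + rng.normal(scale=0.5, size=200)
                             for _ in range(4)])
        scores, _, loadings = compute_wealth_index(X)
        # independent oracle: leading eigenvector of the correlation matrix
        Z = (X - X.mean(0)) / X.std(0)
        evals, evecs = np.linalg.eigh(np.corrcoef(Z.T))
        v = evecs[:, -1]
        oracle = Z @ v
        sign = np.sign(np.dot(oracle, scores))
        np.testing.assert_allclose(scores, sign * oracle, atol=1e-8)

    def test_equal_weights_split_evenly(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        _, quintiles, _ = compute_wealth_index(X)
        counts = pd.Series(quintiles).value_counts()
        assert (counts == 2).all()

    def test_quintiles_track_the_informative_asset(self):
        rng = np.random.default_rng(1)
        asset = rng.normal(size=500)
        X = np.column_stack([asset, 0.05 * rng.normal(size=500),
                             0.05 * rng.normal(size=500), asset * 0.9
                             + 0.1 * rng.normal(size=500)])
        scores, quintiles, _ = compute_wealth_index(X)
        q_num = pd.Series(quintiles).str[1].astype(int)
        rho = pd.Series(asset).rank().corr(q_num.rank())
        assert abs(rho) > 0.9
        # sign convention: more of the wealth-loading asset means higher score
        assert np.corrcoef(asset, scores)[0, 1] > 0

    def test_constant_column_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=50), rng.normal(size=50),
                             np.ones(50)])
        with pytest.warns(UserWarning, match="constant"):
            _, _, loadings = compute_wealth_index(X)
        assert loadings[2] == 0.0

    def test_all_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_wealth_index(np.ones((50, 3)))

    def test_weighted_quintiles_respect_weights(self):
        scores = np.arange(10, dtype=float).reshape(-1, 1)
        X = np.column_stack([scores[:, 0], scores[:, 0] * 2])
        w = np.array([5, 1, 1, 1, 1, 1, 1, 1, 1, 1], dtype=float)
        _, quintiles, _ = compute_wealth_index(X, weights=w)
        # the heavy poorest household fills Q1 nearly alone
        assert quintiles[0] == "Q1"
        assert quintiles[-1] == "Q5"


class TestSampling:
    def test_equal_sizes_give_equal_inclusion(self):
        pi = pps_inclusion_probabilities(np.full(10, 50), 4)
        np.testing.assert_allclose(pi, 0.4)

    def test_pps_systematic_matches_enumeration(self):
        """Empirical selection frequencies over many random starts match
        size/total for a 1-of-3 PPS draw on sizes 100/200/700."""
        sizes = np.array([100, 200, 700])
        counts = np.zeros(3)
        n_draws = 4000
        for s in range(n_draws):
            rng = np.random.default_rng(s)
            sel, pi = _pps_systematic(sizes, 1, rng)
            counts[sel[0]] += 1
            np.testing.assert_allclose(pi, sizes[sel] / 1000.0)
        freq = counts / n_draws
        np.testing.assert_allclose(freq, [0.1, 0.2, 0.7], atol=0.02)

    def test_certainty_cluster_taken_with_probability_one(self):
        sizes = np.array([10, 10, 980])
        rng = np.random.default_rng(0)
        sel, pi = _pps_systematic(sizes, 2, rng)
        assert 2 in sel
        assert pi[list(sel).index(2)] == 1.0

    def test_weights_sum_to_population_total(self, ):
        """Horvitz-Thompson: the weighted sample total estimates the
        population birth count (within 10% at 100 clusters)."""
        pop = generate_population(guinea_like_population(n_women=20_000), seed=9)
        sample = draw_survey_sample(pop, SampleDesignConfig(n_clusters=100, seed=4))
        assert sample["weight"].gt(0).all()
        total = sample["weight"].sum()
        assert abs(total - pop.n_births) / pop.n_births < 0.10

    def test_sampling_deterministic_given_seed(self, small_population):
        d = SampleDesignConfig(n_clusters=20, seed=12)
        a = draw_survey_sample(small_population, d)
        b = draw_survey_sample(small_population, d)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_household_take_within_28_30(self, small_population):
        sample = draw_survey_sample(
            small_population, SampleDesignConfig(n_clusters=15, seed=2))
        per_cluster = sample.groupby("cluster_id")["household_id"].nunique()
        assert per_cluster.le(30).all()

    def test_design_validation(self):
        with pytest.raises(ConfigurationError):
            SampleDesignConfig(n_clusters=10, households_per_cluster=(20, 30))
        with pytest.raises(ConfigurationError):
            SampleDesignConfig(n_clusters=0)

    def test_more_clusters_than_population_rejected(self, small_population):
        with pytest.raises(ConfigurationError):
            draw_survey_sample(small_population,
                               SampleDesignConfig(n_clusters=10_000, seed=0))


class TestTrueSummaryMeasures:
    def test_equal_subgroups_mean_no_inequality(self):
        cfg = guinea_like_population(sba_prob=ProbabilityMap(base=0.4))
        res = true_summary_measures(cfg, WEALTH, "sba")
        assert res["D"] == pytest.approx(0.0, abs=1e-12)
        assert res["R"] == pytest.approx(1.0)
        assert res["PAR"] == pytest.approx(0.0, abs=1e-12)
        assert res["PAF"] == pytest.approx(0.0, abs=1e-12)

    def test_two_subgroup_hand_arithmetic(self):
        """Shares 0.5/0.5 with favorable values 20/80 give D=60, R=4,
        national 50, PAR=30, PAF=60."""
        res = measures_from_values(
            {"rural": 20.0, "urban": 80.0}, {"rural": 0.5, "urban": 0.5},
            RESIDENCE, "sba")
        assert res["national"] == pytest.approx(50.0)
        assert res["D"] == pytest.approx(60.0)
        assert res["R"] == pytest.approx(4.0)
        assert res["PAR"] == pytest.approx(30.0)
        assert res["PAF"] == pytest.approx(60.0)

    def test_adverse_reference_is_least_burdened_and_par_nonpositive(self):
        cfg = guinea_like_population(
            nmr_prob=ProbabilityMap(by={"residence": {"rural": 0.04,
                                                      "urban": 0.02}}))
        res = true_summary_measures(cfg, RESIDENCE, "nmr")
        assert res["reference"] == "urban"
        assert res["D"] == pytest.approx(20.0)
        assert res["PAR"] <= 0
        assert res["PAF"] <= 0

    def test_configured_truth_agrees_with_realized_population(self):
        probs = {"Q1": 0.15, "Q2": 0.3, "Q3": 0.45, "Q4": 0.65, "Q5": 0.9}
        cfg = guinea_like_population(
            n_women=15_000,
            sba_prob=ProbabilityMap(by={"wealth_quintile": probs}))
        design = true_summary_measures(cfg, WEALTH, "sba")
        pop = generate_population(cfg, seed=8)
        gt = pop.ground_truth.query(
            "indicator == 'sba' and dimension == 'wealth_quintile'")
        realized = dict(zip(gt["subgroup"], gt["true_value"]))
        for q, p in probs.items():
            assert realized[q] == pytest.approx(100 * p, abs=1e-9)
        nat = pop.ground_truth.query(
            "indicator == 'sba' and dimension == 'national'")["true_value"].iloc[0]
        assert nat == pytest.approx(design["national"], rel=0.02)

    def test_missing_level_probability_rejected(self):
        cfg = guinea_like_population(
            sba_prob=ProbabilityMap(by={"wealth_quintile": {"Q1": 0.2}}))
        with pytest.raises(ConfigurationError):
            true_summary_measures(cfg, WEALTH, "sba")
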