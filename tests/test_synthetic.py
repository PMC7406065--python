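"""Generator contracts: hierarchy, marginals, copula dependence, census
realization, and exactness of survey design weights."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from popdensity import synthetic as syn
from popdensity.config import (
    ConfigurationError,
    CovariateSpec,
    ScenarioConfig,
    SurveyDesign,
    desk_design,
    desk_scenario,
    national_scenario,
)
from popdensity.synthetic import DesignError, copula_spearman


def small_config(**kw):
    defaults = dict(
        n_districts=3,
        n_subdistricts=8,
        n_villages=120,
        covariates=[CovariateSpec("builtup", "logitnormal", -2.0, 1.5)],
        true_alpha=np.log(100.0),
        true_beta={"builtup": 0.0},
        true_gamma={},
        noise="none",
        seed=3,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestAdminFrame:
    def test_hierarchy_counts_and_nesting(self):
        cfg = desk_scenario(seed=1)
        frame = syn.generate_admin_frame(cfg)
        assert len(frame) == cfg.n_villages
        assert frame["village_id"].is_unique
        assert frame["sub_district_id"].nunique() == cfg.n_subdistricts
        assert frame["district_id"].nunique() == cfg.n_districts
        # each sub-district maps to exactly one district
        nest = frame.groupby("sub_district_id")["district_id"].nunique()
        assert (nest == 1).all()
        assert (frame["area_km2"] > 0).all()
        np.testing.assert_array_equal(frame["log_area"], np.log(frame["area_km2"]))
        assert set(frame["sector"]) <= {"urban", "rural_estate"}

    def test_national_preset_matches_published_admin_counts(self):
        cfg = national_scenario(seed=0)
        frame = syn.generate_admin_frame(cfg)
        assert len(frame) == 13970
        assert frame["sub_district_id"].nunique() == 331
        assert frame["district_id"].nunique() == 25

    def test_degenerate_single_village(self):
        cfg = small_config(n_districts=1, n_subdistricts=1, n_villages=1)
        frame = syn.generate_admin_frame(cfg)
        assert len(frame) == 1

    def test_determinism(self):
        cfg = desk_scenario(seed=9)
        a = syn.generate_admin_frame(cfg)
        b = syn.generate_admin_frame(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(n_districts=10, n_subdistricts=5)
        with pytest.raises(ConfigurationError):
            small_config(n_villages=-3)


class TestCovariates:
    def test_bounded_family_stays_in_range(self, desk_country):
        _, frame, covars, _ = desk_country
        for col in ("builtup", "treecover"):
            assert covars[col].min() >= 0.0
            assert covars[col].max() <= 100.0

    def test_zero_variance_params_give_constant_column(self):
        cfg = small_config(
            covariates=[CovariateSpec("flat", "normal", 5.0, 0.0)],
            true_beta={"flat": 0.0},
        )
        frame = syn.generate_admin_frame(cfg)
        covars = syn.generate_covariates(frame, cfg)
        assert (covars["flat"] == 5.0).all()

    def test_copula_rank_correlation_matches_theory(self):
        # Monte-Carlo oracle: Gaussian copula with latent r = 0.6 implies
        # Spearman rho = (6/pi) asin(r/2) regardless of the marginals.
        cfg = small_config(
            n_villages=10_000,
            n_subdistricts=10,
            covariates=[
                CovariateSpec("a", "lognormal", 0.0, 1.0),
                CovariateSpec("b", "logitnormal", -1.0, 2.0),
            ],
            correlation=[[1.0, 0.6], [0.6, 1.0]],
            true_beta={},
            seed=5,
        )
        frame = syn.generate_admin_frame(cfg)
        covars = syn.generate_covariates(frame, cfg)
        rho = stats.spearmanr(covars["a"], covars["b"]).statistic
        assert rho == pytest.approx(copula_spearman(0.6), abs=0.05)

    def test_non_psd_correlation_rejected(self):
        with pytest.raises(ConfigurationError, match="positive semi-definite"):
            small_config(
                covariates=[
                    CovariateSpec("a", "normal", 0, 1),
                    CovariateSpec("b", "normal", 0, 1),
                ],
                correlation=[[1.0, 1.2], [1.2, 1.0]],
                true_beta={},
            )

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError, match="family"):
            CovariateSpec("bad", "cauchy", 0, 1)


class TestCensus:
    def test_intercept_only_noiseless_density_exact(self):
        # beta = gamma = 0, alpha = ln(100), no noise: density = 100 * area
        # rounding / area, i.e. 100 up to integer rounding of the count.
        cfg = small_config()
        frame = syn.generate_admin_frame(cfg)
        covars = syn.generate_covariates(frame, cfg)
        census = syn.generate_census(frame, covars, cfg)
        expected = np.rint(100.0 * frame["area_km2"]) / frame["area_km2"]
        np.testing.assert_allclose(census["density"], expected)

    def test_poisson_replicates_match_mean_within_3se(self):
        # One village, mu = 500 /km^2, area = 2: mean density over 2,000
        # replicate draws should sit within 3 Monte-Carlo SEs of 500.
        reps = 2000
        area = 2.0
        base = small_config(
            n_districts=1,
            n_subdistricts=1,
            n_villages=1,
            true_alpha=np.log(500.0),
            area_log_mean=np.log(area),
            area_log_sd=0.0,
            noise="poisson",
        )
        frame = syn.generate_admin_frame(base)
        covars = syn.generate_covariates(frame, base)
        densities = np.empty(reps)
        for r in range(reps):
            cfg_r = ScenarioConfig.from_dict({**base.to_dict(), "seed": r})
            densities[r] = syn.generate_census(frame, covars, cfg_r)["density"].iloc[0]
        # var(density) = mu * area / area^2; se of the replicate mean
        se = np.sqrt(500.0 * area) / area / np.sqrt(reps)
        assert abs(densities.mean() - 500.0) < 3 * se

    def test_default_scenario_right_skewed(self, desk_country):
        _, _, _, census = desk_country
        d = census["density"]
        assert d.std() > d.mean()
        assert d.skew() > 1.0

    def test_density_consistent_with_population(self, desk_country):
        _, frame, _, census = desk_country
        np.testing.assert_allclose(
            census["density"], census["population"] / frame["area_km2"]
        )

    def test_linear_predictor_overflow_names_village(self):
        cfg = small_config(true_alpha=40.0)
        frame = syn.generate_admin_frame(cfg)
        covars = syn.generate_covariates(frame, cfg)
        with pytest.raises(FloatingPointError, match="V"):
            syn.generate_census(frame, covars, cfg)


class TestSurvey:
    def test_full_enumeration_weights_are_one(self):
        cfg = small_config(n_villages=30, n_subdistricts=3, true_alpha=np.log(400))
        frame = syn.generate_admin_frame(cfg)
        covars = syn.generate_covariates(frame, cfg)
        census = syn.generate_census(frame, covars, cfg)
        design = SurveyDesign(
            village_sampling_fraction=1.0,
            households_per_psu=10_000,
            households_per_block=10_000_000,
            multi_psu_fraction=0.0,
            seed=1,
        )
        sample = syn.draw_survey(frame, covars, census, design, cfg)
        np.testing.assert_allclose(sample.households["design_weight"], 1.0)
        # census-as-survey: every household of every village enumerated
        got = sample.households.groupby("village_id")["household_size"].sum()
        want = census.set_index("village_id")["population"]
        pd.testing.assert_series_equal(
            got.sort_index(), want[want > 0].sort_index(),
            check_names=False, check_dtype=False,
        )

    def test_ht_total_unbiased_over_replicates(self):
        # brute-force HT unbiasedness: relative bias < 3 MC standard errors
        cfg = small_config(
            n_villages=150, n_subdistricts=6, true_alpha=np.log(300), noise="poisson"
        )
        frame = syn.generate_admin_frame(cfg)
        covars = syn.generate_covariates(frame, cfg)
        census = syn.generate_census(frame, covars, cfg)
        total = census["population"].sum()
        reps = 500
        estimates = np.empty(reps)
        for r in range(reps):
            design = SurveyDesign(
                village_sampling_fraction=0.2, households_per_psu=8, seed=r
            )
            s = syn.draw_survey(frame, covars, census, design, cfg)
            estimates[r] = (s.households["design_weight"] * s.households["household_size"]).sum()
        se = estimates.std(ddof=1) / np.sqrt(reps)
        assert abs(estimates.mean() - total) < 3 * se

    def test_single_psu_default_and_multi_psu_exclusion_rate(self, desk_country, desk_survey):
        cfg, frame, covars, census = desk_country
        design, sample = desk_survey
        per_village = sample.psus.groupby("village_id").size()
        multi = (per_village > 1).mean()
        assert per_village.max() <= 2
        assert 0.0 <= multi <= 0.10  # around the 3% design rate

    def test_tilted_sampling_shifts_covariate_mean(self, desk_country):
        cfg, frame, covars, census = desk_country
        design = desk_design(seed=3, tilt={"builtup": 1.0})
        sample = syn.draw_survey(frame, covars, census, design, cfg)
        sampled = covars.set_index("village_id").loc[sample.sampled_villages, "builtup"]
        assert sampled.mean() > covars["builtup"].mean()

    def test_weights_are_exact_inverse_inclusion_probs(self, desk_country):
        cfg, frame, covars, census = desk_country
        design = desk_design(seed=11)
        sample = syn.draw_survey(frame, covars, census, design, cfg)
        probs = syn.village_inclusion_probs(frame, covars, census, design)
        pi_v = probs.set_index("village_id")["pi"]
        merged = sample.psus.set_index("psu_id")
        # village_prob recorded in metadata equals the design probability
        np.testing.assert_allclose(
            merged["village_prob"].to_numpy(),
            pi_v.reindex(merged["village_id"]).to_numpy(),
        )

    def test_oversized_stratum_request_rejected(self):
        cfg = small_config(
            n_districts=2, n_subdistricts=2, n_villages=20, true_alpha=np.log(200)
        )
        frame = syn.generate_admin_frame(cfg)
        covars = syn.generate_covariates(frame, cfg)
        census = syn.generate_census(frame, covars, cfg)
        strata = frame["district_id"] + ":" + frame["sector"]
        design = SurveyDesign(
            village_sampling_fraction=0.5,
            stratum_sample_sizes={s: 10_000 for s in strata.unique()},
            seed=0,
        )
        with pytest.raises(DesignError, match="requested"):
            syn.draw_survey(frame, covars, census, design, cfg)
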