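import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.regression.mixed_linear_model import MixedLM

import statsmodels.api as sm

from thermoresp import models
from conftest import simulate_lmm_points


class TestAICc:
    @pytest.mark.parametrize("loglik,k,n,expected", [
        (13.147, 4, 37, -17.04),   # cooling-efficiency top model
        (-17.759, 4, 57, 44.29),   # body-temperature top model
        (13.910, 5, 37, -15.88),   # cooling-efficiency runner-up
    ])
    def test_small_sample_identity(self, loglik, k, n, expected):
        assert models.aicc(loglik, k, n) == pytest.approx(expected, abs=0.01)

    def test_reduces_to_aic_for_large_n(self):
        assert models.aicc(-10.0, 4, 10**9) == pytest.approx(20.0 + 8.0,
                                                             abs=1e-6)

    def test_penalty_increasing_in_k(self):
        assert models.aicc(0.0, 5, 40) > models.aicc(0.0, 4, 40)

    def test_decreasing_in_loglik(self):
        assert models.aicc(10.0, 4, 40) < models.aicc(9.0, 4, 40)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            models.aicc(0.0, 4, 5)


class TestAkaikeWeights:
    def test_published_pair(self):
        w = models.akaike_weights([-17.04, -15.88])
        assert w[0] == pytest.approx(0.641, abs=5e-4)
        assert w[1] == pytest.approx(0.359, abs=5e-4)

    def test_wide_gap_pair(self):
        w = models.akaike_weights([44.29, 49.82])
        assert w[0] == pytest.approx(0.941, abs=1e-3)
        assert w[1] == pytest.approx(0.059, abs=1e-3)

    def test_single_model(self):
        assert models.akaike_weights([123.4]) == pytest.approx([1.0])

    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=8))
    def test_sum_to_one_and_renormalization_preserves_ratios(self, vals):
        w = models.akaike_weights(vals)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        if len(vals) > 2 and w[1] > 1e-12 and w[2] > 1e-12:
            w2 = models.akaike_weights(vals[1:])
            assert w2[0] / w2[1] == pytest.approx(w[1] / w[2], rel=1e-6)


class TestFitLMM:
    def test_no_group_structure_reduces_to_ols(self):
        df = simulate_lmm_points(0, n_birds=25, intercept_sd=0.0)
        ours = models.fit_lmm(df, "y", ("Ta",))
        X = sm.add_constant(df["Ta_C"].to_numpy())
        ols = sm.OLS(df["y"].to_numpy(), X).fit()
        assert ours.estimates["Ta"]["beta"] == pytest.approx(ols.params[1],
                                                             abs=1e-3)
        assert ours.boundary  # RE variance pinned at zero is flagged

    def test_slope_recovered_within_two_se(self):
        """Parameter recovery at the body-temperature scale (slope 0.299,
        ~57 observations): nominal ~95% of draws land within 2 SE."""
        hits = 0
        n_sims = 50
        for seed in range(n_sims):
            df = simulate_lmm_points(seed, n_birds=19, ta_values=(35, 39, 43))
            est = models.fit_lmm(df, "y", ("Ta",)).estimates["Ta"]
            hits += abs(est["beta"] - 0.299) <= 2 * est["se"]
        assert hits / n_sims >= 0.88

    def test_too_few_birds_rejected(self):
        df = simulate_lmm_points(0, n_birds=1)
        with pytest.raises(ValueError):
            models.fit_lmm(df, "y", ("Ta",))


class TestDredge:
    def test_candidate_set_respects_marginality(self):
        assert len(models.CANDIDATE_TERMS) == 5
        for terms in models.CANDIDATE_TERMS:
            if "Ta:Mb" in terms:
                assert {"Ta", "Mb"} <= set(terms)

    def test_strong_ta_effect_selects_ta_model(self):
        df = simulate_lmm_points(3, n_birds=19, ta_values=(35, 37, 39, 41, 43))
        tab = models.dredge(df, "y")
        assert tab.rows[0].terms == ("Ta",)
        assert tab.rows[0].delta_aicc == 0.0
        assert sum(m.weight for m in tab.rows) == pytest.approx(1.0, abs=1e-9)
        assert tab.retained  # the delta < 8 set is never empty

    def test_pure_noise_prefers_intercept_only(self):
        wins = 0
        for seed in range(11):
            df = simulate_lmm_points(seed, n_birds=15, slope=0.0,
                                     intercept_sd=0.0, residual_sd=1.0)
            tab = models.dredge(df, "y")
            wins += tab.rows[0].terms == ()
        assert wins > 5

    def test_mass_effect_is_detectable_when_present(self):
        df = simulate_lmm_points(1, n_birds=25, mass_slope=0.5,
                                 intercept_sd=0.05)
        tab = models.dredge(df, "y")
        assert "Mb" in tab.rows[0].terms


class TestCooksDistance:
    def test_matches_explicit_leave_one_out_oracle(self):
        df = simulate_lmm_points(2, n_birds=6, ta_values=(35, 39, 43))
        ours = models.cooks_distance_by_bird(df, "y", ("Ta",))
        # independent computation straight from the definition
        X = pd.DataFrame({"Intercept": 1.0, "Ta": df["Ta_C"].to_numpy()})
        full = MixedLM(df["y"].to_numpy(), X,
                       groups=df["bird_id"].to_numpy()).fit(reml=False)
        cov_inv = np.linalg.pinv(np.asarray(full.cov_params())[:2, :2])
        for bird in df.bird_id.unique():
            sub = df[df.bird_id != bird]
            Xs = pd.DataFrame({"Intercept": 1.0, "Ta": sub["Ta_C"].to_numpy()})
            part = MixedLM(sub["y"].to_numpy(), Xs,
                           groups=sub["bird_id"].to_numpy()).fit(reml=False)
            d = full.fe_params.to_numpy() - part.fe_params.to_numpy()
            oracle = float(d @ cov_inv @ d / 2)
            assert ours[bird] == pytest.approx(oracle, rel=1e-4, abs=1e-8)

    def test_homogeneous_birds_all_below_one(self):
        df = simulate_lmm_points(6, n_birds=10)
        assert (models.cooks_distance_by_bird(df, "y", ("Ta",)) < 1.0).all()

    def test_aberrant_bird_flagged(self):
        """A bird with a grossly deviant thermal response dominates the
        influence ranking and crosses the D > 1 threshold."""
        df = simulate_lmm_points(5, n_birds=10)
        sel = df.bird_id == "b003"
        df.loc[sel, "y"] += 1.0 * (df.loc[sel, "Ta_C"] - 39.0)
        cd = models.cooks_distance_by_bird(df, "y", ("Ta",))
        assert cd.idxmax() == "b003"
        assert cd["b003"] > 1.0
        assert (cd.drop("b003") < 1.0).all()

    def test_deterministic(self):
        df = simulate_lmm_points(4, n_birds=6)
        a = models.cooks_distance_by_bird(df, "y", ("Ta",))
        b = models.cooks_distance_by_bird(df, "y", ("Ta",))
        pd.testing.assert_series_equal(a, b)


class TestRobustFit:
    def test_reduces_to_ml_without_outliers(self):
        df = simulate_lmm_points(0, n_birds=30)
        ml = models.fit_lmm(df, "y", ("Ta",))
        rb = models.robust_fit(df, "y", ("Ta",))
        for term in ("Intercept", "Ta"):
            assert rb.estimates[term]["beta"] == pytest.approx(
                ml.estimates[term]["beta"], rel=0.01)
        assert rb.robust

    def test_resists_gross_contamination(self):
        """5% gross outliers: the Huber refit lands closer to the true slope
        than plain ML in the large majority of draws (scaled-down count)."""
        wins = 0
        n_sims = 20
        for seed in range(n_sims):
            df = simulate_lmm_points(seed)
            rng = np.random.default_rng(1000 + seed)
            idx = rng.choice(len(df), max(1, len(df) // 20), replace=False)
            df.loc[idx, "y"] += 8.0
            ml = models.fit_lmm(df, "y", ("Ta",)).estimates["Ta"]["beta"]
            rb = models.robust_fit(df, "y", ("Ta",)).estimates["Ta"]["beta"]
            wins += abs(rb - 0.299) < abs(ml - 0.299)
        assert wins / n_sims >= 0.8

    def test_deterministic(self):
        df = simulate_lmm_points(9)
        a = models.robust_fit(df, "y", ("Ta",))
        b = models.robust_fit(df, "y", ("Ta",))
        assert a.estimates == b.estimates


class TestFoldChanges:
    def test_reported_bin_means(self):
        assert models.fold_ratio(0.588, 0.804) == 1.4   # metabolic rate
        assert models.fold_ratio(0.348, 0.960) == 2.8   # cooling efficiency

    def test_constant_trait_is_one_fold(self):
        df = pd.DataFrame({"Ta_C": [26.0, 26.5, 42.5, 43.0],
                           "rmr_W": [0.6, 0.6, 0.6, 0.6]})
        fc = models.fold_changes(df, "rmr_W")
        assert fc.ratio_rounded == 1.0

    def test_empty_bin_rejected(self):
        df = pd.DataFrame({"Ta_C": [30.0, 31.0], "rmr_W": [0.6, 0.7]})
        with pytest.raises(ValueError):
            models.fold_changes(df, "rmr_W")


class TestHeatResponseModel:
    def test_end_to_end_on_simulated_study(self, study_points):
        res = models.HeatResponseModel(study_points, "Tb_C").fit(grid=0.05)
        assert 30.0 < res.breakpoint.psi < 35.0
        assert res.top.terms in models.CANDIDATE_TERMS
        assert res.n_above == (study_points.Ta_C > res.breakpoint.psi).sum()
        assert not res.cooks.isna().any()
        text = res.summary()
        assert "breakpoint" in text and "Model selection" in text

    def test_missing_column_rejected(self, study_points):
        with pytest.raises(ValueError, match="column"):
            models.HeatResponseModel(study_points.drop(columns=["mass_g"]),
                                     "Tb_C")
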