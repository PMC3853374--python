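import numpy as np
import pandas as pd
import pytest

import periquant as pq
from oracles import breslow_partial_loglik


def frame(time, event, **cols):
    return pd.DataFrame({"time": time, "event": event, **cols})


class TestKaplanMeier:
    def test_no_censoring_reduces_to_ecdf(self):
        df = frame(np.arange(1.0, 10.0), np.ones(9, dtype=int))
        km = pq.km_estimate(df)
        assert km.median == pytest.approx(5.0)
        # S(t) at each event time = 1 - ECDF
        for t, s in zip(km.times[1:], km.survival[1:]):
            assert s == pytest.approx(1.0 - np.mean(np.arange(1.0, 10.0) <= t))

    def test_all_censored_flat_curve_median_undefined(self):
        df = frame(np.arange(1.0, 6.0), np.zeros(5, dtype=int))
        km = pq.km_estimate(df)
        assert not km.median_defined and km.median is None
        assert np.all(km.survival == 1.0)

    def test_exponential_median_recovery(self):
        lam = np.log(2) / 48.0
        rng = np.random.default_rng(12)
        t = rng.exponential(1 / lam, size=2000)
        km = pq.km_estimate(frame(t, np.ones(2000, dtype=int)))
        assert km.median == pytest.approx(48.0, rel=0.05)
        lo, hi = km.median_ci
        assert lo < km.median < hi

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            pq.km_estimate(frame([0.0, 1.0], [1, 1]))


class TestGroupTTest:
    def test_identical_groups_give_t0_p1(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        df = pd.DataFrame(
            {"residual_gt_0_5cm": [0] * 4 + [1] * 4, "volume": vals}
        )
        t, p = pq.group_ttest(df, "volume")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "residual_gt_0_5cm": [0] * 50 + [1] * 50,
                    "volume": rng.normal(size=100),
                }
            )
            _, p = pq.group_ttest(df, "volume")
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_for_one_sd_shift(self):
        rng = np.random.default_rng(7)
        hits = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "residual_gt_0_5cm": [0] * 50 + [1] * 50,
                    "volume": np.concatenate(
                        [rng.normal(size=50), rng.normal(1.0, 1.0, size=50)]
                    ),
                }
            )
            _, p = pq.group_ttest(df, "volume")
            hits += p < 0.05
        assert hits / reps > 0.99

    def test_tiny_group_rejected(self):
        df = pd.DataFrame({"residual_gt_0_5cm": [0, 0, 1], "volume": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            pq.group_ttest(df, "volume")


class TestCox:
    def test_partial_likelihood_matches_brute_force_risk_sets(self):
        rng = np.random.default_rng(21)
        for trial in range(5):
            n = 20
            x = rng.normal(size=n)
            t = rng.integers(1, 8, size=n).astype(float)  # heavy ties
            e = rng.random(n) < 0.7
            if e.sum() == 0:
                e[0] = True
            df = frame(t, e.astype(int), x=x)
            fit = pq.cox_fit(df, ["x"], ties="breslow")
            beta = np.array([fit["x"].coef])
            assert fit.log_likelihood == pytest.approx(
                breslow_partial_loglik(t, e, x, beta), abs=1e-8
            )
            assert fit.null_log_likelihood == pytest.approx(
                breslow_partial_loglik(t, e, x, np.zeros(1)), abs=1e-8
            )

    def test_parameter_recovery_binary_hr2(self):
        p = pq.CohortParams(n=2000, cox_betas={"residual_gt_0_5cm": np.log(2)}, censor_frac=0.3)
        df = pq.simulate_cohort(p, 4)
        fit = pq.cox_fit(df, ["residual_gt_0_5cm"])
        eff = fit["residual_gt_0_5cm"]
        assert abs(eff.coef - np.log(2)) < 2 * eff.se
        assert eff.ci_low < eff.hazard_ratio < eff.ci_high
        assert eff.hazard_ratio == pytest.approx(np.exp(eff.coef))

    def test_constant_covariate_rejected(self):
        df = frame([1.0, 2.0, 3.0], [1, 1, 1], x=[0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="constant"):
            pq.cox_fit(df, ["x"])

    def test_no_events_rejected(self):
        df = frame([1.0, 2.0], [0, 0], x=[0.0, 1.0])
        with pytest.raises(ValueError, match="event"):
            pq.cox_fit(df, ["x"])


class TestScreen:
    def test_only_signal_covariate_joins_forced_metrics(self):
        p = pq.CohortParams(n=300, cox_betas={"age": 0.08}, censor_frac=0.2)
        df = pq.simulate_cohort(p, 15)
        res = pq.screen_then_multivariate(df, ["age", "female", "biphasic", "bsa"])
        assert res.univariate_p["age"] < 0.1
        assert res.selected == ["age"]
        assert set(res.fit.covariates) == {"volume", "surface_area", "age"}

    def test_screen_alpha_one_includes_all_candidates(self):
        p = pq.CohortParams(n=200)
        df = pq.simulate_cohort(p, 2)
        res = pq.screen_then_multivariate(df, ["age", "female", "bsa"], screen_alpha=1.0)
        assert set(res.fit.covariates) == {"volume", "surface_area", "age", "female", "bsa"}

    def test_null_candidates_usually_leave_only_forced(self):
        kept_extra = 0
        for seed in range(10):
            df = pq.simulate_cohort(pq.CohortParams(n=38), seed)
            res = pq.screen_then_multivariate(df, ["age", "female", "bsa"])
            kept_extra += bool(res.selected)
        assert kept_extra <= 5  # majority of null seeds keep only volume + surface area


class TestPerSDHazardRatio:
    def make_fit(self, coef, se=0.1):
        eff = pq.cohort_stats.CovariateEffect(
            coef=coef, se=se, hazard_ratio=np.exp(coef),
            ci_low=np.exp(coef - 1.96 * se), ci_high=np.exp(coef + 1.96 * se), p=0.5,
        )
        return pq.CoxFit(
            covariates={"x": eff}, log_likelihood=0.0, null_log_likelihood=0.0,
            lr_statistic=0.0, lr_df=1, global_p=1.0, ties="breslow", n=10, n_events=5,
        )

    def test_zero_coefficient_gives_unit_hr(self):
        hr, _ = pq.per_sd_hazard_ratio(self.make_fit(0.0), "x", 1234.5)
        assert hr == 1.0

    def test_log2_coefficient_unit_sd(self):
        hr, _ = pq.per_sd_hazard_ratio(self.make_fit(np.log(2)), "x", 1.0)
        assert hr == pytest.approx(2.0)

    def test_small_per_unit_coefficient_large_sd(self):
        # rounded per-unit HRs near 1.000 hide effects that are large per SD
        hr, _ = pq.per_sd_hazard_ratio(self.make_fit(-0.001), "x", 1158.5)
        assert hr == pytest.approx(np.exp(-1.1585), rel=1e-9)
        assert hr == pytest.approx(0.314, abs=0.001)

    def test_sign_reciprocal_product_is_one(self):
        for coef, sd in [(0.3, 2.0), (-0.4, 532.0), (0.004, 1158.5)]:
            hr_pos, _ = pq.per_sd_hazard_ratio(self.make_fit(coef), "x", sd)
            hr_neg, _ = pq.per_sd_hazard_ratio(self.make_fit(-coef), "x", sd)
            assert hr_pos * hr_neg == pytest.approx(1.0, rel=1e-12)

    def test_absent_covariate_rejected(self):
        with pytest.raises(KeyError):
            pq.per_sd_hazard_ratio(self.make_fit(0.0), "y", 1.0)


class TestGfrRegression:
    def test_noiseless_data_recovered_exactly(self):
        p = pq.CohortParams(n=120, gfr_noise_sd=0.0)
        df = pq.simulate_cohort(p, 8)
        fit = pq.gfr_regression(df)
        truth = p.gfr_coefs
        for name in ("pre_gfr", "bsa", "volume", "surface_area"):
            assert fit.params[name] == pytest.approx(truth[name], abs=1e-6)
        assert fit.retained_interactions == ["bsa_x_volume"]
        assert fit.params["bsa_x_volume"] == pytest.approx(-0.07, abs=1e-6)

    def test_noisy_recovery_within_two_se_and_retention(self):
        p = pq.CohortParams(n=500, gfr_noise_sd=10.0)
        df = pq.simulate_cohort(p, 19)
        fit = pq.gfr_regression(df)
        assert "bsa_x_volume" in fit.retained_interactions
        assert "bsa_x_surface_area" not in fit.retained_interactions

    def test_prediction_matches_linear_predictor(self):
        p = pq.CohortParams(n=200, gfr_noise_sd=0.0)
        df = pq.simulate_cohort(p, 30)
        fit = pq.gfr_regression(df)
        row = df.iloc[0]
        pred = pq.predict_post_gfr(fit, row.pre_gfr, row.bsa, row.volume, row.surface_area)
        assert pred == pytest.approx(row.post_gfr, abs=1e-6)

    def test_scenario_difference_is_linear_in_volume(self):
        p = pq.CohortParams(n=300, gfr_noise_sd=5.0)
        fit = pq.gfr_regression(pq.simulate_cohort(p, 40))
        bsa = 1.92
        dv = 532.0
        d = pq.predict_post_gfr(fit, 100, bsa, 558.4 + dv, 1261.7) - pq.predict_post_gfr(
            fit, 100, bsa, 558.4, 1261.7
        )
        beta_int = fit.params.get("bsa_x_volume", 0.0) if "bsa_x_volume" in fit.retained_interactions else 0.0
        assert d == pytest.approx((fit.params["volume"] + beta_int * bsa) * dv, rel=1e-9)


class TestSimulateCohort:
    def test_zero_censoring_gives_all_events(self):
        df = pq.simulate_cohort(pq.CohortParams(n=100, censor_frac=0.0), 1)
        assert df.event.all()

    def test_deterministic_given_seed(self):
        p = pq.CohortParams(n=50)
        pd.testing.assert_frame_equal(pq.simulate_cohort(p, 77), pq.simulate_cohort(p, 77))

    def test_marginals_match_configured_means(self):
        df = pq.simulate_cohort(pq.CohortParams(n=20000), 5)
        assert df.volume.mean() == pytest.approx(558.4, rel=0.05)
        assert df.volume.std() == pytest.approx(532.0, rel=0.1)
        assert df.surface_area.mean() == pytest.approx(1261.7, rel=0.05)
        assert df.bsa.mean() == pytest.approx(1.92, rel=0.02)

    def test_null_betas_make_km_median_independent_of_strata(self):
        df = pq.simulate_cohort(pq.CohortParams(n=8000, censor_frac=0.0), 3)
        med_hi = pq.km_estimate(df[df.residual_gt_0_5cm == 1]).median
        med_lo = pq.km_estimate(df[df.residual_gt_0_5cm == 0]).median
        assert med_hi == pytest.approx(med_lo, rel=0.1)
        assert med_hi == pytest.approx(48.0, rel=0.1)


def test_bsa_auc_slope_recovery():
    rng = np.random.default_rng(0)
    bsa = rng.normal(1.92, 0.25, size=200)
    auc = 400.0 - 89.7 * bsa + rng.normal(0, 10, size=200)
    slope, p = pq.bsa_auc_regression(pd.DataFrame({"bsa": bsa, "auc": auc}))
    assert slope == pytest.approx(-89.7, rel=0.05)
    assert p < 0.001
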