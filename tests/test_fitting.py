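"""Estimation machinery: SSR assembly, F-tests, pooling, fits, CIs."""

from dataclasses import replace

import numpy as np
import pytest

from tscmdyn.fitting import (
    FitConfig,
    combined_ssr,
    confidence_intervals,
    constrained_fit,
    f_test_nested,
    fit_model,
    homogeneity_test,
    k_scan,
    pool_pvalues,
)
from tscmdyn.label_models import ImplicitModelParams
from tscmdyn.synth import StudyDesign, simulate_fit_data
from tscmdyn.telomere import TelomereParams

LN2 = np.log(2.0)


@pytest.fixture
def noise_free_data(truth, design):
    d = simulate_fit_data(
        ImplicitModelParams(p_n=5e-4, p_s=0.01, Delta=0.01 / 32, k=5, c=4.0, ds_star=0.03),
        truth.water,
        TelomereParams(C=0.0),
        replace(design, label_sd=0.0, theta_sd=1e-12),
        np.random.default_rng(0),
    )
    d.label_sd, d.theta_sd = 5e-4, 150.0  # weights as in the study
    return d


@pytest.fixture
def noisy_data(truth, design):
    return simulate_fit_data(
        ImplicitModelParams(p_n=5e-4, p_s=0.01, Delta=0.01 / 32, k=5, c=4.0, ds_star=0.03),
        truth.water,
        TelomereParams(C=0.0),
        design,
        np.random.default_rng(42),
    )


TRUTH_IMPL = ImplicitModelParams(p_n=5e-4, p_s=0.01, Delta=0.01 / 32, k=5, c=4.0, ds_star=0.03)
CFG = FitConfig(variant="implicit", C_mode="zero", c_fixed=4.0, n_starts=3, seed=0)


class TestCombinedSSR:
    def test_truth_on_noise_free_data_is_zero(self, noise_free_data):
        ssr, comps = combined_ssr(TRUTH_IMPL, TelomereParams(C=0.0), CFG, noise_free_data)
        assert ssr == pytest.approx(0.0, abs=1e-12)
        assert set(comps) == {"label", "telomere"}

    def test_equal_weights_is_plain_ssr(self, noisy_data):
        cfg = replace(CFG, weighting="equal", datasets=("label",))
        ssr, _ = combined_ssr(TRUTH_IMPL, TelomereParams(C=0.0), cfg, noisy_data)
        from tscmdyn.fitting import _predict

        pred = _predict(TRUTH_IMPL, TelomereParams(C=0.0), None, cfg, noisy_data)
        raw = np.sum((pred["label_naive"] - noisy_data.naive_frac) ** 2) + np.sum(
            (pred["label_tscm"] - noisy_data.tscm_frac) ** 2
        )
        assert ssr == pytest.approx(raw, rel=1e-12)

    def test_count_variance_equals_ssr_over_n_sigma2(self, noisy_data):
        telo = TelomereParams(C=0.0)
        eq = replace(CFG, weighting="equal")
        cv = replace(CFG, weighting="count_variance")
        _, comps_eq = combined_ssr(TRUTH_IMPL, telo, eq, noisy_data)
        _, comps_cv = combined_ssr(TRUTH_IMPL, telo, cv, noisy_data)
        n_label = noisy_data.naive_times.size + noisy_data.tscm_times.size
        assert comps_cv["label"] == pytest.approx(
            comps_eq["label"] / (n_label * noisy_data.label_sd**2), rel=1e-12
        )
        assert comps_cv["telomere"] == pytest.approx(
            comps_eq["telomere"] / noisy_data.theta_sd**2, rel=1e-12
        )


class TestFTest:
    def test_equal_ssr_gives_p_one(self):
        res = f_test_nested(1.0, 1.0, 20, 4, 5)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_frozen_example(self):
        # F = ((2-1)/1)/(1/15) = 15 on F(1, 15)
        res = f_test_nested(2.0, 1.0, 20, 4, 5)
        assert res.statistic == pytest.approx(15.0)
        assert res.p_value == pytest.approx(0.00146, abs=5e-5)

    @pytest.mark.parametrize(
        "args",
        [
            (0.5, 1.0, 20, 4, 5),  # reduced better than full
            (2.0, 1.0, 20, 5, 5),  # no extra parameters
            (2.0, 1.0, 5, 4, 5),  # too few points
        ],
    )
    def test_precondition_violations(self, args):
        with pytest.raises(ValueError):
            f_test_nested(*args)


class TestPooling:
    def test_all_ones(self):
        assert pool_pvalues([1.0, 1.0, 1.0]).pooled_p == pytest.approx(1.0)

    def test_frozen_example(self):
        res = pool_pvalues([0.5, 0.5])
        assert res.statistic == pytest.approx(2.7726, abs=1e-4)
        assert res.pooled_p == pytest.approx(0.597, abs=1e-3)

    def test_single_p_unchanged(self):
        assert pool_pvalues([0.037]).pooled_p == pytest.approx(0.037, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pool_pvalues([])


class TestFitModel:
    def test_noise_free_recovers_truth(self, noise_free_data):
        fit = fit_model(replace(CFG, n_starts=6), noise_free_data)
        assert fit.ssr < 1e-10
        assert fit.params["ds_star"] == pytest.approx(0.03, rel=1e-3)
        assert fit.params["p_n"] == pytest.approx(5e-4, rel=1e-3)

    def test_refit_from_optimum_is_fixed_point(self, noisy_data):
        fit = fit_model(CFG, noisy_data)
        refit = fit_model(CFG, noisy_data, starts_override=[dict(fit.params)])
        assert refit.ssr == pytest.approx(fit.ssr, rel=1e-8)

    def test_seeded_reproducibility(self, noisy_data):
        a = fit_model(CFG, noisy_data)
        b = fit_model(CFG, noisy_data)
        assert a.ssr == b.ssr
        assert a.params == b.params

    def test_all_starts_logged(self, noisy_data):
        fit = fit_model(CFG, noisy_data)
        assert len(fit.starts) == CFG.n_starts
        assert all("ssr" in s for s in fit.starts)

    def test_yfv_requires_explicit_model(self, truth, design):
        d = simulate_fit_data(
            truth.kinetics, truth.water, truth.telomere, design,
            np.random.default_rng(1), include_yfv=True,
        )
        with pytest.raises(ValueError, match="explicit"):
            fit_model(replace(CFG, datasets=("label", "telomere", "yfv")), d)

    def test_missing_yfv_fails_fast(self, noisy_data):
        with pytest.raises(ValueError, match="vaccine"):
            fit_model(
                replace(CFG, variant="explicit", datasets=("label", "telomere", "yfv")),
                noisy_data,
            )

    def test_explicit_orders_subpopulations(self, truth, design):
        d = simulate_fit_data(
            truth.kinetics, truth.water, truth.telomere, design,
            np.random.default_rng(3), include_yfv=True,
        )
        cfg = FitConfig(
            variant="explicit", datasets=("label", "telomere", "yfv"),
            c_fixed=4.0, n_starts=6, seed=1,
        )
        fit = fit_model(cfg, d)
        assert fit.derived["half_life_1_years"] <= fit.derived["half_life_2_years"]


class TestHomogeneityTest:
    def test_nesting_holds_and_p_in_unit_interval(self, noisy_data):
        ht = homogeneity_test(CFG, noisy_data)
        assert ht.fit_reduced.ssr >= min(ht.fit_full.ssr, ht.fit_reduced.ssr)
        assert 0.0 <= ht.p_value <= 1.0
        assert ht.fit_full.n_free == ht.fit_reduced.n_free + 1

    def test_naive_pool_variant(self, noisy_data):
        ht = homogeneity_test(CFG, noisy_data, pool="naive")
        assert ht.fit_full.n_free == ht.fit_reduced.n_free + 1
        assert 0.0 <= ht.p_value <= 1.0


class TestKScan:
    def test_single_k_reduces_to_fit_model(self, noisy_data):
        table = k_scan(CFG, noisy_data, ks=[5])
        fit = fit_model(replace(CFG, k=5), noisy_data)
        assert table.loc[0, "ssr"] == pytest.approx(fit.ssr)

    def test_ssr_profile_flat_in_k(self, noisy_data):
        # the clonal burst size is not identifiable: above k ~ 2 the fit
        # quality is independent of k (the burst enters the observables
        # only through amplified products the other parameters absorb)
        table = k_scan(replace(CFG, n_starts=3), noisy_data, ks=[2, 5, 8, 12, 16, 20])
        ssr = table["ssr"].to_numpy()
        assert (ssr.max() - ssr.min()) / ssr.min() < 0.05

    def test_half_life_column_is_definitional(self, noisy_data):
        table = k_scan(CFG, noisy_data, ks=[2, 5])
        # ln2/(d_s - p_s) with d_s - p_s = d_s * fraction_from_naive
        expect = LN2 / (
            table["d_s_per_day"] * table["fraction_from_naive"]
        ) / 365.25
        assert np.allclose(table["clonal_half_life_years"], expect, rtol=1e-10)
        assert set(table["k"]) == {2, 5}
        assert np.all(table["precursor_lifespan_days"] > 0)


class TestConstrainedFit:
    def test_interval_containing_optimum_changes_nothing(self, truth, design):
        d = simulate_fit_data(
            truth.kinetics, truth.water, truth.telomere, design,
            np.random.default_rng(4),
        )
        cfg = FitConfig(variant="explicit", datasets=("label", "telomere"),
                        c_fixed=4.0, n_starts=4, seed=2)
        rep = constrained_fit(cfg, d, min_halflife_years=0.01, max_halflife_years=80.0)
        assert not rep.constraint_binding
        assert rep.compatible
        assert rep.fit_constrained.ssr == pytest.approx(rep.fit_unconstrained.ssr, rel=1e-4)

    def test_requires_explicit_variant(self, noisy_data):
        with pytest.raises(ValueError, match="explicit"):
            constrained_fit(CFG, noisy_data)


class TestConfidenceIntervals:
    def test_noise_free_ci_collapses(self, truth, design):
        d = simulate_fit_data(
            TRUTH_IMPL, truth.water, TelomereParams(C=0.0),
            replace(design, label_sd=0.0, theta_sd=1e-12),
            np.random.default_rng(0),
        )
        d.label_sd, d.theta_sd = 1e-10, 1e-6  # resimulated noise is negligible
        fit = fit_model(CFG, d)
        ci = confidence_intervals(fit, d, n_boot=10, seed=1)
        lo, hi = ci.intervals["ds_star"]
        assert hi - lo < 1e-4 * fit.params["ds_star"]

    def test_intervals_contain_point_estimate(self, noisy_data):
        fit = fit_model(CFG, noisy_data)
        ci = confidence_intervals(fit, noisy_data, n_boot=30, seed=2)
        for name in ("ds_star", "p_n"):
            lo, hi = ci.intervals[name]
            assert lo <= fit.params[name] <= hi

    def test_derived_half_life_interval_is_transform_of_draws(self, noisy_data):
        fit = fit_model(CFG, noisy_data)
        ci = confidence_intervals(fit, noisy_data, n_boot=30, seed=3)
        d_s = ci.draws["d_s_per_day"]
        p_s = ci.draws["p_s"]
        hl = LN2 / (d_s - p_s) / 365.25
        assert np.allclose(np.sort(hl), np.sort(ci.draws["clonal_half_life_years"]), rtol=1e-10)

    def test_profile_mode_brackets_estimate(self, noisy_data):
        fit = fit_model(CFG, noisy_data)
        ci = confidence_intervals(fit, noisy_data, method="profile", profile_param="ds_star")
        lo, hi = ci.intervals["ds_star"]
        assert lo <= fit.params["ds_star"] <= hi
        assert hi > lo


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"variant": "nonsense"},
            {"datasets": ()},
            {"datasets": ("label", "bogus")},
            {"weighting": "bogus"},
            {"k": 21},
            {"C_mode": "sometimes"},
            {"n_starts": 0},
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            FitConfig(**kw)
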