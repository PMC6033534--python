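"""Label-fraction ODE models: closed-form checks, oracles, degeneracies."""

import numpy as np
import pytest

from tscmdyn.label_models import (
    ExplicitModelParams,
    ImplicitModelParams,
    derived_bulk_rates,
    solve_label_euler,
    solve_label_explicit,
    solve_label_implicit,
)
from tscmdyn.water import BodyWaterParams

from conftest import random_explicit, random_implicit


def constant_water(u):
    """U(t) identically u: plateau equals baseline, cessation far away."""
    return BodyWaterParams(f_r=u, delta_w=1.0, beta_s=u, tau=1e6)


class TestImplicitSolver:
    def test_naive_closed_form_constant_forcing(self):
        # dF/dt = p_n (c u - F) => F(t) = c u (1 - e^{-p_n t}); c u = 0.1
        p = ImplicitModelParams(p_n=0.01, p_s=0.0, Delta=0.0, k=5, c=2.0, ds_star=0.02)
        pred = solve_label_implicit(p, constant_water(0.05), [100.0])
        assert pred.F_TN[0] == pytest.approx(0.1 * (1 - np.exp(-1.0)), rel=1e-9)
        assert pred.F_TN[0] == pytest.approx(0.0632121, abs=1e-6)

    def test_no_influx_stays_zero(self):
        p = ImplicitModelParams(p_n=0.0, p_s=0.0, Delta=0.0, k=3, c=1.0, ds_star=0.01)
        pred = solve_label_implicit(p, constant_water(0.05), np.linspace(0, 300, 7))
        assert np.allclose(pred.F_TN, 0.0, atol=1e-14)
        assert np.allclose(pred.F_TSCM, 0.0, atol=1e-14)

    def test_homogeneous_saturates_at_cu(self):
        p = ImplicitModelParams(p_n=0.01, p_s=0.005, Delta=3e-4, k=5, c=2.0)  # ds_star derived
        pred = solve_label_implicit(p, constant_water(0.05), [3000.0])
        assert pred.F_TSCM[0] == pytest.approx(2.0 * 0.05, rel=1e-6)

    def test_initial_condition_zero(self, water, implicit_params):
        pred = solve_label_implicit(implicit_params, water, [0.0, 10.0])
        assert pred.F_TN[0] == pytest.approx(0.0, abs=1e-12)
        assert pred.F_TSCM[0] == pytest.approx(0.0, abs=1e-12)

    def test_fractions_bounded_by_c_fr(self, water, label_times):
        # the bound F <= c f_r is guaranteed when labelled DNA is lost at
        # least as fast as bulk replacement (ds* >= d_s, the heterogeneity
        # direction observed in practice); draws respect that ordering
        rng = np.random.default_rng(0)
        for _ in range(20):
            base = random_implicit(rng)
            from dataclasses import replace

            p = replace(base, ds_star=base.d_s * rng.uniform(1.0, 3.0))
            pred = solve_label_implicit(p, water, label_times)
            bound = p.c * water.f_r * (1 + 1e-9)
            assert np.all(pred.F_TN >= -1e-12) and np.all(pred.F_TN <= bound)
            assert np.all(pred.F_TSCM >= -1e-12) and np.all(pred.F_TSCM <= bound)

    def test_negative_times_rejected(self, water, implicit_params):
        with pytest.raises(ValueError):
            solve_label_implicit(implicit_params, water, [-1.0, 5.0])


class TestExplicitSolver:
    def test_identical_subpopulations_collapse_to_implicit(self, water, label_times):
        ex = ExplicitModelParams(
            p_n=5e-4, p_s1=0.01, d_s1=0.03, p_s2=0.01, d_s2=0.03, f=0.3, Delta=1e-5, k=5, c=4.0
        )
        # matched one-pool parameters: same loss, delta*ratio from the steady state
        im = ImplicitModelParams(
            p_n=5e-4, p_s=0.01, Delta=(0.03 - 0.01) / 2**5, k=5, c=4.0, ds_star=0.03
        )
        pe = solve_label_explicit(ex, water, label_times)
        pi = solve_label_implicit(im, water, label_times)
        assert np.allclose(pe.F_TSCM, pi.F_TSCM, rtol=1e-9)
        assert np.allclose(pe.F_TSCM1, pe.F_TSCM2, rtol=1e-9)

    def test_f_one_with_inert_fast_pool(self, water, label_times):
        # f -> 1: subpopulation 1 receives (almost) no burst input; with
        # p_s1 = 0 its label stays at the vanishing-influx level set by the
        # steady-state tie (exactly zero only in the dnet1 -> 0 limit)
        ex = ExplicitModelParams(
            p_n=5e-4, p_s1=0.0, d_s1=1e-9, p_s2=0.002, d_s2=0.004, f=1.0, k=5, c=4.0
        )
        pred = solve_label_explicit(ex, water, label_times)
        assert np.all(pred.F_TSCM1 < 1e-8)
        assert np.all(pred.F_TSCM2 > 1e-4)
        assert np.all(pred.F_TSCM1 < 1e-4 * pred.F_TSCM2)

    def test_non_stationary_subpopulation_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            ExplicitModelParams(
                p_n=5e-4, p_s1=0.01, d_s1=0.005, p_s2=0.002, d_s2=0.004, f=0.1, k=5
            )

    def test_table_like_params_match_fine_euler_at_49d(self, water):
        # fast/slow half-lives 0.4 y and 9 y, f = 0.06, k = 5
        ln2 = np.log(2)
        ex = ExplicitModelParams(
            p_n=5e-4,
            p_s1=0.015,
            d_s1=0.015 + ln2 / (0.4 * 365.25),
            p_s2=0.002,
            d_s2=0.002 + ln2 / (9 * 365.25),
            f=0.06,
            k=5,
            c=1.0,
        )
        got = solve_label_explicit(ex, water, [49.0]).F_TSCM[0]
        ref = solve_label_euler(ex, water, [49.0], dt=1e-3).F_TSCM[0]
        assert got == pytest.approx(ref, rel=5e-4)  # 4 significant figures

    def test_relative_size_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_explicit(rng)
            assert 0.0 < p.relative_size_2 < 1.0


class TestOracleAgreement:
    @pytest.mark.parametrize("kind", ["implicit", "explicit"])
    def test_expm_matches_ivp(self, kind, water, label_times):
        rng = np.random.default_rng(11)
        draw = random_implicit if kind == "implicit" else random_explicit
        for _ in range(5):
            p = draw(rng)
            solve = solve_label_implicit if kind == "implicit" else solve_label_explicit
            a = solve(p, water, label_times, method="expm")
            b = solve(p, water, label_times, method="ivp")
            assert np.allclose(a.F_TSCM, b.F_TSCM, rtol=1e-5, atol=1e-12)
            assert np.allclose(a.F_TN, b.F_TN, rtol=1e-5, atol=1e-12)

    def test_expm_matches_euler_randomized(self, water, label_times):
        rng = np.random.default_rng(21)
        for _ in range(3):
            p = random_explicit(rng)
            a = solve_label_explicit(p, water, label_times)
            e = solve_label_euler(p, water, label_times, dt=1e-2)
            assert np.allclose(a.F_TSCM, e.F_TSCM, rtol=2e-3, atol=1e-9)


class TestDerivedBulkRates:
    def test_pure_self_renewal(self):
        p = ImplicitModelParams(p_n=1e-3, p_s=0.01, Delta=0.0, k=5, c=1.0, ds_star=0.01)
        assert derived_bulk_rates(p)["fraction_from_naive"] == 0.0

    def test_pure_naive_replacement(self):
        p = ImplicitModelParams(p_n=1e-3, p_s=0.0, Delta=1e-3, k=5, c=1.0, ds_star=0.03)
        assert derived_bulk_rates(p)["fraction_from_naive"] == 1.0

    def test_balanced_sources(self):
        # 2^k * delta_ratio == p_s -> half of new cells come from naive
        p = ImplicitModelParams(p_n=1e-3, p_s=0.032, Delta=1e-3, k=5, c=1.0, ds_star=0.05)
        d = derived_bulk_rates(p)
        assert d["fraction_from_naive"] == pytest.approx(0.5)
        assert d["d_s"] == pytest.approx(0.064)

    def test_homogeneous_constraint_ties_ds_star(self, homogeneous_params):
        assert homogeneous_params.ds_star_resolved == pytest.approx(homogeneous_params.d_s)
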