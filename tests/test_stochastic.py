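"""Exact birth-death clone simulation against closed-form laws."""

import math

import numpy as np
import pytest

from tscmdyn.stochastic import (
    CloneSimConfig,
    degree_of_self_renewal,
    deterministic_half_life,
    extinction_probability,
    extinction_time_cdf,
    extinction_time_quantile,
    initial_clone_size,
    precursor_lifespan_distribution,
    simulate_clone,
    simulate_clones,
)

from conftest import random_explicit

LN2 = math.log(2.0)


class TestDeterministicHalfLife:
    def test_one_year(self):
        assert deterministic_half_life(LN2 / 365 + 0.001, 0.001) == pytest.approx(365.0)

    def test_nine_year_net_loss_rate(self):
        # inversion: a 9-year half-life implies d - p ~ 2.11e-4 per day
        d_minus_p = LN2 / (9 * 365.25)
        assert d_minus_p == pytest.approx(2.11e-4, rel=5e-3)
        assert deterministic_half_life(0.002 + d_minus_p, 0.002) == pytest.approx(9 * 365.25)

    def test_non_decaying_clone_rejected(self):
        with pytest.raises(ValueError):
            deterministic_half_life(0.01, 0.01)


class TestInitialCloneSize:
    def test_bulk_convention(self):
        assert initial_clone_size(0, 1e-5, 1.0) == 1_000_000

    def test_zero_burst_fraction_warns(self):
        with pytest.warns(UserWarning, match="no long-lived clone"):
            assert initial_clone_size(5, 1e-5, 0.0) == 0

    def test_long_lived_clone_size(self):
        assert initial_clone_size(10, 1e-5, 0.058) == 59_392_000


class TestSSA:
    def test_pure_death_single_cell_mean_lifetime(self):
        s = simulate_clones(CloneSimConfig(p=0.0, d=0.01, n0=1, n_runs=10_000, seed=5))
        mean = s.summary()["mean_extinction_days"]
        assert mean == pytest.approx(100.0, abs=3.0)  # 3 x SE at 1/d = 100

    def test_large_clone_half_life_matches_deterministic(self):
        s = simulate_clones(CloneSimConfig(p=0.002, d=0.004, n0=10_000, n_runs=300, seed=5))
        med = s.summary()["median_half_life_days"]
        assert med == pytest.approx(LN2 / 0.002, rel=0.05)

    def test_no_death_never_extinct(self):
        s = simulate_clone(
            CloneSimConfig(p=0.01, d=0.0, n0=3, n_runs=1, seed=1, max_time=500.0)
        )
        assert s.censored
        assert math.isnan(s.extinction_time)

    def test_degenerate_no_events_warns(self):
        with pytest.warns(UserWarning, match="no events"):
            traj = simulate_clone(CloneSimConfig(p=0.0, d=0.0, n0=5, n_runs=1, seed=0))
        assert traj.sizes[-1] == 5

    def test_extinction_time_after_half_life(self):
        s = simulate_clones(CloneSimConfig(p=0.001, d=0.003, n0=100, n_runs=50, seed=9))
        ok = ~np.isnan(s.extinction_times) & ~np.isnan(s.half_life_times)
        assert np.all(s.extinction_times[ok] >= s.half_life_times[ok])

    def test_seeded_determinism(self):
        cfg = CloneSimConfig(p=0.003, d=0.005, n0=50, n_runs=20, seed=123)
        a, b = simulate_clones(cfg), simulate_clones(cfg)
        assert np.array_equal(a.extinction_times, b.extinction_times)
        t1 = simulate_clone(cfg)
        t2 = simulate_clone(cfg)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.sizes, t2.sizes)

    def test_mean_trajectory_matches_deterministic_decay(self):
        # E[x(t)] = n0 exp((p-d) t); checked at three checkpoints against
        # the exact birth-death variance for the Monte-Carlo error bars
        p, d, n0, n_runs = 0.002, 0.006, 30, 10_000
        cfg = CloneSimConfig(p=p, d=d, n0=n0, n_runs=n_runs, seed=77, max_time=2000.0)
        checkpoints = np.array([100.0, 300.0, 600.0])
        totals = np.zeros(3)
        for ss in np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs):
            traj = simulate_clone(cfg, rng=np.random.default_rng(ss))
            idx = np.searchsorted(traj.times, checkpoints, side="right") - 1
            vals = traj.sizes[idx].astype(float)
            if not traj.censored:  # extinct: zero beyond the last event
                vals[checkpoints >= traj.extinction_time] = 0.0
            totals += vals
        mean = totals / n_runs
        r = d - p
        expect = n0 * np.exp(-r * checkpoints)
        var = n0 * (p + d) / r * (np.exp(-r * checkpoints) - np.exp(-2 * r * checkpoints))
        assert np.all(np.abs(mean - expect) < 4 * np.sqrt(var / n_runs))

    def test_extinction_fraction_matches_analytic_cdf(self):
        # subcritical: all runs extinct; supercritical: fraction follows q(t)^n0
        sub = simulate_clones(CloneSimConfig(p=0.001, d=0.004, n0=20, n_runs=200, seed=3))
        assert np.all(~sub.censored)
        sup = simulate_clones(
            CloneSimConfig(p=0.02, d=0.01, n0=1, n_runs=1000, seed=2, max_time=600.0)
        )
        frac = float(np.mean(~sup.censored))
        expect = extinction_time_cdf(600.0, 0.02, 0.01, 1)
        assert frac == pytest.approx(expect, abs=3 * 0.016)  # 3 x binomial SE
        assert extinction_probability(0.02, 0.01, 1) == pytest.approx(0.5)


class TestExtinctionLaw:
    def test_quantile_inverts_cdf(self):
        for p, d, n0 in [(0.0, 0.01, 3), (0.002, 0.004, 100), (0.004, 0.004, 10)]:
            for q in (0.1, 0.5, 0.9):
                t = extinction_time_quantile(q, p, d, n0)
                assert extinction_time_cdf(t, p, d, n0) == pytest.approx(q, rel=1e-9)

    def test_median_lifespan_grows_by_doubling_time_when_n0_doubles(self):
        # far-tail asymptotics of the max of n0 i.i.d. clone lifetimes
        p, d = 0.001, 0.004
        t1 = extinction_time_quantile(0.5, p, d, 200_000)
        t2 = extinction_time_quantile(0.5, p, d, 400_000)
        assert t2 - t1 == pytest.approx(LN2 / (d - p), rel=0.02)

    def test_two_pure_death_cells_mean_extinction(self):
        # E[max of two exp(d)] = 1.5/d = 150 days at d = 0.01
        s = simulate_clones(CloneSimConfig(p=0.0, d=0.01, n0=2, n_runs=10_000, seed=8))
        assert s.summary()["mean_extinction_days"] == pytest.approx(150.0, abs=4.0)

    def test_ssa_distribution_matches_cdf(self):
        p, d, n0 = 0.002, 0.005, 50
        s = simulate_clones(CloneSimConfig(p=p, d=d, n0=n0, n_runs=2000, seed=21))
        for q in (0.25, 0.5, 0.75):
            t_q = extinction_time_quantile(q, p, d, n0)
            emp = float(np.mean(s.extinction_times <= t_q))
            assert emp == pytest.approx(q, abs=0.04)


class TestPrecursorLifespan:
    def test_zero_clone_size(self):
        with pytest.warns(UserWarning):
            s = precursor_lifespan_distribution(0.002, 0.004, k=5, Delta=1e-5, f=0.0, n_runs=10)
        assert np.all(s.extinction_times == 0)

    def test_small_scale_run(self):
        s = precursor_lifespan_distribution(
            0.001, 0.005, k=0, Delta=1e-9, f=1.0, n_runs=50, seed=4
        )
        assert np.all(np.isfinite(s.extinction_times))
        assert s.summary()["fraction_censored"] == 0.0


class TestDegreeOfSelfRenewal:
    def test_direct_rate_form(self):
        assert degree_of_self_renewal(p=0.002, d=0.012) == pytest.approx(100.0)

    def test_table_median_half_life_implies_4600_days(self):
        dnet = LN2 / (8.74 * 365.25)
        got = degree_of_self_renewal(p=0.002, d=0.002 + dnet)
        assert got == pytest.approx(4605.5, abs=1.0)
        assert got == pytest.approx(4600.0, rel=0.01)

    def test_non_decaying_pool_is_infinite(self):
        assert degree_of_self_renewal(p=0.01, d=0.005) == math.inf

    def test_rate_and_size_routes_agree(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            ex = random_explicit(rng)
            assert degree_of_self_renewal(ex, subpopulation=2) == pytest.approx(
                1.0 / ex.dnet2, rel=1e-10
            )
            assert degree_of_self_renewal(ex, subpopulation=1) == pytest.approx(
                1.0 / ex.dnet1, rel=1e-10
            )
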