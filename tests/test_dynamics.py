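"""Selection dynamics: cascade ODE, stochastic engine, production coupling."""

import math

import numpy as np
import pytest

from assemblykit.dynamics import (
    SelectionParams,
    discovery_production_sim,
    estimate_selection_params,
    final_ensemble,
    integrate_growth,
    poisson_cascade,
    regime_classify,
    stochastic_growth,
)


class TestParams:
    def test_timescales(self):
        p = SelectionParams(alpha=0.5, k_d=4.0, k_p=0.5)
        assert p.tau_d == 0.25 and p.tau_p == 2.0

    @pytest.mark.parametrize("kwargs", [
        {"alpha": -0.1}, {"alpha": 1.1}, {"k_d": 0.0}, {"k_d": math.nan},
        {"k_p": -1.0}, {"k_d": math.inf},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SelectionParams(**kwargs)


class TestCascadeODE:
    def test_alpha1_matches_closed_form(self):
        t = np.linspace(0.5, 5.0, 10)
        traj = integrate_growth(
            SelectionParams(alpha=1.0, k_d=1.0), N1=2.0, t_grid=t, a_max=10,
            rtol=1e-12, atol=1e-20,
        )
        for ai, a in enumerate(traj.a_levels):
            cf = poisson_cascade(2.0, 1.0, t, int(a))
            np.testing.assert_allclose(traj.counts[:, ai], cf, rtol=1e-6)

    def test_initial_condition_at_t0(self):
        t = np.array([0.0, 1.0])
        traj = integrate_growth(SelectionParams(alpha=0.7, k_d=1.0), N1=3.0, t_grid=t, a_max=5)
        assert traj.counts[0, 0] == 3.0
        np.testing.assert_array_equal(traj.counts[0, 1:], 0.0)

    def test_alpha0_front_advances_one_level_per_discovery_time(self):
        k_d = 2.0
        t = np.linspace(0.0, 3.0, 301)
        traj = integrate_growth(SelectionParams(alpha=0.0, k_d=k_d), N1=1.0, t_grid=t, a_max=6)
        crossing = []
        for ai in range(1, len(traj.a_levels)):
            c = traj.counts[:, ai]
            if (c >= 1.0).any():
                crossing.append(traj.t[np.argmax(c >= 1.0)])
        gaps = np.diff(crossing)
        assert np.all(np.abs(gaps - 1.0 / k_d) < 0.05)

    def test_counts_nondecreasing_in_time(self):
        t = np.linspace(0, 4, 41)
        traj = integrate_growth(SelectionParams(alpha=0.5, k_d=1.5), N1=2.0, t_grid=t, a_max=8)
        diffs = np.diff(traj.counts, axis=0)
        assert (diffs >= -1e-9).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            integrate_growth(SelectionParams(), N1=0.0, t_grid=[0, 1])
        with pytest.raises(ValueError):
            integrate_growth(SelectionParams(), N1=1.0, t_grid=[-1, 1])


class TestStochasticEngine:
    def test_zero_events_initial_state(self):
        traj = stochastic_growth(SelectionParams(), seed=1, n_events=0, N1=4)
        assert traj.counts[-1, 0] == 4 and traj.counts[-1, 1:].sum() == 0

    def test_alpha1_mean_matches_poisson_cascade(self):
        # replicate means vs closed form, within 3 Monte-Carlo standard errors
        t_end, N1, reps = 2.0, 20, 40
        finals = np.array([
            stochastic_growth(SelectionParams(alpha=1.0, k_d=1.0), seed=s,
                              t_end=t_end, N1=N1, a_max=60).counts[-1]
            for s in range(reps)
        ])
        for a in range(2, 7):
            mean = finals[:, a - 1].mean()
            se = finals[:, a - 1].std(ddof=1) / math.sqrt(reps)
            cf = poisson_cascade(N1, 1.0, t_end, a)
            assert abs(mean - cf) <= 3 * max(se, 1e-9), (a, mean, cf, se)

    def test_reproducible_given_seed(self):
        a = stochastic_growth(SelectionParams(alpha=0.6, k_d=1.0), seed=9, n_events=200, N1=3)
        b = stochastic_growth(SelectionParams(alpha=0.6, k_d=1.0), seed=9, n_events=200, N1=3)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_array_equal(a.t, b.t)

    def test_selection_slows_unique_object_growth(self):
        t_end, N1 = 5.0, 5
        tot = {alpha: [] for alpha in (0.5, 1.0)}
        for s in range(10):
            for alpha in tot:
                traj = stochastic_growth(SelectionParams(alpha=alpha, k_d=1.0),
                                         seed=s, t_end=t_end, N1=N1, a_max=150)
                tot[alpha].append(traj.counts[-1].sum())
        assert np.mean(tot[0.5]) < np.mean(tot[1.0])


class TestDiscoveryProduction:
    def test_no_production_means_zero_assembly(self):
        params = SelectionParams(alpha=1.0, k_d=1.0, k_p=0.0)
        traj = discovery_production_sim(params, seed=3, mass_budget=60)
        assert np.all(traj.A == 0.0)
        assert all(n == 1 for _, n in traj.meta["objects"])

    def test_mass_budget_respected_and_clean_end(self):
        params = SelectionParams(alpha=0.5, k_d=1.0, k_p=1.0)
        traj = discovery_production_sim(params, seed=5, mass_budget=40)
        assert traj.meta["mass"] == 40
        assert traj.copies[-1].sum() == 40

    def test_fast_discovery_gives_singleton_explosion(self):
        params = SelectionParams(alpha=1.0, k_d=100.0, k_p=1.0)
        traj = discovery_production_sim(params, seed=11, mass_budget=100)
        objects = traj.meta["objects"]
        assert len(objects) >= 50
        assert max(n for _, n in objects) <= 2

    def test_fast_production_gives_few_low_index_objects(self):
        params = SelectionParams(alpha=1.0, k_d=0.01, k_p=1.0)
        traj = discovery_production_sim(params, seed=11, mass_budget=100)
        objects = traj.meta["objects"]
        assert len(objects) <= 10
        assert max(a for a, _ in objects) <= 3
        assert max(n for _, n in objects) >= 30

    def test_final_ensemble_consistent_with_A(self):
        params = SelectionParams(alpha=0.5, k_d=1.0, k_p=1.0)
        traj = discovery_production_sim(params, seed=2, mass_budget=50)
        ens = final_ensemble(traj)
        assert ens.assembly() == pytest.approx(traj.A[-1], rel=1e-12)
        assert ens.N_T == traj.meta["mass"]

    def test_reproducible(self):
        params = SelectionParams(alpha=0.5, k_d=1.0, k_p=1.0)
        a = discovery_production_sim(params, seed=8, mass_budget=30)
        b = discovery_production_sim(params, seed=8, mass_budget=30)
        np.testing.assert_array_equal(a.A, b.A)


class TestRegimes:
    @pytest.mark.parametrize("tau_d,tau_p,expected", [
        (0.001, 1.0, 1), (1000.0, 1.0, 2), (1.0, 1.0, 3), (0.5, 1.0, 3), (5.0, 1.0, 3),
    ])
    def test_classification(self, tau_d, tau_p, expected):
        assert regime_classify(tau_d, tau_p) == expected

    def test_thresholds_configurable(self):
        assert regime_classify(0.5, 1.0, r_low=0.6) == 1

    def test_invalid_timescales(self):
        with pytest.raises(ValueError):
            regime_classify(-1.0, 1.0)
        with pytest.raises(ValueError):
            regime_classify(1.0, 0.0)

    def test_estimator_is_a_stub(self):
        with pytest.raises(NotImplementedError):
            estimate_selection_params([0, 1], [[1, 0]])
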