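"""Stochastic quorum model: update rules, outcome classification,
threshold finding and the phase diagram."""

from dataclasses import replace

import numpy as np
import pytest

from macroqs.stochastic_quorum import (
    EXPANDED,
    EXTINCT,
    UNDECIDED,
    PopState,
    PopTrajectory,
    QSParams,
    classify_outcome,
    extinction_fraction,
    find_threshold_density,
    phase_diagram,
    replication_probability,
    simulate_ensemble,
    simulate_fixed_concentration,
    simulate_population,
    step,
)


class TestReplicationProbability:
    def test_landmarks(self, measured_params):
        p = measured_params
        assert replication_probability(p, 0.0) == 0.0
        assert replication_probability(p, p.K_half) == pytest.approx(p.mu / 2)
        # at the threshold concentration replication balances death
        assert replication_probability(p, p.threshold_concentration) == pytest.approx(p.gamma)

    def test_saturates_below_mu(self, measured_params):
        M = np.logspace(0, 12, 50)
        probs = replication_probability(measured_params, M)
        assert np.all(np.diff(probs) > 0)
        assert np.all(probs < measured_params.mu)

    def test_negative_concentration_rejected(self, measured_params):
        with pytest.raises(ValueError):
            replication_probability(measured_params, -1.0)


class TestStep:
    def test_empty_population_stays_empty_and_factor_decays(self, measured_params):
        rng = np.random.default_rng(0)
        state = PopState(t=0, N=0, M=100.0)
        for k in range(1, 6):
            state = step(measured_params, state, rng)
            assert state.N == 0
            assert state.M == pytest.approx(100.0 * measured_params.d**k)

    def test_factor_accumulation_closed_form(self):
        """With births and deaths disabled, iterating the update matches
        the geometric-series closed form (N/V)(1-d^t)/(1-d) exactly."""
        p = QSParams(mu=0.0, gamma=0.0, V=10.0, d=0.99)
        rng = np.random.default_rng(1)
        state = PopState(t=0, N=1000, M=0.0)
        for t in range(1, 73):
            state = step(p, state, rng)
            expected = (1000 / p.V) * (1 - p.d**t) / (1 - p.d)
            assert state.M == pytest.approx(expected, rel=1e-12)

    def test_pure_death_mean_matches_branching_expectation(self):
        """mu=0 gives a pure death process: the Monte-Carlo mean of N_t
        must match N0 (1-gamma)^t within 3 standard errors."""
        p = QSParams(mu=0.0, gamma=0.023)
        n_reps, N0, t_end = 1000, 200, 48
        ss = np.random.SeedSequence(42)
        finals = np.array([
            simulate_population(p, N0, t_end, child).N[-1] for child in ss.spawn(n_reps)
        ])
        expected = N0 * (1 - p.gamma) ** t_end
        se = finals.std(ddof=1) / np.sqrt(n_reps)
        assert abs(finals.mean() - expected) < 3 * se

    def test_fixed_concentration_is_galton_watson(self, measured_params):
        """With M frozen, E[N_t] = N0 (1 + P_mu - gamma)^t."""
        p = measured_params
        M_fix = 2.0 * p.K_half
        growth = 1 + replication_probability(p, M_fix) - p.gamma
        n_reps, N0, t_end = 400, 500, 48
        ss = np.random.SeedSequence(7)
        finals = np.array([
            simulate_fixed_concentration(p, N0, M_fix, t_end, child).N[-1]
            for child in ss.spawn(n_reps)
        ])
        expected = N0 * growth**t_end
        se = finals.std(ddof=1) / np.sqrt(n_reps)
        assert abs(finals.mean() - expected) < 3 * se


class TestSimulatePopulation:
    def test_zero_start_stays_zero(self, measured_params):
        traj = simulate_population(measured_params, 0, 48, seed=3)
        assert np.all(traj.N == 0)

    def test_seed_determinism(self, measured_params):
        N0 = measured_params.cells_from_density(1931)
        a = simulate_population(measured_params, N0, 96, seed=11)
        b = simulate_population(measured_params, N0, 96, seed=11)
        np.testing.assert_array_equal(a.N, b.N)
        np.testing.assert_array_equal(a.M, b.M)
        c = simulate_population(measured_params, N0, 96, seed=12)
        assert not np.array_equal(a.N, c.N)

    def test_factor_never_negative(self, measured_params):
        traj = simulate_population(measured_params, 10000, 200, seed=5)
        assert np.all(traj.M >= 0)

    def test_high_density_expands_low_density_dies(self, measured_params):
        """The measured parameters reproduce the growth-vs-extinction
        contrast between high (5,172/cm^2) and low (862/cm^2) seedings."""
        p = measured_params
        hi = simulate_ensemble(p, p.cells_from_density(5172), 144, 10, seed=21)
        hi_folds = [tr.N[-1] / tr.N[0] for tr in hi.trajectories]
        assert sum(f > 1 for f in hi_folds) >= 9
        lo = simulate_ensemble(p, p.cells_from_density(862), 384, 10, seed=22)
        lo_folds = [tr.N[-1] / tr.N[0] for tr in lo.trajectories]
        assert sum(f < 0.6 for f in lo_folds) >= 9


def make_traj(values):
    values = np.asarray(values, dtype=np.int64)
    return PopTrajectory(times=np.arange(len(values), dtype=float),
                         N=values, M=np.zeros(len(values)))


class TestClassifyOutcome:
    def test_deep_decline_is_extinct(self):
        n = np.linspace(1000, 100, 145).astype(int)  # fold 0.1 by day 6
        assert classify_outcome(make_traj(n)) == EXTINCT

    def test_constant_is_undecided(self):
        assert classify_outcome(make_traj(np.full(145, 500))) == UNDECIDED

    def test_monotone_rise_is_expanded(self):
        n = np.linspace(1000, 10000, 145).astype(int)
        assert classify_outcome(make_traj(n)) == EXPANDED

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome(make_traj(np.full(50, 10)))


class TestExtinctionFraction:
    def test_empty_population_always_extinct(self, measured_params):
        assert extinction_fraction(measured_params, 0, 10, 144, seed=0) == 1.0

    def test_far_above_threshold_never_extinct(self, measured_params, threshold_10ml):
        N0 = measured_params.cells_from_density(10 * threshold_10ml.density)
        assert extinction_fraction(measured_params, N0, 50, 144, seed=1) == 0.0

    def test_monotone_nonincreasing_in_density(self, measured_params):
        p = measured_params
        fracs = [
            extinction_fraction(p, p.cells_from_density(d), 20, 144, seed=13)
            for d in (400, 900, 1300, 1800, 4000)
        ]
        assert all(b <= a + 0.15 for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == 1.0 and fracs[-1] == 0.0


class TestFindThreshold:
    def test_zero_death_rate_gives_zero_threshold(self, measured_params):
        thr = find_threshold_density(replace(measured_params, gamma=0.0))
        assert thr.density == 0.0

    def test_mu_below_gamma_rejected(self, measured_params):
        with pytest.raises(ValueError):
            find_threshold_density(replace(measured_params, mu=0.01))

    def test_degenerate_bracket_reported(self, measured_params):
        with pytest.raises(ValueError, match="degenerate"):
            find_threshold_density(measured_params, bounds=(5000.0, 20000.0),
                                   n_reps=6, seed=2)

    def test_doubling_volume_doubles_threshold(self, measured_params, threshold_10ml):
        thr_2v = find_threshold_density(replace(measured_params, V=20.0), seed=1)
        ratio = thr_2v.density / threshold_10ml.density
        assert 1.6 < ratio < 2.4

    def test_threshold_monotone_in_parameters(self, measured_params, threshold_10ml):
        """Threshold density rises with V and K_half and falls with mu."""
        base = threshold_10ml.density
        lo_V = find_threshold_density(replace(measured_params, V=5.0), seed=31).density
        assert lo_V < base
        hi_K = find_threshold_density(replace(measured_params, K_half=1e6), seed=32).density
        lo_K = find_threshold_density(replace(measured_params, K_half=2e5), seed=33).density
        assert lo_K < base < hi_K
        hi_mu = find_threshold_density(replace(measured_params, mu=0.08), seed=34).density
        lo_mu = find_threshold_density(replace(measured_params, mu=0.04), seed=35).density
        assert hi_mu < base < lo_mu

    def test_random_outcome_at_threshold(self, measured_params, threshold_10ml):
        """At the bisected threshold the outcome is genuinely stochastic:
        the extinction fraction sits strictly inside (0.1, 0.9)."""
        N0 = measured_params.cells_from_density(threshold_10ml.density)
        frac = extinction_fraction(measured_params, N0, 100, 144, seed=77)
        assert 0.1 < frac < 0.9


class TestPhaseDiagram:
    def test_far_above_threshold_all_survive(self, measured_params):
        pd_res = phase_diagram(measured_params, V_list=[10.0],
                               density_list=[8000, 15000], n_reps=8, seed=4)
        assert set(pd_res.conditions["label"]) == {"always_survives"}

    def test_grid_fully_labeled_and_mixed_near_boundary(self, measured_params,
                                                        threshold_10ml):
        dens = [300, threshold_10ml.density, 8000]
        pd_res = phase_diagram(measured_params, V_list=[10.0], density_list=dens,
                               n_reps=8, seed=9)
        labels = pd_res.conditions.set_index("density_cells_per_cm2")["label"]
        assert labels.loc[300] == "always_extinct"
        assert labels.loc[8000] == "always_survives"
        assert labels.loc[threshold_10ml.density] == "both_possible"
        assert len(pd_res.boundary) == 1
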