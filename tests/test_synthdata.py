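"""The generator must reproduce the stochastic structure the model assumes."""

import numpy as np
import pandas as pd
import pytest

from hoopoeipm import synthdata
from hoopoeipm.params import HABITATS, TrueParams
from hoopoeipm.productivity import annual_R


def flat_params(**kw):
    """Time-constant rates (no trends, no year noise) unless overridden."""
    defaults = dict(
        trend={}, sigma_s1=0.0, sigma_s2=0.0, sigma_succ=0.0,
        sigma_fled=0.0, sigma_omega=0.0, p_sd=0.0,
    )
    defaults.update(kw)
    return TrueParams(**defaults)


class TestSimulatePopulation:
    def test_absorbing_zero_state(self):
        """No survival and no immigration drives every habitat to zero."""
        p = flat_params(s1=0.0, s2=0.0, omega=0.0)
        traj = synthdata.simulate_population(p, 6, seed=1)
        assert np.all(traj.Ntot[:, 1:] == 0)

    def test_default_generating_fledgling_means(self):
        p = TrueParams()
        # habitat order is (H, M, L); low -> high quality reads (5.9, 6.0, 6.7)
        assert tuple(p.mu_fled[::-1]) == (5.9, 6.0, 6.7)

    def test_deterministic_one_step_matches_hand_arithmetic(self):
        """Decoupled habitats, N = 100: one-step total is N(R*S1 + S2 + w)."""
        psi = np.full((3, 3), 0.01)
        np.fill_diagonal(psi, 0.98)
        p = flat_params(
            s1=0.2, s2=0.4, psucc=0.8, mu_fled=(6.0, 6.0, 6.0), omega=0.1,
            psi1=psi, psi2=psi,
            init_N=np.array([[30, 50, 20]] * 3),
        )
        traj = synthdata.simulate_population(p, 3, seed=1, deterministic=True)
        R = 0.5 * 0.8 * 6.0
        expected = 100 * (R * 0.2 + 0.4 + 0.1)
        assert np.allclose(traj.Ntot[:, 1], expected)

    def test_movement_conservation(self):
        """Summed over destinations, expected survivors equal S*N whatever
        the movement matrix is."""
        rng = np.random.default_rng(3)
        p = flat_params(
            psi1=rng.dirichlet(np.ones(3), 3), psi2=rng.dirichlet(np.ones(3), 3),
            init_N=np.array([[40, 60, 20]] * 3),
        )
        traj = synthdata.simulate_population(p, 2, seed=1, deterministic=True)
        ntot0 = traj.Ntot[:, 0]
        # adult survivors summed over all destination habitats
        assert np.isclose(traj.N2[:, 1].sum(), (p.s2 * ntot0).sum())
        R = annual_R(p.psucc, p.mu_fled)
        assert np.isclose(traj.N1[:, 1].sum(), (R * p.s1 * ntot0).sum())

    def test_monte_carlo_agreement_with_expectation(self):
        """Replicate means of each stage match the analytic expectation
        within 3 standard errors."""
        p = flat_params(init_N=np.array([[40, 60, 20]] * 3))
        det = synthdata.simulate_population(p, 3, seed=0, deterministic=True)
        reps = np.array([
            synthdata.simulate_population(p, 3, seed=s).N1[:, 1]
            for s in range(1000)
        ])
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(reps.mean(axis=0) - det.N1[:, 1]) < 3 * se + 1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            TrueParams(psi1=np.full((3, 3), 0.5))
        with pytest.raises(ValueError):
            TrueParams(init_N=np.array([[-1, 2, 3]] * 3))
        with pytest.raises(ValueError):
            synthdata.simulate_population(TrueParams(), 1, seed=0)

    def test_reproducible(self):
        a = synthdata.simulate_population(TrueParams(), 8, seed=9)
        b = synthdata.simulate_population(TrueParams(), 8, seed=9)
        assert np.array_equal(a.N1, b.N1) and np.array_equal(a.Ni, b.Ni)


class TestCaptureHistories:
    def test_perfect_detection_static_world(self):
        """p = 1, S = 1, identity movement: every bird is seen every year in
        its marking habitat."""
        psi = np.eye(3) * 1.0
        p = flat_params(s1=1.0, s2=1.0, psi1=psi, psi2=psi,
                        p_mean=50.0, omega=0.0)
        traj = synthdata.simulate_population(p, 5, seed=2, deterministic=True)
        hist = synthdata.simulate_capture_histories(traj, p, seed=3)
        for i in range(hist.n_individuals):
            row = hist.obs[i, hist.first_occ[i]:]
            assert np.all(row == row[0]) and row[0] != 0

    def test_adult_transition_counts_binomial_oracle(self):
        """10,000 adults in H with S2 = 0.5 and psi(H->M) = 0.2 yield about
        1,000 observed H->M transitions (within 99% binomial bounds)."""
        from scipy.stats import binom

        psi2 = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        p = flat_params(
            s2=0.5, psi2=psi2, p_mean=50.0, omega=0.0,
            mark_rate_adult=1.0, mark_rate_juv=0.0,
            init_N=np.array([[0, 10000, 0], [0, 1, 0], [0, 1, 0]]),
        )
        traj = synthdata.simulate_population(p, 2, seed=4, deterministic=True)
        hist = synthdata.simulate_capture_histories(traj, p, seed=5)
        marked_H = (hist.obs[:, 0] == 1)
        n = int(marked_H.sum())
        transitions = int(np.sum(hist.obs[marked_H, 1] == 2))
        lo, hi = binom.ppf([0.005, 0.995], n, 0.5 * 0.2)
        assert lo <= transitions <= hi

    def test_reproducible(self, small_params):
        traj = synthdata.simulate_population(small_params, 8, seed=11)
        a = synthdata.simulate_capture_histories(traj, small_params, seed=1)
        b = synthdata.simulate_capture_histories(traj, small_params, seed=1)
        assert np.array_equal(a.obs, b.obs)


class TestProductivity:
    def test_success_rate_at_logit_zero(self):
        p = flat_params(psucc=0.5, init_N=np.array([[600, 1000, 400]] * 3))
        cov = synthdata.generate_covariates(3, 1)
        traj = synthdata.simulate_population(p, 3, seed=1, deterministic=True)
        broods = synthdata.simulate_productivity(traj, p, cov, seed=2)
        assert abs(broods["success"].mean() - 0.5) < 0.02

    def test_fledgling_means_recover_defaults(self):
        """Per-habitat means at n ~ 5,000 successful records recover the
        generating (H, M, L) = (6.7, 6.0, 5.9) within 0.1."""
        p = flat_params(init_N=np.array([[700, 1200, 500]] * 3))
        cov = synthdata.generate_covariates(3, 1)
        traj = synthdata.simulate_population(p, 3, seed=1, deterministic=True)
        broods = synthdata.simulate_productivity(traj, p, cov, seed=3)
        means = broods[broods.success == 1].groupby("habitat").fledglings.mean()
        for hab, expected in zip(HABITATS, p.mu_fled):
            assert abs(means[hab] - expected) < 0.1

    def test_delay_threshold_shifts_mean(self):
        """A 0.1 slope with delay -4 shifts the record mean by -0.4; a
        positive delay leaves it untouched."""
        from hoopoeipm.productivity import threshold_delay_term

        assert threshold_delay_term(-4.0, 0.1) == pytest.approx(-0.4)
        assert threshold_delay_term(3.0, 0.1) == 0.0

    def test_raises_on_nonpositive_mean(self):
        p = flat_params(
            mu_fled=(0.5, 0.5, 0.5),
            covariate_effects={"fled": {"del": 1.0}},
            init_N=np.array([[50, 80, 30]] * 3),
        )
        cov = synthdata.generate_covariates(3, 1)
        cov["del_mean"] = -10.0
        traj = synthdata.simulate_population(p, 3, seed=1, deterministic=True)
        with pytest.raises(ValueError, match="non-positive gamma mean"):
            synthdata.simulate_productivity(traj, p, cov, seed=2)

    def test_rounding_option_gives_positive_integers(self, small_params):
        cov = synthdata.generate_covariates(6, 1)
        traj = synthdata.simulate_population(small_params, 6, seed=1, cov=cov)
        broods = synthdata.simulate_productivity(
            traj, small_params, cov, seed=2, round_fledglings=True)
        fl = broods.loc[broods.success == 1, "fledglings"]
        assert np.all(fl == np.floor(fl)) and np.all(fl >= 1)


class TestCounts:
    def test_zero_population_zero_counts(self):
        p = flat_params(s1=0.0, s2=0.0, omega=0.0)
        traj = synthdata.simulate_population(p, 4, seed=1)
        counts = synthdata.simulate_counts(traj, seed=2)
        assert np.all(counts.counts[:, 1:] == 0)

    def test_poisson_mean_and_dispersion(self):
        """10,000 replicate draws at Ntot = 50: mean in [49.4, 50.6] and
        variance/mean ~ 1."""
        from hoopoeipm.params import PopulationTrajectory

        traj = PopulationTrajectory(
            N1=np.full((3, 2), 10), N2=np.full((3, 2), 30),
            Ni=np.full((3, 2), 10), years=np.array([2002, 2003]),
        )
        draws = np.array([
            synthdata.simulate_counts(traj, seed=s).counts[0, 0]
            for s in range(10000)
        ])
        assert 49.4 <= draws.mean() <= 50.6
        assert 0.9 <= draws.var(ddof=1) / draws.mean() <= 1.1


class TestCovariates:
    def test_standardised_weather(self):
        cov = synthdata.generate_covariates(16, seed=5)
        for c in ("temp", "prec"):
            assert abs(cov[c].mean()) < 1e-6
            assert abs(cov[c].std(ddof=0) - 1.0) < 1e-6

    def test_bundle_reproducible(self, small_params):
        b1, _ = synthdata.simulate_bundle(small_params, n_years=6, seed=7)
        b2, _ = synthdata.simulate_bundle(small_params, n_years=6, seed=7)
        assert np.array_equal(b1.histories.obs, b2.histories.obs)
        pd.testing.assert_frame_equal(b1.broods, b2.broods)
        assert np.array_equal(b1.counts.counts, b2.counts.counts)
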