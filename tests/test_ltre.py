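"""Transient-LTRE decompositions against closed forms and projections."""

import numpy as np
import pytest

from hoopoeipm.ltre import (
    PARAM_NAMES,
    contributions_difference,
    contributions_variance,
    lambda_from_rates,
    realized_lambda,
)


def constant_series(T=10, R=2.6, s1=0.2, s2=0.35, omega=0.1, pi=None):
    pi = np.array([1 / 3, 1 / 3, 1 / 3]) if pi is None else np.asarray(pi)
    return {
        "R": np.full((3, T), R), "s1": np.full((3, T), s1),
        "s2": np.full((3, T), s2), "omega": np.full((3, T), omega),
        "pi": np.repeat(pi[:, None], T, axis=1),
    }


class TestRealizedLambda:
    def test_constant_population(self):
        g = realized_lambda(np.full(6, 120.0))
        assert np.allclose(g.lam, 1.0) and np.allclose(g.log_lam, 0.0)

    def test_simple_ratio(self):
        g = realized_lambda(np.array([100.0, 110.0]))
        assert g.lam[0] == pytest.approx(1.1)

    def test_matches_log_diff_identity(self, rng):
        n = np.exp(rng.normal(4, 0.3, 12))
        g = realized_lambda(n)
        assert np.allclose(g.lam, np.exp(np.diff(np.log(n))))

    def test_rejects_zero_totals(self):
        with pytest.raises(ValueError):
            realized_lambda(np.array([10.0, 0.0, 5.0]))


class TestLambdaFromRates:
    def test_hand_arithmetic(self):
        lam = lambda_from_rates(
            {"R": [3.35, 3.35, 3.35], "s1": [0.12] * 3, "s2": [0.35] * 3,
             "omega": [0.10] * 3}, pi=[1, 0, 0])
        assert lam == pytest.approx(3.35 * 0.12 + 0.35 + 0.10)
        assert lam == pytest.approx(0.852)

    def test_independent_of_structure_when_rates_equal(self, rng):
        theta = {"R": [2.5] * 3, "s1": [0.2] * 3, "s2": [0.4] * 3,
                 "omega": [0.1] * 3}
        lams = [lambda_from_rates(theta, pi=rng.dirichlet(np.ones(3)))
                for _ in range(5)]
        assert np.ptp(lams) < 1e-12

    def test_matches_deterministic_projection(self, rng):
        """lambda from rates equals the realized growth of the expectation
        projection, movement cancelling in the total."""
        from hoopoeipm.params import TrueParams
        from hoopoeipm import synthdata

        p = TrueParams(
            trend={}, sigma_s1=0, sigma_s2=0, sigma_succ=0, sigma_fled=0,
            sigma_omega=0, p_sd=0,
            psi1=rng.dirichlet(np.ones(3), 3), psi2=rng.dirichlet(np.ones(3), 3),
            init_N=np.array([[30, 50, 20], [10, 20, 5], [40, 10, 10]]),
        )
        traj = synthdata.simulate_population(p, 4, seed=1, deterministic=True)
        g = realized_lambda(traj.Ntot)
        r = traj.rates
        for t in range(3):
            ntot = traj.Ntot[:, t]
            pi = ntot / ntot.sum()
            lam = lambda_from_rates(
                {"R": r.R[:, t], "s1": r.s1[:, t], "s2": r.s2[:, t],
                 "omega": r.omega[:, t]}, pi=pi)
            assert lam == pytest.approx(g.lam[t], abs=1e-10)

    def test_rejects_bad_structure(self):
        with pytest.raises(ValueError):
            lambda_from_rates({"R": [2] * 3, "s1": [0.2] * 3, "s2": [0.4] * 3,
                               "omega": [0.1] * 3}, pi=[0.5, 0.2, 0.2])


class TestContributionsVariance:
    def test_time_constant_series_contribute_nothing(self):
        out = contributions_variance(constant_series())
        assert out.target == pytest.approx(0.0, abs=1e-25)
        assert all(abs(v) < 1e-25 for v in out.contributions.values())

    def test_single_varying_parameter_closed_form(self, rng):
        """Only adult survival in H varies: its contribution is
        pi_H^2 var(S2_H) exactly and the residual vanishes."""
        series = constant_series(T=12, pi=[0.5, 0.3, 0.2])
        s2H = 0.35 + 0.08 * rng.standard_normal(12)
        series["s2"] = series["s2"].copy()
        series["s2"][0] = s2H
        out = contributions_variance(series)
        expected = 0.25 * np.var(s2H, ddof=1)
        assert out.contributions["s2:H"] == pytest.approx(expected, abs=1e-12)
        assert abs(out.residual) < 1e-12

    def test_first_order_adequacy_on_fluctuating_series(self, rng):
        """Moderate annual variability in every rate: the contribution sum
        tracks var(lambda) within 15%."""
        T = 16
        series = {
            "R": 2.6 * np.exp(0.12 * rng.standard_normal((3, T))),
            "s1": np.clip(0.2 + 0.03 * rng.standard_normal((3, T)), 0.01, 1),
            "s2": np.clip(0.35 + 0.04 * rng.standard_normal((3, T)), 0.01, 1),
            "omega": np.clip(0.1 + 0.02 * rng.standard_normal((3, T)), 0, 1),
        }
        pi_raw = np.abs(1 + 0.15 * rng.standard_normal((3, T)))
        series["pi"] = pi_raw / pi_raw.sum(axis=0, keepdims=True)
        out = contributions_variance(series)
        assert abs(out.residual) / out.target < 0.15

    def test_structure_contributions_vanish_for_equal_rates(self, rng):
        series = constant_series(T=10)
        pi_raw = np.abs(1 + 0.3 * rng.standard_normal((3, 10)))
        series["pi"] = pi_raw / pi_raw.sum(axis=0, keepdims=True)
        out = contributions_variance(series)
        for hab in "HML":
            assert abs(out.contributions[f"pi:{hab}"]) < 1e-12

    def test_habitat_relabel_equivariance(self, rng):
        T = 10
        series = {
            k: rng.uniform(0.1, 0.5, (3, T)) for k in ("s1", "s2", "omega")
        }
        series["R"] = rng.uniform(2, 3, (3, T))
        pi_raw = rng.uniform(0.5, 1.5, (3, T))
        series["pi"] = pi_raw / pi_raw.sum(axis=0, keepdims=True)
        out = contributions_variance(series)
        perm = [2, 0, 1]
        permuted = {k: v[perm] for k, v in series.items()}
        out_p = contributions_variance(permuted)
        for i, kind in enumerate(("R", "s1", "s2", "omega", "pi")):
            for j, hab in enumerate("HML"):
                src_hab = "HML"[perm[j]]
                assert out_p.contributions[f"{kind}:{hab}"] == pytest.approx(
                    out.contributions[f"{kind}:{src_hab}"], abs=1e-12)

    def test_requires_three_years(self):
        with pytest.raises(ValueError):
            contributions_variance(constant_series(T=2))


class TestContributionsDifference:
    def test_identical_periods_contribute_nothing(self):
        series = constant_series(T=10)
        series["R"] = series["R"] + np.linspace(0, 0.5, 10)
        out = contributions_difference(series, (0, 3), (0, 3))
        assert all(abs(v) < 1e-15 for v in out.contributions.values())

    def test_partial_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            contributions_difference(constant_series(T=10), (0, 4), (2, 6))

    def test_single_parameter_change_matches_taylor(self):
        """Only R_H differs by ~10% between periods: its direct contribution
        equals the change in mean log lambda within the expansion residual
        (< 5%)."""
        series = constant_series(T=10, pi=[0.5, 0.3, 0.2])
        series["R"] = series["R"].copy()
        series["R"][0, 5:] *= 1.10
        out = contributions_difference(series, (0, 4), (5, 9))
        direct = out.contributions["R:H"]
        assert out.target != 0
        assert abs(direct - out.target) / abs(out.target) < 0.05
        others = [v for k, v in out.contributions.items() if k != "R:H"]
        assert all(abs(v) < 1e-12 for v in others)

    def test_antisymmetric_under_period_swap(self, rng):
        T = 12
        series = {
            "R": rng.uniform(2, 3, (3, T)), "s1": rng.uniform(0.1, 0.3, (3, T)),
            "s2": rng.uniform(0.3, 0.5, (3, T)), "omega": rng.uniform(0, 0.2, (3, T)),
        }
        pi_raw = rng.uniform(0.5, 1.5, (3, T))
        series["pi"] = pi_raw / pi_raw.sum(axis=0, keepdims=True)
        a = contributions_difference(series, (0, 4), (8, 12))
        b = contributions_difference(series, (8, 12), (0, 4))
        for k in PARAM_NAMES:
            assert a.contributions[k] == pytest.approx(-b.contributions[k], abs=1e-12)
            assert a.extras["indirect"][k] == pytest.approx(
                -b.extras["indirect"][k], abs=1e-12)

    def test_residual_shrinks_with_variability(self, rng):
        """Scaling all fluctuations by 1, 0.5, 0.25 shrinks the expansion
        residual monotonically."""
        T = 16
        base = {
            "R": 0.4 * rng.standard_normal((3, T)),
            "s1": 0.04 * rng.standard_normal((3, T)),
            "s2": 0.05 * rng.standard_normal((3, T)),
            "omega": 0.02 * rng.standard_normal((3, T)),
        }
        resids = []
        for scale in (1.0, 0.5, 0.25):
            series = {
                "R": 2.6 + scale * base["R"], "s1": 0.2 + scale * base["s1"],
                "s2": 0.35 + scale * base["s2"],
                "omega": np.clip(0.1 + scale * base["omega"], 0, 1),
            }
            series["pi"] = np.full((3, T), 1 / 3)
            out = contributions_difference(series, (0, 6), (10, 16))
            resids.append(abs(out.residual))
        assert resids[0] > resids[1] > resids[2]
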