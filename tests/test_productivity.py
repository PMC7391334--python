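"""Productivity submodels: logit success, identity-link gamma fledglings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hoopoeipm.modelspec import ModelSpec, RateFormula, Term, model_I
from hoopoeipm.productivity import (
    ProductivityParams,
    annual_R,
    fledglings_loglik,
    fledglings_mean,
    success_loglik,
    threshold_delay_term,
)

YEARS = np.arange(2002, 2008)


def base_params(**kw):
    defaults = dict(
        succ_intercept=np.zeros(3),
        fled_intercept=np.array([6.7, 6.0, 5.9]),
        shape=6.0,
        years=YEARS,
        succ_year_eff=np.zeros((3, len(YEARS))),
        fled_year_eff=np.zeros((3, len(YEARS))),
    )
    defaults.update(kw)
    return ProductivityParams(**defaults)


def table(**cols):
    n = len(next(iter(cols.values())))
    base = {
        "habitat": ["H"] * n, "year": [2002] * n, "success": [1] * n,
        "fledglings": [5.0] * n, "cs": [0.0] * n, "hat": [0.0] * n,
        "del": [0.0] * n, "meth": [0] * n, "partag": [0] * n,
        "temp": [0.0] * n, "prec": [0.0] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestThresholdDelay:
    @given(st.floats(min_value=0, max_value=1e6),
           st.floats(min_value=-10, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_zero_for_nonnegative_delays(self, d, slope):
        assert threshold_delay_term(d, slope) == 0.0

    @given(st.floats(min_value=-1e3, max_value=-1e-6),
           st.floats(min_value=-10, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_linear_for_negative_delays(self, d, slope):
        assert threshold_delay_term(d, slope) == pytest.approx(slope * d)

    def test_boundary(self):
        assert threshold_delay_term(0.0, 5.0) == 0.0


class TestSuccessLoglik:
    def test_null_coefficients_give_log_half(self):
        t = table(success=[1, 0, 1, 0])
        ll = success_loglik(t, base_params(), model_I())
        assert ll == pytest.approx(4 * np.log(0.5))

    def test_saturation(self):
        t = table(success=[1])
        p = base_params(succ_intercept=np.array([30.0, 0, 0]))
        assert success_loglik(t, p, model_I()) == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_bernoulli_sum(self):
        """Five records, habitat intercepts (1, 0.5, -1), checked against an
        explicitly written-out Bernoulli sum."""
        from scipy.special import expit

        t = table(habitat=["H", "H", "M", "L", "L"], success=[1, 0, 1, 1, 0])
        p = base_params(succ_intercept=np.array([1.0, 0.5, -1.0]))
        probs = expit(np.array([1.0, 1.0, 0.5, -1.0, -1.0]))
        y = np.array([1, 0, 1, 1, 0])
        expected = np.sum(y * np.log(probs) + (1 - y) * np.log(1 - probs))
        assert success_loglik(t, p, model_I()) == pytest.approx(expected, abs=1e-12)


class TestFledglingsMean:
    def test_intercept_only(self):
        rec = table(habitat=["H"]).iloc[0]
        assert fledglings_mean(rec, base_params(), model_I()) == pytest.approx(6.7)

    def test_quadratic_is_even_in_covariate(self):
        spec = ModelSpec(variant="III", formulas={
            "succ": RateFormula(year_re=True),
            "fled": RateFormula(terms=[Term("temp", quadratic=True)]),
            "s1": RateFormula(), "s2": RateFormula(), "omega": RateFormula(),
        })
        p = base_params(coefs={"temp": 0.0, "temp2": -0.4})
        t = table(temp=[1.3, -1.3])
        m = fledglings_mean(t, p, spec)
        assert m[0] == pytest.approx(m[1])

    def test_fully_specified_record_against_arithmetic(self):
        """Every term of the final covariate model exercised at once and
        compared to a spreadsheet-style expansion."""
        from hoopoeipm.modelspec import model_III

        spec = model_III(final=True)
        p = base_params(coefs={
            "temp": np.array([0.3, 0.1, -0.2]), "temp2": np.array([-0.2, -0.1, 0.0]),
            "prec": 0.15, "prec2": -0.05, "hat": -0.1, "hat2": -0.2,
            "cs": 0.25, "del": 0.1,
        })
        rec = table(habitat=["M"], temp=[0.8], prec=[-1.2], hat=[0.5],
                    cs=[1.5], **{"del": [-3.0]}).iloc[0]
        expected = (
            6.0
            + 0.1 * 0.8 + (-0.1) * 0.8**2
            + 0.15 * (-1.2) + (-0.05) * (-1.2) ** 2
            + (-0.1) * 0.5 + (-0.2) * 0.5**2
            + 0.25 * 1.5
            + 0.1 * (-3.0)
        )
        assert fledglings_mean(rec, p, spec) == pytest.approx(expected, abs=1e-12)


class TestFledglingsLoglik:
    def test_density_peaks_near_mean(self):
        t1 = table(fledglings=[6.0])
        t2 = table(fledglings=[12.0])
        p = base_params(fled_intercept=np.array([6.0, 6.0, 6.0]), shape=6.0)
        assert fledglings_loglik(t1, p, model_I()) > fledglings_loglik(t2, p, model_I())

    def test_against_scipy_gamma(self):
        from scipy import stats

        t = table(fledglings=[5.0], habitat=["M"])
        p = base_params(fled_intercept=np.array([0, 6.0, 0]), shape=20.0)
        expected = stats.gamma.logpdf(5.0, a=20.0, scale=6.0 / 20.0)
        assert fledglings_loglik(t, p, model_I()) == pytest.approx(expected, abs=1e-10)

    def test_ml_mean_recovery(self, rng):
        """The likelihood's maximiser over the mean sits within 0.1 of the
        generating mean at n = 5,000."""
        from scipy.optimize import minimize_scalar

        y = rng.gamma(6.0, 6.0 / 6.0, 5000)
        t = table(fledglings=y, habitat=["H"] * 5000, success=[1] * 5000)

        def nll(mu):
            p = base_params(fled_intercept=np.array([mu, 1, 1]))
            return -fledglings_loglik(t, p, model_I())

        res = minimize_scalar(nll, bounds=(3, 10), method="bounded")
        assert abs(res.x - 6.0) < 0.1

    def test_delay_slope_recovery(self, rng):
        """Joint intercept/slope fit recovers the generating delay slope
        within 50% at n = 1,000 with ~40% negative delays."""
        from scipy.optimize import minimize

        n = 1000
        dl = rng.normal(0.5, 3.5, n)
        true_slope = 0.3
        mean = 6.0 + np.asarray(threshold_delay_term(dl, true_slope))
        y = rng.gamma(8.0, mean / 8.0)
        spec = ModelSpec(variant="III", formulas={
            "succ": RateFormula(year_re=True),
            "fled": RateFormula(terms=[Term("del", threshold=True)]),
            "s1": RateFormula(), "s2": RateFormula(), "omega": RateFormula(),
        })
        t = table(fledglings=y, habitat=["H"] * n, success=[1] * n, **{"del": dl})

        def nll(x):
            p = base_params(fled_intercept=np.array([x[0], 1, 1]),
                            shape=8.0, coefs={"del": x[1]})
            return -fledglings_loglik(t, p, spec)

        res = minimize(nll, x0=[5.0, 0.0], method="Nelder-Mead")
        assert abs(res.x[1] - true_slope) < 0.5 * true_slope

    def test_rejects_nonpositive_observation(self):
        t = table(fledglings=[0.0])
        with pytest.raises(ValueError):
            fledglings_loglik(t, base_params(), model_I())


class TestAnnualR:
    @pytest.mark.parametrize("psucc,mu,expected", [
        (1.0, 6.7, 3.35),
        (0.0, 6.0, 0.0),
        (0.9, 6.0, 2.7),
    ])
    def test_half_product(self, psucc, mu, expected):
        assert annual_R(psucc, mu) == pytest.approx(expected)


def test_identity_link_shift_matches_symbolic_expansion(rng):
    """Adding c to a covariate changes the quadratic-term mean by exactly
    b1*c + b2*(2*x*c + c^2)."""
    spec = ModelSpec(variant="III", formulas={
        "succ": RateFormula(year_re=True),
        "fled": RateFormula(terms=[Term("temp", quadratic=True)]),
        "s1": RateFormula(), "s2": RateFormula(), "omega": RateFormula(),
    })
    b1, b2 = 0.37, -0.21
    p = base_params(coefs={"temp": b1, "temp2": b2})
    for _ in range(20):
        x, c = rng.normal(size=2)
        m0 = fledglings_mean(table(temp=[x]).iloc[0], p, spec)
        m1 = fledglings_mean(table(temp=[x + c]).iloc[0], p, spec)
        assert m1 - m0 == pytest.approx(b1 * c + b2 * (2 * x * c + c**2), abs=1e-10)
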