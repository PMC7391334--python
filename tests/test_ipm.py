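"""State-space likelihood, joint likelihood, MCMC fit and simplification."""

import numpy as np
import pytest

from hoopoeipm.ipm import (
    Posterior,
    fit,
    ipm_params_from_truth,
    joint_loglik,
    joint_loglik_components,
    model_I,
    model_III,
    simplify_model_III,
)
from hoopoeipm.io import DataBundle
from hoopoeipm.params import AnnualRates, CountTable, PopulationTrajectory, TrueParams
from hoopoeipm.statespace import (
    _sum_binomial_logpmf,
    count_loglik,
    state_loglik,
)


def constant_rates(T, s1=0.2, s2=0.4, psucc=0.8, mu=6.0, omega=0.1, p=0.8):
    return AnnualRates(
        s1=np.full((3, T - 1), s1), s2=np.full((3, T - 1), s2),
        psucc=np.full((3, T), psucc), mu_fled=np.full((3, T), mu),
        omega=np.full((3, T - 1), omega), p=np.full(T - 1, p),
    )


def make_traj(n1, n2, ni, rates=None):
    n1 = np.asarray(n1)
    years = np.arange(2002, 2002 + n1.shape[1])
    return PopulationTrajectory(N1=n1, N2=np.asarray(n2), Ni=np.asarray(ni),
                                years=years, rates=rates)


class TestStateLoglik:
    def test_zero_population_certain(self):
        T = 4
        rates = constant_rates(T, omega=0.0)
        traj = make_traj(np.zeros((3, T), int), np.zeros((3, T), int),
                         np.zeros((3, T), int), rates)
        assert state_loglik(traj) == 0.0

    def test_single_habitat_reduction_matches_pmf_oracle(self):
        """Decoupled habitats at N = 10 reproduce the non-spatial model
        term by term against scipy pmfs."""
        from scipy import stats

        T = 2
        rates = constant_rates(T)
        n1 = np.array([[3, 4], [3, 5], [4, 3]])
        n2 = np.array([[4, 5], [4, 4], [3, 4]])
        ni = np.array([[3, 1], [3, 2], [3, 0]])
        traj = make_traj(n1, n2, ni, rates)
        ll = state_loglik(traj)  # identity movement by default
        R = 0.5 * 0.8 * 6.0
        expected = 0.0
        for h in range(3):
            ntot = 10
            expected += stats.poisson.logpmf(n1[h, 1], R * 0.2 * ntot)
            expected += stats.binom.logpmf(n2[h, 1], ntot, 0.4)
            expected += stats.poisson.logpmf(ni[h, 1], 0.1 * ntot)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_impossible_survivor_count(self):
        T = 2
        rates = constant_rates(T)
        n2 = np.array([[4, 40], [4, 4], [3, 4]])  # more survivors than birds
        traj = make_traj(np.full((3, 2), 3), n2, np.full((3, 2), 3), rates)
        assert state_loglik(traj) == -np.inf

    def test_sum_of_binomials_pmf_matches_enumeration(self, rng):
        """The convolution of the three source binomials agrees with direct
        enumeration over all survivor splits."""
        from scipy import stats

        ns = [3, 4, 2]
        ps = rng.uniform(0.1, 0.6, 3)
        for k in range(sum(ns) + 1):
            total = 0.0
            for k1 in range(ns[0] + 1):
                for k2 in range(ns[1] + 1):
                    k3 = k - k1 - k2
                    if 0 <= k3 <= ns[2]:
                        total += (stats.binom.pmf(k1, ns[0], ps[0])
                                  * stats.binom.pmf(k2, ns[1], ps[1])
                                  * stats.binom.pmf(k3, ns[2], ps[2]))
            got = _sum_binomial_logpmf(k, ns, ps)
            assert np.exp(got) == pytest.approx(total, abs=1e-12)


class TestCountLoglik:
    def test_counts_equal_abundance(self):
        from scipy import stats

        T = 3
        traj = make_traj(np.full((3, T), 2), np.full((3, T), 5),
                         np.full((3, T), 1), constant_rates(T))
        counts = CountTable(counts=traj.Ntot.copy(), years=traj.years)
        expected = 9 * stats.poisson.logpmf(8, 8)
        assert count_loglik(counts, traj) == pytest.approx(expected, abs=1e-10)

    def test_hand_checked_single_cell(self):
        """y = 3, N = 5: log(5^3 e^-5 / 3!)."""
        T = 2
        traj = make_traj(np.full((3, T), 1), np.full((3, T), 3),
                         np.full((3, T), 1), constant_rates(T))
        counts = np.full((3, T), 3)
        ll = count_loglik(CountTable(counts=counts, years=traj.years), traj)
        single = 3 * np.log(5) - 5 - np.log(6)
        assert ll == pytest.approx(6 * single, abs=1e-10)

    def test_more_years_more_terms(self):
        for T, factor in ((2, 2), (4, 4)):
            traj = make_traj(np.full((3, T), 1), np.full((3, T), 3),
                             np.full((3, T), 1), constant_rates(T))
            counts = CountTable(counts=np.full((3, T), 5), years=traj.years)
            one_term = count_loglik(
                CountTable(counts=np.full((3, 1), 5), years=traj.years[:1]),
                make_traj(np.full((3, 1), 1), np.full((3, 1), 3),
                          np.full((3, 1), 1)))
            assert count_loglik(counts, traj) == pytest.approx(
                3 * factor * (one_term / 3), abs=1e-9)


class TestJointLoglik:
    @pytest.fixture(scope="class")
    def bundle_and_params(self, small_bundle):
        bundle, traj = small_bundle
        p = TrueParams(init_N=np.array([[6, 10, 4]] * 3))
        params = ipm_params_from_truth(traj, p.psi1, p.psi2, shape=p.shape_fled)
        return bundle, params

    def test_sum_of_components(self, bundle_and_params):
        bundle, params = bundle_and_params
        comps = joint_loglik_components(bundle, params, model_I())
        assert joint_loglik(bundle, params, model_I()) == sum(comps.values())
        assert set(comps) == {"cmr", "success", "fledglings", "state", "counts"}

    def test_removing_component_changes_total_by_its_value(self, bundle_and_params):
        bundle, params = bundle_and_params
        comps = joint_loglik_components(bundle, params, model_I())
        reduced = DataBundle(
            histories=None, broods=bundle.broods, counts=bundle.counts,
            covariates=bundle.covariates, years=bundle.years)
        assert joint_loglik(reduced, params, model_I()) == pytest.approx(
            joint_loglik(bundle, params, model_I()) - comps["cmr"], abs=1e-9)

    def test_invariant_to_row_order(self, bundle_and_params, rng):
        bundle, params = bundle_and_params
        shuffled = DataBundle(
            histories=bundle.histories,
            broods=bundle.broods.sample(frac=1.0, random_state=1),
            counts=bundle.counts, covariates=bundle.covariates,
            years=bundle.years)
        assert joint_loglik(shuffled, params, model_I()) == pytest.approx(
            joint_loglik(bundle, params, model_I()), abs=1e-9)


class TestFit:
    def test_same_seed_identical_chains(self, small_bundle):
        bundle, _ = small_bundle
        a = fit(model_I(), bundle, n_chains=2, n_iter=40, n_burn=20, seed=5,
                check_convergence=False)
        b = fit(model_I(), bundle, n_chains=2, n_iter=40, n_burn=20, seed=5,
                check_convergence=False)
        for k in a.samples:
            assert np.array_equal(a.samples[k], b.samples[k]), k

    def test_incremental_caches_match_full_refresh(self, small_bundle):
        """After many heterogeneous updates the incrementally maintained
        likelihood components equal a from-scratch recomputation."""
        from hoopoeipm.design import FitData
        from hoopoeipm.mcmc import IPMSampler

        bundle, _ = small_bundle
        smp = IPMSampler(FitData(bundle, model_I()), np.random.SeedSequence(2))
        for _ in range(20):
            smp.iterate()
        incremental = dict(smp.st.ll)
        smp.st.refresh_all()
        for k, v in smp.st.ll.items():
            assert incremental[k] == pytest.approx(v, abs=1e-6), k

    def test_prior_only_run_reproduces_priors(self):
        """With no data the sampler draws from the priors: vague normal
        intercepts, U(0.01, 15) fledgling intercept, U(0, 10) shape."""
        bundle = DataBundle(histories=None, broods=None, counts=None,
                            covariates=None, years=np.arange(2002, 2010))
        post = fit(model_I(), bundle, n_chains=2, n_iter=2000, n_burn=500,
                   seed=3, check_convergence=False)
        fled = post.stacked("a_fled")
        assert abs(fled.mean() - 7.5) < 1.0
        assert fled.min() >= 0.01 and fled.max() <= 15.0
        shape = post.stacked("shape")
        assert abs(shape.mean() - 5.0) < 0.8
        # logit-scale intercept prior sd ~ 31.6
        s2 = post.stacked("a_s2")  # natural scale; spread fills (0, 1)
        assert s2.std() > 0.3

    def test_fit_warns_on_poor_convergence(self, small_bundle):
        bundle, _ = small_bundle
        with pytest.warns(RuntimeWarning, match="R-hat"):
            fit(model_I(), bundle, n_chains=2, n_iter=30, n_burn=10, seed=1)


class _FakePosterior:
    """Stand-in posterior exposing only coefficient draws (synthetic)."""

    def __init__(self, draws: dict):
        self._draws = draws

    def coef_draws(self, rate, name):
        return self._draws[f"{rate}:{name}"]


class TestSimplification:
    def _fake_fit(self, draws):
        def fit_fn(spec, bundle, **kw):
            fit_fn.specs.append(spec)
            return _FakePosterior(draws)
        fit_fn.specs = []
        return fit_fn

    def test_no_optional_terms_returned_unchanged(self):
        spec = model_I()
        final, trail, post = simplify_model_III(
            None, spec, fit_fn=self._fake_fit({}))
        assert trail == []
        assert [f.terms for f in final.formulas.values()] == \
               [f.terms for f in spec.formulas.values()]

    def test_heterogeneous_interaction_retained_null_terms_removed(self, rng):
        """A clearly habitat-heterogeneous temperature effect survives while
        null research-activity terms and homogeneous interactions drop."""
        n = 4000
        draws = {}
        # strongly heterogeneous temp effect on fledglings
        for hab, c in zip("HML", (0.9, 0.0, -0.9)):
            draws[f"fled:temp:{hab}"] = rng.normal(c, 0.1, n)
            draws[f"fled:temp2:{hab}"] = rng.normal(-0.4 * (c != 0), 0.1, n)
        # homogeneous precipitation and hatching effects -> collapse
        for base, c in (("prec", -0.3), ("prec2", 0.1), ("hat", -0.2), ("hat2", -0.1)):
            for hab in "HML":
                draws[f"fled:{base}:{hab}"] = rng.normal(c, 0.05, n)
        # after collapsing, shared coefficients keep the same draws
        for base, c in (("prec", -0.3), ("prec2", 0.1), ("hat", -0.2), ("hat2", -0.1)):
            draws[f"fled:{base}"] = rng.normal(c, 0.05, n)
        draws["fled:cs"] = rng.normal(0.3, 0.05, n)
        draws["fled:del"] = rng.normal(0.15, 0.03, n)
        for name in ("meth", "partag"):
            draws[f"fled:{name}"] = rng.normal(0.0, 0.1, n)
        for name in ("temp", "temp2", "prec", "prec2", "del", "meth", "partag"):
            draws[f"s1:{name}"] = rng.normal(-0.3, 0.05, n)
        for name in ("temp", "temp2", "prec", "prec2"):
            draws[f"s2:{name}"] = rng.normal(-0.3, 0.05, n)
        draws["s2:tag"] = rng.normal(0.0, 0.1, n)

        final, trail, _ = simplify_model_III(
            None, model_III(), fit_fn=self._fake_fit(draws))
        fled = final.formula("fled")
        assert fled.term("temp").by_habitat  # heterogeneous -> retained
        assert not fled.term("prec").by_habitat  # homogeneous -> collapsed
        assert fled.term("meth") is None and fled.term("partag") is None
        assert final.formula("s2").term("tag") is None
        assert fled.term("cs") is not None

    def test_all_null_drops_every_optional_term(self, rng):
        n = 4000
        draws = {}
        for rate in ("fled", "s1", "s2"):
            for name in ("temp", "temp2", "prec", "prec2", "hat", "hat2",
                         "cs", "del", "meth", "partag", "tag"):
                draws[f"{rate}:{name}"] = rng.normal(0.0, 0.1, n)
                for hab in "HML":
                    draws[f"{rate}:{name}:{hab}"] = rng.normal(0.0, 0.1, n)
        final, trail, _ = simplify_model_III(
            None, model_III(), fit_fn=self._fake_fit(draws))
        for rate in ("fled", "s1", "s2"):
            for term in final.formula(rate).terms:
                assert not term.by_habitat
                assert term.name not in ("meth", "partag", "tag", "del")
        assert len(trail) > 5


def test_posterior_save_load_roundtrip(tmp_path, small_bundle):
    bundle, _ = small_bundle
    post = fit(model_I(), bundle, n_chains=2, n_iter=30, n_burn=10, seed=2,
               check_convergence=False)
    path = tmp_path / "post.npz"
    post.save(path)
    loaded = Posterior.load(path)
    assert np.array_equal(loaded.years, post.years)
    for k in post.samples:
        assert np.array_equal(loaded.samples[k], post.samples[k])
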