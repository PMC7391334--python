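"""Integrated population model: joint likelihood, Bayesian fit and backward
model simplification.

The joint likelihood is the sum of four independent components sharing
parameters: the multistate capture–recapture likelihood, the two
productivity GLM likelihoods (success and fledglings), the state-space
process likelihood of the latent habitat-stratified abundances, and the
Poisson count-observation likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from ._dist import logit
from .cmr import MSParams, cmr_dataset_loglik
from .design import FitData
from .io import DataBundle, validate_bundle
from .mcmc import RATE_NAMES, run_chain
from .modelspec import (  # noqa: F401  (public re-exports)
    RESEARCH_TERMS,
    ModelSpec,
    RateFormula,
    Term,
    model_I,
    model_II,
    model_III,
)
from .params import N_HAB, AnnualRates, PopulationTrajectory
from .productivity import (
    ProductivityParams,
    attach_year_covariates,
    fledglings_loglik,
    success_loglik,
)
from .statespace import count_loglik, state_loglik

RHAT_LIMIT = 1.01


@dataclass
class IPMParams:
    """A complete parameter configuration for evaluating the joint likelihood."""

    rates: AnnualRates
    psi1: np.ndarray
    psi2: np.ndarray
    prod: ProductivityParams
    traj: PopulationTrajectory


def ipm_params_from_truth(traj: PopulationTrajectory, psi1, psi2,
                          shape: float, years=None) -> IPMParams:
    """Wrap a simulated trajectory's realised rates as an IPMParams (the
    productivity coefficients are expressed as saturated year effects)."""
    rates = traj.rates
    years = np.asarray(years if years is not None else traj.years)
    prod = ProductivityParams(
        succ_intercept=np.zeros(N_HAB),
        fled_intercept=np.zeros(N_HAB),
        shape=shape,
        years=years,
        succ_year_eff=logit(rates.psucc),
        fled_year_eff=rates.mu_fled.copy(),
    )
    return IPMParams(rates=rates, psi1=np.asarray(psi1), psi2=np.asarray(psi2),
                     prod=prod, traj=traj)


def joint_loglik_components(bundle: DataBundle, params: IPMParams,
                            spec: ModelSpec) -> dict:
    """The four data-set log-likelihood contributions, individually."""
    validate_bundle(bundle)
    out = {}
    ms = MSParams(s1=params.rates.s1, s2=params.rates.s2,
                  psi1=params.psi1, psi2=params.psi2, p=params.rates.p)
    out["cmr"] = (cmr_dataset_loglik(bundle.histories, ms)
                  if bundle.histories is not None else 0.0)
    broods = bundle.broods
    if broods is not None and len(broods):
        if bundle.covariates is not None:
            broods = attach_year_covariates(broods, bundle.covariates)
        out["success"] = success_loglik(broods, params.prod, spec)
        out["fledglings"] = fledglings_loglik(broods, params.prod, spec)
    else:
        out["success"] = out["fledglings"] = 0.0
    out["state"] = state_loglik(params.traj, params.rates, params.psi1, params.psi2)
    out["counts"] = (count_loglik(bundle.counts, params.traj)
                     if bundle.counts is not None else 0.0)
    return out


def joint_loglik(bundle: DataBundle, params: IPMParams, spec: ModelSpec) -> float:
    """Sum of the four component log-likelihoods."""
    return float(sum(joint_loglik_components(bundle, params, spec).values()))


class Posterior:
    """MCMC output: samples, convergence diagnostics and derived quantities.

    ``samples[name]`` has shape (chains, draws, *param_shape).
    """

    def __init__(self, samples: dict, years: np.ndarray, spec: ModelSpec,
                 coef_names: dict, seed: int, meta: dict | None = None):
        self.samples = samples
        self.years = np.asarray(years)
        self.spec = spec
        self.coef_names = coef_names
        self.seed = seed
        self.meta = meta or {}
        self._rhat = None

    # -- basic accessors -----------------------------------------------------

    def stacked(self, name: str) -> np.ndarray:
        s = self.samples[name]
        return s.reshape(-1, *s.shape[2:])

    def mean(self, name: str) -> np.ndarray:
        return self.stacked(name).mean(axis=0)

    def ci(self, name: str, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        a = (1 - level) / 2
        s = self.stacked(name)
        return np.quantile(s, a, axis=0), np.quantile(s, 1 - a, axis=0)

    def coef_draws(self, rate: str, coef: str) -> np.ndarray:
        names = self.coef_names[rate]
        return self.stacked(f"beta_{rate}")[:, names.index(coef)]

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    # -- diagnostics ---------------------------------------------------------

    def rhat(self) -> dict:
        """Gelman–Rubin statistic (max over elements) per saved parameter."""
        if self._rhat is None:
            import arviz as az

            keys = [k for k in self.samples
                    if k.startswith(("a_", "sig_", "beta_"))
                    or k in ("shape", "mean_p", "psi1", "psi2")]
            data = {k: self.samples[k] for k in keys}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rh = az.rhat(az.from_dict(posterior=data))
            self._rhat = {k: float(np.nanmax(rh[k].values)) for k in keys}
        return self._rhat

    def convergence_ok(self, limit: float = RHAT_LIMIT) -> bool:
        return all(v < limit for v in self.rhat().values() if np.isfinite(v))

    # -- derived demographic quantities ---------------------------------------

    def lambda_draws(self) -> np.ndarray:
        """Realized growth rate per draw: ratio of successive totals (all
        habitats summed).  Shape (n_draws, T-1)."""
        ntot = self.stacked("Ntot").sum(axis=1)  # (draws, T)
        return ntot[:, 1:] / np.maximum(ntot[:, :-1], 1e-12)

    def rate_series_draws(self) -> dict:
        """Per-draw annual series used by the retrospective decomposition:
        R, s1, s2, omega over intervals, and the habitat structure pi."""
        R = 0.5 * self.stacked("succ") * self.stacked("fled")
        ntot = self.stacked("Ntot")
        pi = ntot / np.maximum(ntot.sum(axis=1, keepdims=True), 1e-12)
        return {
            "R": R[:, :, :-1],
            "s1": self.stacked("s1"),
            "s2": self.stacked("s2"),
            "omega": self.stacked("omega"),
            "pi": pi[:, :, :-1],
        }

    def project_expected(self, systematic_only: bool = True) -> np.ndarray:
        """Deterministic expectation projection (3, T) of the population from
        the posterior-mean initial stage abundances — the "fitted population
        sizes" used for variance-explained attribution.

        With ``systematic_only`` (default) the projection uses only the
        systematic part of each rate (habitat intercepts plus covariate and
        trend terms): that is the component the model's covariates can
        explain.  Year random effects are excluded — they would absorb any
        annual signal and make every covariate look redundant.
        """
        T = len(self.years)
        pre = "sys_" if systematic_only else ""
        R = 0.5 * self.mean(pre + "succ") * self.mean(pre + "fled")
        s1, s2 = self.mean(pre + "s1"), self.mean(pre + "s2")
        omega = self.mean(pre + "omega")
        psi1, psi2 = self.mean("psi1"), self.mean("psi2")
        n1 = np.zeros((N_HAB, T))
        n2 = np.zeros((N_HAB, T))
        ni = np.zeros((N_HAB, T))
        n1[:, 0] = self.mean("N1")[:, 0]
        n2[:, 0] = self.mean("N2")[:, 0]
        ni[:, 0] = self.mean("Ni")[:, 0]
        for t in range(T - 1):
            ntot = n1[:, t] + n2[:, t] + ni[:, t]
            n1[:, t + 1] = (R[:, t] * s1[:, t] * ntot) @ psi1
            n2[:, t + 1] = (s2[:, t] * ntot) @ psi2
            ni[:, t + 1] = omega[:, t] * ntot
        return n1 + n2 + ni

    def save(self, path) -> None:
        """Columnar archive of the samples plus parameter-name metadata."""
        import json

        meta = {
            "years": [int(y) for y in self.years],
            "variant": self.spec.variant,
            "coef_names": self.coef_names,
            "seed": self.seed,
            "meta": self.meta,
        }
        np.savez_compressed(path, __meta__=json.dumps(meta),
                            **{k: v for k, v in self.samples.items()})

    @classmethod
    def load(cls, path, spec: ModelSpec | None = None) -> "Posterior":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            samples = {k: z[k] for k in z.files if k != "__meta__"}
        from .modelspec import model_I, model_II, model_III

        if spec is None:
            spec = {"I": model_I, "II": model_II, "III": model_III}[meta["variant"]]()
        return cls(samples, np.array(meta["years"]), spec, meta["coef_names"],
                   meta["seed"], meta["meta"])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in ("a_s1", "a_s2", "a_succ", "a_fled", "a_omega"):
            m = self.mean(name)
            lo, hi = self.ci(name)
            for h, hab in enumerate(("H", "M", "L")):
                rows.append((f"{name[2:]}[{hab}]", m[h], lo[h], hi[h]))
        rows.append(("mean_p", float(self.mean("mean_p")),
                     *map(float, self.ci("mean_p"))))
        rows.append(("shape", float(self.mean("shape")),
                     *map(float, self.ci("shape"))))
        return pd.DataFrame(rows, columns=["parameter", "mean", "lo95", "hi95"])


def fit(spec: ModelSpec, bundle: DataBundle, n_chains: int = 3,
        n_iter: int = 3000, n_burn: int = 1500, seed: int = 0,
        check_convergence: bool = True) -> Posterior:
    """Fit one model variant by MCMC.

    Defaults mirror the analysis protocol: 3 chains of 3,000 iterations with
    the first 1,500 discarded as burn-in (during which proposal scales
    adapt), no thinning.  Warns — does not fail — when any saved parameter's
    Gelman–Rubin statistic is 1.01 or above.
    """
    validate_bundle(bundle)
    fd = FitData(bundle, spec)
    per_chain = []
    for c in range(n_chains):
        samples, _ = run_chain(fd, np.random.SeedSequence([seed, c]),
                               n_iter, n_burn)
        per_chain.append(samples)
    stacked = {k: np.stack([s[k] for s in per_chain]) for k in per_chain[0]}
    post = Posterior(
        stacked, bundle.years, spec,
        coef_names={r: list(fd.designs[r].names) for r in RATE_NAMES},
        seed=seed,
        meta={"n_chains": n_chains, "n_iter": n_iter, "n_burn": n_burn},
    )
    if check_convergence and not post.convergence_ok():
        bad = {k: round(v, 3) for k, v in post.rhat().items() if v >= RHAT_LIMIT}
        warnings.warn(f"R-hat >= {RHAT_LIMIT} for: {bad}", RuntimeWarning)
    return post


# ---------------------------------------------------------------------------
# backward simplification of the covariate model
# ---------------------------------------------------------------------------


def _overlap_with_zero(draws: np.ndarray) -> float:
    """Posterior mass on the minority side of 0 (0 = clearly signed,
    0.5 = centred on zero)."""
    pos = float(np.mean(draws > 0))
    return min(pos, 1.0 - pos)


def _candidates(spec: ModelSpec):
    """Yield (rate, term, action, base_coef_names) removable structures, in
    the hierarchy interaction -> quadratic -> research-activity simple term."""
    for rate in ("fled", "s1", "s2"):
        formula = spec.formula(rate)
        for term in formula.terms:
            if term.by_habitat:
                yield rate, term, "collapse", term.coef_names()
            elif term.quadratic:
                yield rate, term, "dequadratify", [term.name + "2"]
            elif term.name in RESEARCH_TERMS:
                yield rate, term, "remove", [term.name]


def _candidate_overlap(post: Posterior, rate: str, action: str,
                       names: list[str]) -> float:
    """Minority-side-of-zero mass of the structure's decisive coefficients.

    For a habitat interaction the decisive quantities are the deviations of
    the per-habitat coefficients from their across-habitat mean (a strong
    but habitat-homogeneous effect collapses to a shared coefficient); for
    anything else it is the coefficient itself.  A group is protected as
    soon as any decisive quantity clearly excludes zero, so the group
    overlap is the minimum over members.
    """
    overlaps = []
    for base in names:
        if action == "collapse":
            draws = np.stack([post.coef_draws(rate, f"{base}:{hab}")
                              for hab in ("H", "M", "L")])
            dev = draws - draws.mean(axis=0, keepdims=True)
            overlaps.extend(_overlap_with_zero(d) for d in dev)
        else:
            overlaps.append(_overlap_with_zero(post.coef_draws(rate, base)))
    return min(overlaps)


def _apply_action(spec: ModelSpec, rate: str, term_name: str, action: str) -> ModelSpec:
    new = spec.copy()
    formula = new.formula(rate)
    term = formula.term(term_name)
    if action == "collapse":
        term.by_habitat = False
    elif action == "dequadratify":
        term.quadratic = False
    else:
        formula.terms.remove(term)
    return new


@dataclass
class SimplificationStep:
    rate: str
    term: str
    action: str
    overlap: float
    n_terms_left: int


def simplify_model_III(
    bundle: DataBundle,
    start_spec: ModelSpec,
    fit_fn: Optional[Callable[..., Posterior]] = None,
    ci_level: float = 0.95,
    **fit_kwargs,
):
    """Backward simplification of the covariate model.

    At each step the removable structure whose coefficients' 95% credible
    intervals overlap 0 the most is dropped: habitat interactions collapse
    to shared coefficients first, quadratic terms reduce to linear, and
    research-activity terms may leave entirely.  A group's overlap is the
    smallest minority-side posterior mass among its member coefficients, so
    a group is protected as soon as any member's interval excludes 0.
    Stops when every remaining candidate excludes 0.

    Returns ``(final_spec, trail, final_posterior)``.
    """
    fit_fn = fit_fn or fit
    spec = start_spec.copy()
    trail: list[SimplificationStep] = []
    threshold = (1 - ci_level) / 2
    while True:
        try:
            post = fit_fn(spec, bundle, **fit_kwargs)
        except Exception as e:  # noqa: BLE001 - record and stop, keep last good fit
            warnings.warn(f"simplification fit failed ({e}); stopping")
            break
        best = None
        for rate, term, action, names in _candidates(spec):
            try:
                overlap = _candidate_overlap(post, rate, action, names)
            except (KeyError, ValueError):
                continue
            if best is None or overlap > best[3]:
                best = (rate, term.name, action, overlap)
        if best is None or best[3] < threshold:
            return spec, trail, post
        rate, term_name, action, overlap = best
        spec = _apply_action(spec, rate, term_name, action)
        trail.append(SimplificationStep(
            rate=rate, term=term_name, action=action, overlap=overlap,
            n_terms_left=sum(len(spec.formula(r).terms) for r in RATE_NAMES),
        ))
    return spec, trail, None
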