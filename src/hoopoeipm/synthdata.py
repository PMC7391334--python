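"""Synthetic data generator for the habitat-stratified population model.

Everything here draws from exactly the stochastic structure the integrated
model assumes: Poisson recruitment and immigration, binomial adult survival
with movement between habitat-quality classes, Bernoulli-logit reproductive
success, gamma fledgling numbers of successful females, Bernoulli recapture
with a logit-normal year effect, and Poisson count observation.  Known "true"
parameters go in, the four data tables come out, which makes full
simulation–estimation round trips possible without the field data.

The default scenario is a 16-year, three-habitat population whose
habitat-specific mean fledgling numbers are (6.7, 6.0, 5.9) for (H, M, L) and
whose mean recapture probability is 0.81; survival, immigration and initial
sizes are scenario defaults chosen to keep the default population roughly
stationary (see docs/methods.md).
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from ._dist import logit
from .params import (
    HABITATS,
    N_HAB,
    AnnualRates,
    CaptureHistorySet,
    CountTable,
    PopulationTrajectory,
    TrueParams,
)
from .productivity import threshold_delay_term

# generative distributions of the record-level brood covariates; hat and cs
# are generated directly as z-scores, capture delay on the raw day scale
DEL_SD = 3.0
P_METH = 0.5
P_PARTAG = 0.3
P_TAG = 0.1


def generate_covariates(
    n_years: int,
    seed: int,
    start_year: int = 2002,
    temp_trend: float = 0.0,
    prec_trend: float = 0.0,
    del_mean_start: float = 0.5,
    del_mean_end: float = -4.5,
) -> pd.DataFrame:
    """Annual covariate table: standardised spring weather + mean capture delay.

    ``temp`` and ``prec`` are z-scored over the generated years (after adding
    any linear trend).  ``del_mean`` is the annual mean of the maternal
    capture delay in raw days; its default drifts from +0.5 to -4.5 days,
    emulating a field protocol in which mothers were captured progressively
    earlier relative to hatching.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)
    ys = (np.arange(n_years) - (n_years - 1) / 2) / max(n_years / 4, 1)
    temp = rng.standard_normal(n_years) + temp_trend * ys
    prec = rng.standard_normal(n_years) + prec_trend * ys
    temp = (temp - temp.mean()) / temp.std(ddof=0)
    prec = (prec - prec.mean()) / prec.std(ddof=0)
    del_mean = np.linspace(del_mean_start, del_mean_end, n_years)
    return pd.DataFrame(
        {"year": years, "temp": temp, "prec": prec, "del_mean": del_mean}
    )


def _year_std(n_years: int) -> np.ndarray:
    y = np.arange(n_years, dtype=float)
    return (y - y.mean()) / y.std(ddof=0)


def _habitat_coef(effects: dict, name: str) -> np.ndarray:
    v = effects.get(name, 0.0)
    v = np.asarray(v, dtype=float)
    return np.repeat(v, N_HAB) if v.ndim == 0 else v


def _rate_linpred(
    base_link: np.ndarray,
    n_steps: int,
    year_idx: np.ndarray,
    trend: np.ndarray,
    effects: dict,
    cov: pd.DataFrame | None,
    n_years: int,
) -> np.ndarray:
    """(3, n_steps) link-scale predictor: base + trend + annual weather terms."""
    ys = _year_std(n_years)[year_idx]
    eta = base_link[:, None] + trend[:, None] * ys[None, :]
    if cov is not None:
        temp = cov["temp"].to_numpy()[year_idx]
        prec = cov["prec"].to_numpy()[year_idx]
        for name, x in (("temp", temp), ("prec", prec)):
            eta += _habitat_coef(effects, name)[:, None] * x[None, :]
            eta += _habitat_coef(effects, name + "2")[:, None] * (x**2)[None, :]
    return eta


def expected_record_contribution(
    params: TrueParams, cov: pd.DataFrame, n_years: int
) -> np.ndarray:
    """Annual expectation of the record-level terms of the fledgling mean.

    hat and cs are standard-normal z-scores, so their linear terms average to
    zero and a quadratic hat term contributes its coefficient once
    (E[hat^2] = 1).  The threshold capture-delay term has expectation
    slope * E[min(del, 0)] under del ~ Normal(del_mean_t, DEL_SD).
    """
    eff = params.covariate_effects.get("fled", {})
    out = np.zeros(n_years)
    out += float(eff.get("hat2", 0.0)) * 1.0
    out += float(eff.get("meth", 0.0)) * P_METH
    out += float(eff.get("partag", 0.0)) * P_PARTAG
    slope = float(eff.get("del", 0.0))
    if slope != 0.0:
        m = cov["del_mean"].to_numpy()[:n_years]
        s = DEL_SD
        # E[min(X, 0)] for X ~ N(m, s)
        e_neg = m * norm.cdf(-m / s) - s * norm.pdf(m / s)
        out += slope * e_neg
    return out


def draw_annual_rates(
    params: TrueParams,
    n_years: int,
    rng: np.random.Generator,
    cov: pd.DataFrame | None = None,
    deterministic: bool = False,
) -> AnnualRates:
    """Realise annual demographic rates from intercepts, trends, covariate
    effects, and year random deviations.

    The population-level fledgling mean includes the annual expectation of
    the record-level covariate terms so the trajectory's reproduction is
    consistent with the brood records the productivity simulator produces.
    """
    t_all = np.arange(n_years)
    t_int = np.arange(n_years - 1)

    def re(sigma, n):
        if deterministic:
            return np.zeros((N_HAB, n))
        return rng.standard_normal((N_HAB, n)) * sigma[:, None]

    def make(rate, base, link, year_idx, sigma):
        eta = _rate_linpred(
            link(base),
            len(year_idx),
            year_idx,
            _habitat_coef(params.trend, rate) if rate in params.trend else np.zeros(N_HAB),
            params.covariate_effects.get(rate, {}),
            cov,
            n_years,
        )
        eta = eta + re(sigma, len(year_idx))
        return eta

    s1 = expit(make("s1", params.s1, logit, t_int, params.sigma_s1))
    s2 = expit(make("s2", params.s2, logit, t_int, params.sigma_s2))
    psucc = expit(make("succ", params.psucc, logit, t_all, params.sigma_succ))
    mu = make("fled", params.mu_fled, lambda x: x, t_all, params.sigma_fled)
    if cov is not None:
        mu = mu + expected_record_contribution(params, cov, n_years)[None, :]
    if np.any(mu <= 0):
        raise ValueError("annual fledgling means must stay positive; "
                         "reduce sigma_fled or covariate effects")
    omega = expit(make("omega", params.omega, logit, t_int, params.sigma_omega))
    if deterministic:
        p = np.full(n_years - 1, expit(params.p_mean))
    else:
        p = expit(params.p_mean + rng.standard_normal(n_years - 1) * params.p_sd)
    return AnnualRates(s1=s1, s2=s2, psucc=psucc, mu_fled=mu, omega=omega, p=p)


def simulate_population(
    params: TrueParams,
    n_years: int,
    seed: int,
    cov: pd.DataFrame | None = None,
    start_year: int = 2002,
    deterministic: bool = False,
) -> PopulationTrajectory:
    """Project the habitat-stratified population forward n_years.

    Recruits in habitat h at t+1 are Poisson with mean
    sum_src R_src S1_src psi1[src, h] Ntot_src; experienced adults are the sum
    over sources of Binomial(Ntot_src, S2_src psi2[src, h]); immigrants are
    Poisson(omega_h Ntot_h).  ``deterministic=True`` replaces every draw by
    its expectation (float-valued trajectory, used by oracle tests).
    """
    if n_years < 2:
        raise ValueError("need n_years >= 2")
    rng = np.random.default_rng(seed)
    rates = draw_annual_rates(params, n_years, rng, cov=cov, deterministic=deterministic)
    R = rates.R

    dtype = float if deterministic else int
    N1 = np.zeros((N_HAB, n_years), dtype=dtype)
    N2 = np.zeros((N_HAB, n_years), dtype=dtype)
    Ni = np.zeros((N_HAB, n_years), dtype=dtype)
    N1[:, 0] = params.init_N[:, 0]
    N2[:, 0] = params.init_N[:, 1]
    Ni[:, 0] = params.init_N[:, 2]

    for t in range(n_years - 1):
        ntot = N1[:, t] + N2[:, t] + Ni[:, t]
        rec_mean = (R[:, t] * rates.s1[:, t] * ntot) @ params.psi1
        surv_p = rates.s2[:, t][:, None] * params.psi2  # (src, dest)
        imm_mean = rates.omega[:, t] * ntot
        if deterministic:
            N1[:, t + 1] = rec_mean
            N2[:, t + 1] = (ntot[:, None] * surv_p).sum(axis=0)
            Ni[:, t + 1] = imm_mean
        else:
            N1[:, t + 1] = rng.poisson(rec_mean)
            B = rng.binomial(np.broadcast_to(ntot[:, None], (N_HAB, N_HAB)), surv_p)
            N2[:, t + 1] = B.sum(axis=0)
            Ni[:, t + 1] = rng.poisson(imm_mean)

    years = np.arange(start_year, start_year + n_years)
    return PopulationTrajectory(N1=N1, N2=N2, Ni=Ni, years=years, rates=rates)


def simulate_capture_histories(
    traj: PopulationTrajectory,
    params: TrueParams,
    seed: int,
    rates: AnnualRates | None = None,
) -> CaptureHistorySet:
    """Mark cohorts of nestlings and adults and follow them with the
    age-structured survival × movement × recapture process.

    New marks per habitat and year are Poisson with per-capita rates
    ``mark_rate_juv`` (ringed nestlings, first interval governed by
    first-year rates) and ``mark_rate_adult`` (first captures of adults).
    Every marked bird is observed at its marking occasion; afterwards it is
    re-encountered with probability p_t while alive and in the study area.
    """
    rates = rates if rates is not None else traj.rates
    if rates is None:
        raise ValueError("trajectory carries no realised rates; pass rates=")
    T = traj.n_years
    rng = np.random.default_rng(seed)
    ntot = traj.Ntot

    first_occ, first_age, obs_rows = [], [], []
    for t0 in range(T - 1):
        for h in range(N_HAB):
            for age0, rate in ((0, params.mark_rate_juv), (1, params.mark_rate_adult)):
                n_new = rng.poisson(rate * ntot[h, t0])
                for _ in range(n_new):
                    obs = np.zeros(T, dtype=int)
                    obs[t0] = h + 1
                    state = h
                    for t in range(t0, T - 1):
                        juv = age0 == 0 and t == t0
                        s = rates.s1[state, t] if juv else rates.s2[state, t]
                        psi = params.psi1 if juv else params.psi2
                        if rng.random() >= s:
                            break
                        state = rng.choice(N_HAB, p=psi[state])
                        if rng.random() < rates.p[t]:
                            obs[t + 1] = state + 1
                    first_occ.append(t0)
                    first_age.append(age0)
                    obs_rows.append(obs)
    if not obs_rows:
        return CaptureHistorySet(
            first_occ=np.zeros(0, dtype=int),
            first_age=np.zeros(0, dtype=int),
            obs=np.zeros((0, T), dtype=int),
        )
    return CaptureHistorySet(
        first_occ=np.array(first_occ),
        first_age=np.array(first_age),
        obs=np.array(obs_rows),
    )


def simulate_productivity(
    traj: PopulationTrajectory,
    params: TrueParams,
    cov: pd.DataFrame,
    seed: int,
    rates: AnnualRates | None = None,
    round_fledglings: bool = False,
) -> pd.DataFrame:
    """One brood record per breeding female and year.

    The number of breeding females per habitat-year equals the prebreeding
    census total (the population of nonbreeders is taken as negligible).
    Success is Bernoulli on the annual habitat rate; fledglings of successful
    females are gamma with the record-level identity-link mean (annual core
    mean + covariate terms incl. the threshold capture-delay effect) and the
    shared shape.
    """
    rates = rates if rates is not None else traj.rates
    if rates is None:
        raise ValueError("trajectory carries no realised rates; pass rates=")
    T = traj.n_years
    rng = np.random.default_rng(seed)
    eff = params.covariate_effects.get("fled", {})
    exp_contrib = expected_record_contribution(params, cov, T)
    mu_core = rates.mu_fled - exp_contrib[None, :]  # annual mean net of record terms
    del_mean = cov["del_mean"].to_numpy()

    rows = []
    fid = 0
    ntot = traj.Ntot
    for t in range(T):
        for h in range(N_HAB):
            n_fem = int(ntot[h, t])
            if params.brood_fraction < 1.0:
                n_fem = int(rng.binomial(n_fem, params.brood_fraction))
            if n_fem == 0:
                continue
            hat = rng.standard_normal(n_fem)
            cs = rng.standard_normal(n_fem)
            dl = rng.normal(del_mean[t], DEL_SD, n_fem)
            meth = rng.binomial(1, P_METH, n_fem)
            partag = rng.binomial(1, P_PARTAG, n_fem)
            tag = rng.binomial(1, P_TAG, n_fem)
            succ = rng.binomial(1, rates.psucc[h, t], n_fem)
            mean = (
                mu_core[h, t]
                + float(eff.get("hat", 0.0)) * hat
                + float(eff.get("hat2", 0.0)) * hat**2
                + float(eff.get("cs", 0.0)) * cs
                + float(eff.get("meth", 0.0)) * meth
                + float(eff.get("partag", 0.0)) * partag
                + threshold_delay_term(dl, float(eff.get("del", 0.0)))
            )
            fled = np.full(n_fem, np.nan)
            ok = succ == 1
            if np.any(ok):
                if np.any(mean[ok] <= 0):
                    bad = int(np.flatnonzero(ok & (mean <= 0))[0])
                    raise ValueError(
                        f"non-positive gamma mean {mean[bad]:.3f} for record "
                        f"(habitat={HABITATS[h]}, year={traj.years[t]}, row={bad})"
                    )
                draw = rng.gamma(params.shape_fled, mean[ok] / params.shape_fled)
                if round_fledglings:
                    draw = np.maximum(1, np.round(draw))
                fled[ok] = draw
            for i in range(n_fem):
                rows.append(
                    (
                        fid + i,
                        int(traj.years[t]),
                        HABITATS[h],
                        int(succ[i]),
                        fled[i],
                        cs[i],
                        hat[i],
                        dl[i],
                        int(meth[i]),
                        int(partag[i]),
                        int(tag[i]),
                    )
                )
            fid += n_fem
    return pd.DataFrame(
        rows,
        columns=[
            "female_id", "year", "habitat", "success", "fledglings",
            "cs", "hat", "del", "meth", "partag", "tag",
        ],
    )


def simulate_counts(traj: PopulationTrajectory, seed: int) -> CountTable:
    """Poisson count index of population size: y[h, t] ~ Poisson(Ntot[h, t])."""
    rng = np.random.default_rng(seed)
    return CountTable(counts=rng.poisson(traj.Ntot), years=traj.years.copy())


def simulate_bundle(
    params: TrueParams,
    n_years: int = 16,
    seed: int = 0,
    start_year: int = 2002,
    cov: pd.DataFrame | None = None,
):
    """Generate the four linked data tables plus the underlying truth.

    Returns a ``(bundle, traj)`` pair; sub-seeds for the four stochastic
    stages are spawned deterministically from ``seed``.
    """
    from .io import DataBundle  # local import to avoid a cycle

    ss = np.random.SeedSequence(seed).generate_state(5)
    if cov is None:
        cov = generate_covariates(n_years, int(ss[0]), start_year=start_year)
    traj = simulate_population(params, n_years, int(ss[1]), cov=cov, start_year=start_year)
    hist = simulate_capture_histories(traj, params, int(ss[2]))
    broods = simulate_productivity(traj, params, cov, int(ss[3]))
    counts = simulate_counts(traj, int(ss[4]))
    bundle = DataBundle(
        histories=hist,
        broods=broods,
        counts=counts,
        covariates=cov,
        years=traj.years.copy(),
        meta={"seed": int(seed), "synthetic": True},
    )
    return bundle, traj
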