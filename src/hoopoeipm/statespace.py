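"""State-space component of the integrated likelihood.

The demographic process: recruits into habitat h are Poisson with mean
``sum_src R_src S1_src psi1[src, h] Ntot_src``; experienced adults are the
sum over source habitats of independent Binomial(Ntot_src, S2_src
psi2[src, h]) draws; immigrants are Poisson(omega_h Ntot_h).  The count
index observes the totals with Poisson error.

Two evaluations of the adult-survivor term are provided: the exact
convolution of the three source binomials (public ``state_loglik``, working
from a trajectory alone) and an augmented form over latent
source→destination survivor counts (used by the sampler, where the flows
``B[src, dest, t]`` are explicit states).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._dist import binomial_logpmf, poisson_logpmf
from .params import N_HAB, CountTable, PopulationTrajectory


def _check_int(a, name):
    a = np.asarray(a)
    if np.any(a != np.floor(a)) or np.any(a < 0):
        raise ValueError(f"{name} must be non-negative integers")
    return a.astype(int)


def _sum_binomial_logpmf(k: int, ns, ps) -> float:
    """Exact log pmf of a sum of independent Binomial(n_i, p_i) at k."""
    pmf = np.ones(1)
    for n, p in zip(ns, ps):
        comp = stats.binom.pmf(np.arange(int(n) + 1), int(n), p)
        pmf = np.convolve(pmf, comp)
    if k < 0 or k >= pmf.size:
        return -np.inf
    val = pmf[int(k)]
    return float(np.log(val)) if val > 0 else -np.inf


def state_loglik(traj: PopulationTrajectory, rates=None, psi1=None, psi2=None) -> float:
    """Log-probability of a latent trajectory under the process model.

    ``rates`` defaults to the realised rates stored on the trajectory.
    Impossible states (e.g. more survivors than any source configuration
    allows) return -inf.
    """
    rates = rates if rates is not None else traj.rates
    if rates is None:
        raise ValueError("no rates supplied")
    psi1 = np.asarray(psi1) if psi1 is not None else np.eye(N_HAB)
    psi2 = np.asarray(psi2) if psi2 is not None else np.eye(N_HAB)
    n1 = _check_int(traj.N1, "N1")
    n2 = _check_int(traj.N2, "N2")
    ni = _check_int(traj.Ni, "Ni")
    ntot = n1 + n2 + ni
    T = traj.n_years
    R = rates.R

    ll = 0.0
    for t in range(T - 1):
        rec_mean = (R[:, t] * rates.s1[:, t] * ntot[:, t]) @ psi1
        ll += float(np.sum(poisson_logpmf(n1[:, t + 1], rec_mean)))
        for dest in range(N_HAB):
            ll += _sum_binomial_logpmf(
                n2[dest, t + 1],
                ntot[:, t],
                rates.s2[:, t] * psi2[:, dest],
            )
        ll += float(np.sum(poisson_logpmf(ni[:, t + 1], rates.omega[:, t] * ntot[:, t])))
        if not np.isfinite(ll):
            return -np.inf
    return ll


def state_loglik_augmented(
    n1: np.ndarray,  # (3, T) recruits; column 0 = initial recruits
    n2: np.ndarray,  # (3, T) experienced adults (t >= 1 must equal B sums)
    ni: np.ndarray,  # (3, T) immigrants
    b2: np.ndarray,  # (3, 3, T-1) latent survivor flows src -> dest
    s1: np.ndarray,
    s2: np.ndarray,
    R: np.ndarray,
    omega: np.ndarray,
    psi1: np.ndarray,
    psi2: np.ndarray,
) -> float:
    """Process log-probability with explicit survivor flows (no convolution)."""
    ntot = n1 + n2 + ni
    rec_mean = np.einsum("st,sd->dt", R[:, :-1] * s1 * ntot[:, :-1], psi1)
    ll = float(np.sum(poisson_logpmf(n1[:, 1:], rec_mean)))
    q = s2[:, None, :] * psi2[:, :, None]  # (src, dest, t)
    ll += float(np.sum(binomial_logpmf(b2, ntot[:, None, :-1], q)))
    ll += float(np.sum(poisson_logpmf(ni[:, 1:], omega * ntot[:, :-1])))
    return ll


def count_loglik(counts: CountTable, traj: PopulationTrajectory) -> float:
    """Poisson observation model: y[h, t] ~ Poisson(Ntot[h, t])."""
    y = _check_int(counts.counts, "counts")
    if y.shape != traj.Ntot.shape:
        raise ValueError("count table and trajectory shapes differ")
    return float(np.sum(poisson_logpmf(y, traj.Ntot.astype(float))))
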