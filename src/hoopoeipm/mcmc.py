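"""Adaptive Metropolis-within-Gibbs sampler for the integrated model.

The posterior is explored with single-site or small-block random-walk
Metropolis updates whose proposal scales adapt during burn-in
(Robbins–Monro on the log scale, targeting ~0.44 acceptance for scalar and
~0.25 for block updates).  Latent abundances and the survivor flows are
integer-valued states updated with symmetric integer random walks and local
likelihood evaluation; the full likelihood components are refreshed from the
caches once per iteration, so a single iteration costs a handful of
capture–recapture forward passes plus vectorised GLM evaluations.

Priors follow the analysis defaults: Normal(0, var 1000) for intercepts and
slopes on the link scale, Uniform(0.01, 15) for the fledgling intercept,
Uniform(0, 10) for random-effect standard deviations and the gamma shape,
Dirichlet(1,1,1) for movement rows (sampled in additive-log-ratio
coordinates), and discrete-uniform [0, 5 x first count] initial abundances.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.special import expit

from ._dist import gamma_logpdf_mean_shape, poisson_logpmf
from .cmr import _forward_batch
from .design import FitData
from .params import N_HAB

_SLOPE_SD = math.sqrt(1000.0)
_SIG_MAX = 10.0
_SHAPE_MAX = 10.0
_FLED_LO, _FLED_HI = 0.01, 15.0

_EXPIT_RATES = ("s1", "s2", "succ", "omega")
RATE_NAMES = ("succ", "fled", "s1", "s2", "omega")


@njit(cache=True)
def _pois_lp(k, mu):  # pragma: no cover - numba
    if mu <= 0.0:
        return 0.0 if (k == 0 and mu == 0.0) else -np.inf
    return k * math.log(mu) - mu - math.lgamma(k + 1.0)


@njit(cache=True)
def _bin_lp(k, n, p):  # pragma: no cover - numba
    if k < 0 or k > n or n < 0:
        return -np.inf
    if p <= 0.0:
        return 0.0 if k == 0 and p == 0.0 else -np.inf
    if p >= 1.0:
        return 0.0 if k == n and p == 1.0 else -np.inf
    return (
        math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)
        + k * math.log(p) + (n - k) * math.log1p(-p)
    )


@njit(cache=True)
def _pois_sum(k, mu):  # pragma: no cover - numba
    s = 0.0
    for i in range(k.size):
        s += _pois_lp(k[i], mu[i])
    return s


@njit(cache=True)
def _bin_sum(k, n, p):  # pragma: no cover - numba
    s = 0.0
    for i in range(k.size):
        s += _bin_lp(k[i], n[i], p[i])
    return s


@njit(cache=True)
def _pois_sum2d(k, mu):  # pragma: no cover - numba
    s = 0.0
    for i in range(k.shape[0]):
        for j in range(k.shape[1]):
            s += _pois_lp(k[i, j], mu[i, j])
    return s


@njit(cache=True)
def _bin_sum_b2(b2, ntot, q):  # pragma: no cover - numba
    """Sum of Binomial(b2[s,d,t]; ntot[s,t], q[s,d,t]) log-pmfs."""
    s = 0.0
    for i in range(b2.shape[0]):
        for j in range(b2.shape[1]):
            for t in range(b2.shape[2]):
                s += _bin_lp(b2[i, j, t], ntot[i, t], q[i, j, t])
    return s


@njit(cache=True)
def _pois_colsum_diff(k, m0, m1):  # pragma: no cover - numba
    """Per-column difference of Poisson log-pmf sums: (T,) vector of
    sum_rows [log Pois(k; m1) - log Pois(k; m0)]."""
    T = k.shape[1]
    out = np.zeros(T)
    for t in range(T):
        for i in range(k.shape[0]):
            out[t] += _pois_lp(k[i, t], m1[i, t]) - _pois_lp(k[i, t], m0[i, t])
    return out


@njit(cache=True)
def _ntot_delta_nb(h, t, d, n1, ni, b2, ntot, rec_mean, crs, q2, omg, y):  # pragma: no cover
    """Loglik change of every term depending on Ntot[h, t] when it moves by d
    (count observation + downstream process terms at t -> t+1)."""
    T = n1.shape[1]
    n_old = ntot[h, t]
    n_new = n_old + d
    if n_new < 0:
        return -np.inf
    delta = _pois_lp(y[h, t], float(n_new)) - _pois_lp(y[h, t], float(n_old))
    if t <= T - 2:
        for dest in range(N_HAB):
            m0 = rec_mean[dest, t]
            delta += _pois_lp(n1[dest, t + 1], m0 + d * crs[h, dest, t]) \
                - _pois_lp(n1[dest, t + 1], m0)
            delta += _bin_lp(b2[h, dest, t], n_new, q2[h, dest, t]) \
                - _bin_lp(b2[h, dest, t], n_old, q2[h, dest, t])
        delta += _pois_lp(ni[h, t + 1], omg[h, t] * n_new) \
            - _pois_lp(ni[h, t + 1], omg[h, t] * n_old)
    return delta


@njit(cache=True)
def _apply_ntot_nb(h, t, d, ntot, rec_mean, crs):  # pragma: no cover
    ntot[h, t] += d
    if t <= ntot.shape[1] - 2:
        for dest in range(N_HAB):
            rec_mean[dest, t] += d * crs[h, dest, t]


@njit(cache=True)
def _adapt_scale(scale, n, acc, target):  # pragma: no cover
    step = min(0.25, n ** -0.6)
    s = scale * math.exp(step * ((1.0 if acc else 0.0) - target))
    return min(max(s, 1e-4), 1e4)


@njit(cache=True)
def _latent_sweep_nb(n1, n2, ni, ntot, b2, rec_mean, crs, q2, omg, y, init_ub,
                     sc_n1, sc_ni, sc_n2, sc_b2, ct_n1, ct_ni, ct_n2, ct_b2,
                     adapting, norm, unif, coin):  # pragma: no cover - numba
    """One Metropolis sweep over all latent abundances and survivor flows.

    Proposals are symmetric integer steps; each site's acceptance uses only
    the local likelihood terms it touches.  Proposal scales adapt in place
    during burn-in.
    """
    T = n1.shape[1]
    idx = 0
    for h in range(N_HAB):
        for t in range(T):
            for fam in range(2):  # 0 = recruits, 1 = immigrants
                sc = sc_n1[h, t] if fam == 0 else sc_ni[h, t]
                mag = 1 + int(abs(norm[idx]) * sc)
                d = mag if coin[idx] < 0.5 else -mag
                arr = n1 if fam == 0 else ni
                new = arr[h, t] + d
                if new < 0 or (t == 0 and new > init_ub[h]):
                    delta = -np.inf
                else:
                    delta = 0.0
                    if t > 0:
                        mean = rec_mean[h, t - 1] if fam == 0 \
                            else omg[h, t - 1] * ntot[h, t - 1]
                        delta += _pois_lp(new, mean) - _pois_lp(arr[h, t], mean)
                    delta += _ntot_delta_nb(h, t, d, n1, ni, b2, ntot,
                                            rec_mean, crs, q2, omg, y)
                acc = np.isfinite(delta) and (
                    delta >= 0.0 or unif[idx] < math.exp(max(delta, -745.0)))
                if acc:
                    arr[h, t] = new
                    _apply_ntot_nb(h, t, d, ntot, rec_mean, crs)
                if adapting:
                    if fam == 0:
                        ct_n1[h, t] += 1.0
                        sc_n1[h, t] = _adapt_scale(sc, ct_n1[h, t], acc, 0.44)
                    else:
                        ct_ni[h, t] += 1.0
                        sc_ni[h, t] = _adapt_scale(sc, ct_ni[h, t], acc, 0.44)
                idx += 1
        # initial experienced adults
        sc = sc_n2[h]
        mag = 1 + int(abs(norm[idx]) * sc)
        d = mag if coin[idx] < 0.5 else -mag
        new = n2[h, 0] + d
        if new < 0 or new > init_ub[h]:
            delta = -np.inf
        else:
            delta = _ntot_delta_nb(h, 0, d, n1, ni, b2, ntot,
                                   rec_mean, crs, q2, omg, y)
        acc = np.isfinite(delta) and (
            delta >= 0.0 or unif[idx] < math.exp(max(delta, -745.0)))
        if acc:
            n2[h, 0] = new
            _apply_ntot_nb(h, 0, d, ntot, rec_mean, crs)
        if adapting:
            ct_n2[h] += 1.0
            sc_n2[h] = _adapt_scale(sc, ct_n2[h], acc, 0.44)
        idx += 1

    # survivor flows; n2 at t >= 1 is their column sum
    for src in range(N_HAB):
        for dest in range(N_HAB):
            for t in range(T - 1):
                sc = sc_b2[src, dest, t]
                mag = 1 + int(abs(norm[idx]) * sc)
                d = mag if coin[idx] < 0.5 else -mag
                new = b2[src, dest, t] + d
                q = q2[src, dest, t]
                if new < 0 or new > ntot[src, t]:
                    delta = -np.inf
                else:
                    delta = _bin_lp(new, ntot[src, t], q) \
                        - _bin_lp(b2[src, dest, t], ntot[src, t], q)
                    delta += _ntot_delta_nb(dest, t + 1, d, n1, ni, b2, ntot,
                                            rec_mean, crs, q2, omg, y)
                acc = np.isfinite(delta) and (
                    delta >= 0.0 or unif[idx] < math.exp(max(delta, -745.0)))
                if acc:
                    b2[src, dest, t] = new
                    n2[dest, t + 1] += d
                    _apply_ntot_nb(dest, t + 1, d, ntot, rec_mean, crs)
                if adapting:
                    ct_b2[src, dest, t] += 1.0
                    sc_b2[src, dest, t] = _adapt_scale(sc, ct_b2[src, dest, t],
                                                       acc, 0.44)
                idx += 1


class _Adapt:
    """Robbins–Monro adaptation of one proposal scale during burn-in."""

    __slots__ = ("scale", "target", "n")

    def __init__(self, scale: float, target: float = 0.44):
        self.scale = scale
        self.target = target
        self.n = 0

    def update(self, accepted: bool):
        self.n += 1
        step = min(0.25, self.n ** -0.6)
        self.scale *= math.exp(step * ((1.0 if accepted else 0.0) - self.target))
        self.scale = min(max(self.scale, 1e-4), 1e4)


def _alr_to_simplex(z: np.ndarray) -> np.ndarray:
    """Row-wise additive log-ratio -> movement matrix; the diagonal (staying)
    is the reference category."""
    psi = np.empty((N_HAB, N_HAB))
    for i in range(N_HAB):
        e = np.ones(N_HAB)
        k = 0
        for j in range(N_HAB):
            if j != i:
                e[j] = math.exp(z[i, k])
                k += 1
        psi[i] = e / e.sum()
    return psi


class ChainState:
    """All parameters, latent states and likelihood caches of one chain."""

    def __init__(self, fd: FitData, rng: np.random.Generator):
        self.fd = fd
        self.spec = fd.spec
        self.rng = rng
        T = fd.T
        self.has_counts = fd.counts is not None
        self.has_cmr = fd.ch is not None and fd.ch.obs.shape[0] > 0
        self.n_rec = len(fd.broods)
        self.n_rec1 = fd.fled_y.size

        # --- parameters -----------------------------------------------------
        self.a = {}
        self.beta = {r: np.zeros(fd.designs[r].K) for r in RATE_NAMES}
        self.eps = {}
        self.sig = {}
        for r in RATE_NAMES:
            Tg = T if r in ("succ", "fled") else T - 1
            if self.spec.formula(r).year_re:
                self.eps[r] = np.zeros((N_HAB, Tg))
                self.sig[r] = np.full(N_HAB, 0.1)
        self.z1 = np.full((N_HAB, 2), math.log(0.1 / 0.8))
        self.z2 = np.full((N_HAB, 2), math.log(0.1 / 0.8))
        self.mu_p = 1.4
        self.sig_p = 0.1
        self.eps_p = np.zeros(T - 1)
        self.shape = 5.0
        self._init_intercepts()

        # --- latent abundances ---------------------------------------------
        if self.has_counts:
            self._init_latents()
        else:
            self.n1 = self.n2 = self.ni = self.b2 = None

        self.refresh_all()
        if not np.isfinite(self.total_ll()):
            parts = {k: v for k, v in self.ll.items()}
            raise RuntimeError(
                f"non-finite initial joint log-likelihood; components: {parts}"
            )

    # -- initial values ------------------------------------------------------

    def _init_intercepts(self):
        fd = self.fd
        if self.n_rec:
            ps = np.array([
                fd.succ_y[fd.hab_rec[h]].mean() if fd.hab_rec[h].size else 0.8
                for h in range(N_HAB)
            ])
            mf = np.array([
                fd.fled_y[fd.hab_rec1[h]].mean() if fd.hab_rec1[h].size else 6.0
                for h in range(N_HAB)
            ])
        else:
            ps, mf = np.full(N_HAB, 0.8), np.full(N_HAB, 6.0)
        ps = np.clip(ps, 0.05, 0.95)
        self.a = {
            "succ": np.log(ps / (1 - ps)),
            "fled": np.clip(mf, 1.0, 14.0),
            "s1": np.full(N_HAB, math.log(0.15 / 0.85)),
            "s2": np.full(N_HAB, math.log(0.35 / 0.65)),
            "omega": np.full(N_HAB, math.log(0.10 / 0.90)),
        }

    def _init_latents(self):
        """Feasible latent starting state tracking the observed counts.

        Stage splits follow rough demographic shares; the adult numbers are
        capped by the joint survivor capacity of the previous year's totals
        (the shortfall goes to immigrants, whose Poisson support is always
        positive because every habitat-year total is kept at >= 1).
        """
        fd = self.fd
        T = fd.T
        y = fd.counts
        self.init_ub = 5 * np.maximum(1, y[:, 0])
        n1 = np.zeros((N_HAB, T), dtype=int)
        n2 = np.zeros((N_HAB, T), dtype=int)
        ni = np.zeros((N_HAB, T), dtype=int)
        b2 = np.zeros((N_HAB, N_HAB, T - 1), dtype=int)
        for t in range(T):
            target = np.maximum(1, y[:, t])
            n1[:, t] = np.round(0.25 * target).astype(int)
            ni[:, t] = np.maximum(1, np.round(0.15 * target).astype(int))
            n2[:, t] = np.maximum(0, target - n1[:, t] - ni[:, t])
            if t > 0:
                cap = (n1 + n2 + ni)[:, t - 1].copy()
                total = int(n2[:, t].sum())
                if total > cap.sum():
                    scaled = np.floor(n2[:, t] * cap.sum() / total).astype(int)
                    ni[:, t] += n2[:, t] - scaled  # keep totals near counts
                    n2[:, t] = scaled
                for dest in range(N_HAB):
                    rem = n2[dest, t]
                    for src in [dest] + [s for s in range(N_HAB) if s != dest]:
                        take = min(rem, cap[src])
                        b2[src, dest, t - 1] += take
                        cap[src] -= take
                        rem -= take
                        if rem == 0:
                            break
        self.n1, self.n2, self.ni, self.b2 = n1, n2, ni, b2
        self.init_ub = np.maximum(self.init_ub, np.max(
            [n1[:, 0], n2[:, 0], ni[:, 0]], axis=0))

    # -- cache computation ---------------------------------------------------

    def eta_grid(self, r: str) -> np.ndarray:
        fd = self.fd
        d = fd.designs[r]
        Tg = fd.T if r in ("succ", "fled") else fd.T - 1
        eta = np.repeat(self.a[r][:, None], Tg, axis=1)
        if d.K:
            eta = eta + np.tensordot(self.beta[r], d.grids, axes=1)
        if r in self.eps:
            eta = eta + self.eps[r]
        return eta

    def record_eta(self, r: str) -> np.ndarray:
        fd = self.fd
        d = fd.designs[r]
        if r == "succ":
            hab, ti = fd.hab, fd.ti
            X = d.Xrec
        else:
            hab, ti = fd.hab1, fd.ti1
            X = d.Xrec[fd.idx_succ] if d.Xrec is not None else None
        eta = self.a[r][hab]
        if d.K and X is not None and X.shape[0]:
            eta = eta + X @ self.beta[r]
        if r in self.eps:
            eta = eta + self.eps[r][hab, ti]
        return eta

    def refresh_all(self):
        """Recompute every cache and likelihood component from scratch."""
        fd = self.fd
        self.nat = {}
        for r in RATE_NAMES:
            eta = self.eta_grid(r)
            self.nat[r] = expit(eta) if r in _EXPIT_RATES else eta
        self.psi1 = _alr_to_simplex(self.z1)
        self.psi2 = _alr_to_simplex(self.z2)
        self.pvec = expit(self.mu_p + self.eps_p)
        self.succ_eta = self.record_eta("succ")
        self.fled_mu = self.record_eta("fled")
        self.R = 0.5 * self.nat["succ"] * self.nat["fled"]
        if self.has_counts:
            self.ntot = self.n1 + self.n2 + self.ni
            self.rec_mean = np.einsum(
                "st,sd->dt",
                self.R[:, :-1] * self.nat["s1"] * self.ntot[:, :-1],
                self.psi1,
            )
        self.ll = {
            "cmr": self.ll_cmr(self.nat["s1"], self.nat["s2"],
                               self.psi1, self.psi2, self.pvec),
            "succ": self.ll_succ(self.succ_eta),
            "fled": self.ll_fled(self.fled_mu, self.shape, self.nat["fled"]),
        }
        if self.has_counts:
            self.ll.update(self.state_parts())
        else:
            self.ll.update({"rec": 0.0, "b2": 0.0, "ni": 0.0, "count": 0.0})

    def total_ll(self) -> float:
        return float(sum(self.ll.values()))

    # -- likelihood components ----------------------------------------------

    def ll_cmr(self, s1, s2, psi1, psi2, p) -> float:
        if not self.has_cmr:
            return 0.0
        ch = self.fd.ch
        return float(_forward_batch(
            ch.first_occ, ch.first_age, ch.obs, ch.weight,
            np.ascontiguousarray(s1), np.ascontiguousarray(s2),
            np.ascontiguousarray(psi1), np.ascontiguousarray(psi2),
            np.ascontiguousarray(p),
        ))

    def ll_succ(self, eta) -> float:
        if eta.size == 0:
            return 0.0
        return float(np.sum(self.fd.succ_y * eta - np.logaddexp(0.0, eta)))

    def ll_fled(self, mu, shape, mu_grid=None) -> float:
        if mu_grid is not None and self.has_counts and np.any(mu_grid <= 0):
            return -np.inf
        if mu.size == 0:
            return 0.0
        if np.any(mu <= 0):
            return -np.inf
        return float(np.sum(gamma_logpdf_mean_shape(self.fd.fled_y, mu, shape)))

    def state_parts(self) -> dict:
        ntot = self.ntot
        rec = _pois_sum2d(self.n1[:, 1:], self.rec_mean)
        q = np.ascontiguousarray(self.nat["s2"][:, None, :] * self.psi2[:, :, None])
        b2 = _bin_sum_b2(self.b2, ntot, q)
        ni = _pois_sum2d(self.ni[:, 1:], self.nat["omega"] * ntot[:, :-1])
        cnt = _pois_sum2d(self.fd.counts, ntot.astype(float))
        return {"rec": rec, "b2": b2, "ni": ni, "count": cnt}


class IPMSampler:
    """One MCMC chain over a :class:`ChainState`, with adaptive proposals."""

    def __init__(self, fd: FitData, seed_seq: np.random.SeedSequence):
        self.rng = np.random.default_rng(seed_seq)
        self.fd = fd
        self.st = ChainState(fd, self.rng)
        self.adapting = True
        self.it = 0
        # immigration parameters stay at their data-driven initial values for
        # the first stretch of burn-in, so the latent trajectory and the
        # CMR-informed rates settle before the weakly identified immigration
        # level starts moving (otherwise early-burn-in chaos can push a
        # habitat's immigration into a sticky near-zero corner)
        self.freeze_omega = False
        self._build_adapt()

    def _build_adapt(self):
        st, fd = self.st, self.fd
        self.ad = {}
        for r in RATE_NAMES:
            for h in range(N_HAB):
                self.ad[f"a:{r}:{h}"] = _Adapt(0.1)
            for k in range(fd.designs[r].K):
                self.ad[f"b:{r}:{k}"] = _Adapt(0.1)
            if r in st.eps:
                for h in range(N_HAB):
                    self.ad[f"sig:{r}:{h}"] = _Adapt(0.1)
                    self.ad[f"rc:{r}:{h}"] = _Adapt(0.1)
                    self.ad[f"ss:{r}:{h}"] = _Adapt(0.3)
                if r in ("s1", "s2"):
                    for h in range(N_HAB):
                        self.ad[f"eb:{r}:{h}"] = _Adapt(0.05, target=0.25)
                else:
                    Tg = st.eps[r].shape[1]
                    for h in range(N_HAB):
                        for t in range(Tg):
                            self.ad[f"es:{r}:{h}:{t}"] = _Adapt(0.2)
        for age in (1, 2):
            for row in range(N_HAB):
                self.ad[f"z{age}:{row}"] = _Adapt(0.2, target=0.3)
        self.ad["mu_p"] = _Adapt(0.1)
        self.ad["sig_p"] = _Adapt(0.1)
        self.ad["eps_p"] = _Adapt(0.05, target=0.25)
        self.ad["rc:p"] = _Adapt(0.1)
        self.ad["ss:p"] = _Adapt(0.3)
        self.ad["shape"] = _Adapt(0.3)
        for h in range(N_HAB):
            self.ad[f"oex:{h}"] = _Adapt(0.3)
        if st.has_counts:
            T = fd.T
            # latent-site proposal scales and adaptation counters (arrays,
            # updated in place by the numba sweep kernel)
            self.sc_n1 = np.full((N_HAB, T), 2.0)
            self.sc_ni = np.full((N_HAB, T), 2.0)
            self.sc_n2 = np.full(N_HAB, 2.0)
            self.sc_b2 = np.full((N_HAB, N_HAB, T - 1), 2.0)
            self.ct_n1 = np.zeros((N_HAB, T))
            self.ct_ni = np.zeros((N_HAB, T))
            self.ct_n2 = np.zeros(N_HAB)
            self.ct_b2 = np.zeros((N_HAB, N_HAB, T - 1))
            self.n_lat_sites = 2 * N_HAB * T + N_HAB + N_HAB * N_HAB * (T - 1)

    # -- Metropolis helpers ---------------------------------------------------

    def _accept(self, delta: float) -> bool:
        return delta >= 0 or self.rng.random() < math.exp(max(delta, -700.0))

    def _mh(self, key: str | None, delta: float) -> bool:
        ok = np.isfinite(delta) and self._accept(delta)
        if self.adapting and key is not None:
            self.ad[key].update(ok)
        return ok

    # -- coefficient updates ---------------------------------------------------

    def _dependent(self, r: str, nat: np.ndarray):
        """Every likelihood component downstream of rate r's grid, evaluated
        for the candidate natural-scale grid ``nat`` (which must reflect the
        already-written candidate parameters where record-level predictors
        are involved)."""
        st = self.st
        new_ll, caches = {}, {}
        if r in ("s1", "s2"):
            s1 = nat if r == "s1" else st.nat["s1"]
            s2 = nat if r == "s2" else st.nat["s2"]
            new_ll["cmr"] = st.ll_cmr(s1, s2, st.psi1, st.psi2, st.pvec)
        if r in ("succ", "fled"):
            rec_eta = st.record_eta(r)
            if r == "succ":
                new_ll["succ"] = st.ll_succ(rec_eta)
            else:
                new_ll["fled"] = st.ll_fled(rec_eta, st.shape, nat)
            caches["rec_eta"] = rec_eta
        if st.has_counts:
            if r in ("succ", "fled", "s1"):
                R = st.R
                s1g = st.nat["s1"]
                if r == "succ":
                    R = 0.5 * nat * st.nat["fled"]
                elif r == "fled":
                    R = 0.5 * st.nat["succ"] * nat
                else:
                    s1g = nat
                rm = np.einsum("st,sd->dt",
                               R[:, :-1] * s1g * st.ntot[:, :-1], st.psi1)
                new_ll["rec"] = _pois_sum2d(st.n1[:, 1:], rm)
                caches["R"], caches["rec_mean"] = R, rm
            elif r == "s2":
                q = np.ascontiguousarray(nat[:, None, :] * st.psi2[:, :, None])
                new_ll["b2"] = _bin_sum_b2(st.b2, st.ntot, q)
            elif r == "omega":
                new_ll["ni"] = _pois_sum2d(st.ni[:, 1:], nat * st.ntot[:, :-1])
        return new_ll, caches

    def _commit(self, r: str, nat, new_ll, caches):
        st = self.st
        st.nat[r] = nat
        st.ll.update(new_ll)
        if "rec_eta" in caches:
            if r == "succ":
                st.succ_eta = caches["rec_eta"]
            else:
                st.fled_mu = caches["rec_eta"]
        if "R" in caches:
            st.R, st.rec_mean = caches["R"], caches["rec_mean"]

    def upd_coef(self, r: str, kind: str, idx: int):
        st = self.st
        key = f"{kind}:{r}:{idx}"
        store = st.a[r] if kind == "a" else st.beta[r]
        old = store[idx]
        new = old + self.rng.normal(0.0, self.ad[key].scale)
        if kind == "a" and r == "fled":
            if not (_FLED_LO <= new <= _FLED_HI):
                self._mh(key, -np.inf)
                return
            dprior = 0.0
        else:
            dprior = -0.5 * (new**2 - old**2) / _SLOPE_SD**2
        store[idx] = new
        eta = st.eta_grid(r)
        nat = expit(eta) if r in _EXPIT_RATES else eta
        new_ll, caches = self._dependent(r, nat)
        delta = dprior + sum(new_ll.values()) - sum(st.ll[k] for k in new_ll)
        if self._mh(key, delta):
            self._commit(r, nat, new_ll, caches)
        else:
            store[idx] = old

    def upd_eps_block(self, r: str, h: int):
        """Joint random-walk update of one habitat's annual survival deviations."""
        st = self.st
        key = f"eb:{r}:{h}"
        old = st.eps[r][h].copy()
        new = old + self.rng.normal(0.0, self.ad[key].scale, old.size)
        dprior = -0.5 * float(np.sum(new**2 - old**2)) / st.sig[r][h] ** 2
        st.eps[r][h] = new
        nat = expit(st.eta_grid(r))
        new_ll, caches = self._dependent(r, nat)
        delta = dprior + sum(new_ll.values()) - sum(st.ll[k] for k in new_ll)
        if self._mh(key, delta):
            self._commit(r, nat, new_ll, caches)
        else:
            st.eps[r][h] = old

    def upd_sig_scale(self, r: str, h: int):
        """Group scale move: multiply one habitat's random-effect sd and its
        deviations by a common factor.

        The non-centred companion of the plain sigma update: with eps held
        fixed, sigma can only creep, because large moves conflict with the
        conditional N(0, sigma) density of the current deviations.  Scaling
        both together leaves the standardised deviations unchanged; the
        Jacobian of the expansion cancels the prior terms except for one
        factor, so the acceptance ratio is the likelihood ratio plus z.
        """
        st = self.st
        key = f"ss:{r}:{h}"
        z = self.rng.normal(0.0, self.ad[key].scale)
        c = math.exp(z)
        new_sig = st.sig[r][h] * c
        if not (0.0 < new_sig < _SIG_MAX):
            self._mh(key, -np.inf)
            return
        old_eps = st.eps[r][h].copy()
        st.eps[r][h] = old_eps * c
        eta = st.eta_grid(r)
        nat = expit(eta) if r in _EXPIT_RATES else eta
        new_ll, caches = self._dependent(r, nat)
        delta = z + sum(new_ll.values()) - sum(st.ll[k] for k in new_ll)
        if self._mh(key, delta):
            st.sig[r][h] = new_sig
            self._commit(r, nat, new_ll, caches)
        else:
            st.eps[r][h] = old_eps

    def upd_eps_vec(self, r: str, h: int):
        """Simultaneous per-year Metropolis updates of one habitat's annual
        deviations of succ / fled / omega.

        Sites at different years touch disjoint likelihood terms (their cell
        records and the recruitment term of their own interval), so the
        accept/reject decisions factorise exactly across years.
        """
        st, fd = self.st, self.fd
        T = fd.T
        Tg = st.eps[r].shape[1]
        scales = np.array([self.ad[f"es:{r}:{h}:{t}"].scale for t in range(Tg)])
        d = self.rng.standard_normal(Tg) * scales
        logu = np.log(self.rng.random(Tg))
        eps_old = st.eps[r][h]
        sig = st.sig[r][h]
        delta = -0.5 * ((eps_old + d) ** 2 - eps_old**2) / sig**2
        eta_new = st.eta_row(r, h) + d

        if r == "omega":
            om_new = expit(eta_new)
            dll = np.zeros(Tg)
            if st.has_counts:
                nsrc = st.ntot[h, :-1]
                dll = poisson_logpmf(st.ni[h, 1:], om_new * nsrc) \
                    - poisson_logpmf(st.ni[h, 1:], st.nat["omega"][h] * nsrc)
                delta = delta + dll
            acc = delta > logu
            st.eps[r][h, acc] += d[acc]
            st.nat["omega"][h, acc] = om_new[acc]
            if st.has_counts:
                st.ll["ni"] += float(dll[acc].sum())
        else:
            if r == "succ":
                idx = fd.hab_rec[h]
                ti_h = fd.ti[idx]
                yv = fd.succ_y[idx]
                e_old = st.succ_eta[idx]
                e_new = e_old + d[ti_h]
                rec_dll = (yv * e_new - np.logaddexp(0.0, e_new)) \
                    - (yv * e_old - np.logaddexp(0.0, e_old))
                cell_dll = np.bincount(ti_h, weights=rec_dll, minlength=Tg)
                nat_new = expit(eta_new)
                R_new = 0.5 * nat_new * st.nat["fled"][h]
            else:
                idx = fd.hab_rec1[h]
                ti_h = fd.ti1[idx]
                yf = fd.fled_y[idx]
                m_old = st.fled_mu[idx]
                m_new = m_old + d[ti_h]
                bad = m_new <= 0
                rec_dll = gamma_logpdf_mean_shape(
                    yf, np.where(bad, 1.0, m_new), st.shape) \
                    - gamma_logpdf_mean_shape(yf, m_old, st.shape)
                cell_dll = np.bincount(ti_h, weights=rec_dll, minlength=Tg)
                if np.any(bad):
                    cell_dll[np.unique(ti_h[bad])] = -np.inf
                nat_new = eta_new
                if st.has_counts:
                    cell_dll[nat_new <= 0] = -np.inf
                R_new = 0.5 * st.nat["succ"][h] * nat_new
            delta = delta + cell_dll
            rec_dll_t = np.zeros(T - 1)
            if st.has_counts:
                dR = (R_new - st.R[h])[: T - 1]
                coef = st.nat["s1"][h] * st.ntot[h, :-1]  # (T-1,)
                m1 = st.rec_mean + (dR * coef)[None, :] * st.psi1[h][:, None]
                rec_dll_t = _pois_colsum_diff(st.n1[:, 1:], st.rec_mean, m1)
                delta[: T - 1] += rec_dll_t
            acc = delta > logu
            tacc = np.flatnonzero(acc)
            if tacc.size:
                st.eps[r][h, tacc] += d[tacc]
                st.nat[r][h, tacc] = nat_new[tacc]
                racc = acc[ti_h]
                if r == "succ":
                    st.succ_eta[idx[racc]] += d[ti_h[racc]]
                    st.ll["succ"] += float(cell_dll[tacc].sum())
                else:
                    st.fled_mu[idx[racc]] += d[ti_h[racc]]
                    st.ll["fled"] += float(cell_dll[tacc].sum())
                if st.has_counts:
                    t2 = tacc[tacc <= T - 2]
                    st.rec_mean[:, t2] += (dR[t2] * coef[t2])[None, :] \
                        * st.psi1[h][:, None]
                    st.ll["rec"] += float(rec_dll_t[t2].sum())
                st.R[h, tacc] = R_new[tacc]
        if self.adapting:
            for t in range(Tg):
                self.ad[f"es:{r}:{h}:{t}"].update(bool(acc[t]))

    def upd_recenter(self, r: str, h: int):
        """Translation move along the intercept/year-effect ridge.

        ``a_h -> a_h + delta`` with ``eps_h -> eps_h - delta`` leaves every
        linear predictor unchanged, so the acceptance ratio involves only the
        priors.  Without this move the intercept and the annual deviations
        are free to drift jointly (only their sum is likelihood-identified),
        which inflates the random-effect standard deviations and makes the
        intercept meaningless.
        """
        st = self.st
        key = f"rc:{r}:{h}"
        delta = self.rng.normal(0.0, self.ad[key].scale)
        a_old = st.a[r][h]
        a_new = a_old + delta
        if r == "fled":
            if not (_FLED_LO <= a_new <= _FLED_HI):
                self._mh(key, -np.inf)
                return
            dprior = 0.0
        else:
            dprior = -0.5 * (a_new**2 - a_old**2) / _SLOPE_SD**2
        e = st.eps[r][h]
        dprior += -0.5 * float(np.sum((e - delta) ** 2 - e**2)) / st.sig[r][h] ** 2
        if self._mh(key, dprior):
            st.a[r][h] = a_new
            st.eps[r][h] -= delta

    def upd_recenter_p(self):
        """Same translation move for the recapture intercept and its year
        effects."""
        st = self.st
        key = "rc:p"
        delta = self.rng.normal(0.0, self.ad[key].scale)
        new = st.mu_p + delta
        dprior = -0.5 * (new**2 - st.mu_p**2) / _SLOPE_SD**2
        dprior += -0.5 * float(np.sum((st.eps_p - delta) ** 2 - st.eps_p**2)) \
            / st.sig_p**2
        if self._mh(key, dprior):
            st.mu_p = new
            st.eps_p -= delta

    def upd_omega_exchange(self, h: int, target: str = "rec",
                           scale: float | None = None):
        """Joint move of the immigration level and the latent immigrant
        counts of one habitat.

        Proposes a shift of the immigration intercept together with a
        matched reallocation between immigrants and either recruits
        (``target="rec"``) or same-habitat adult survivors
        (``target="adult"``) that keeps every annual total fixed, so only
        the allocation pmfs (and the intercept prior) enter the acceptance
        ratio.  Without this move the sampler can freeze in the corner where
        both the immigrant counts and the immigration rate are near zero,
        because single-site updates of either quantity alone are always
        rejected.  ``scale=None`` uses the adapted scale; an explicit scale
        gives a bold non-adapted jump that can cross between the zero-
        immigration and positive-immigration modes.
        """
        st = self.st
        if not st.has_counts:
            return
        key = f"oex:{h}"
        adapt_key = key if scale is None else None
        delta_a = self.rng.normal(0.0, scale if scale else self.ad[key].scale)
        a_old = st.a["omega"][h]
        a_new = a_old + delta_a
        om_old = st.nat["omega"][h]
        om_new = expit(st.eta_row("omega", h) + delta_a)
        nsrc = st.ntot[h, :-1]
        d = np.round((om_new - om_old) * nsrc).astype(int)
        ni_new = st.ni[h, 1:] + d
        dprior = -0.5 * (a_new**2 - a_old**2) / _SLOPE_SD**2
        if target == "rec":
            n1_new = st.n1[h, 1:] - d
            if np.any(ni_new < 0) or np.any(n1_new < 0):
                self._mh(adapt_key, -np.inf)
                return
            rm = np.ascontiguousarray(st.rec_mean[h])
            dother = _pois_sum(n1_new, rm) - _pois_sum(st.n1[h, 1:].copy(), rm)
        else:
            b2_new = np.ascontiguousarray(st.b2[h, h, :] - d)
            q = st.nat["s2"][h] * st.psi2[h, h]
            if np.any(ni_new < 0) or np.any(b2_new < 0) \
                    or np.any(b2_new > nsrc):
                self._mh(adapt_key, -np.inf)
                return
            dother = _bin_sum(b2_new, nsrc, q) \
                - _bin_sum(np.ascontiguousarray(st.b2[h, h, :]), nsrc, q)
        dni = _pois_sum(ni_new, om_new * nsrc) \
            - _pois_sum(st.ni[h, 1:].copy(), om_old * nsrc)
        if self._mh(adapt_key, dprior + dni + dother):
            st.a["omega"][h] = a_new
            st.nat["omega"][h] = om_new
            st.ni[h, 1:] = ni_new
            st.ll["ni"] += dni
            if target == "rec":
                st.n1[h, 1:] = n1_new
                st.ll["rec"] += dother
            else:
                st.b2[h, h, :] = b2_new
                st.n2[h, 1:] -= d
                st.ll["b2"] += dother

    def upd_sigma(self, r: str, h: int):
        st = self.st
        key = f"sig:{r}:{h}"
        old = st.sig[r][h]
        new = old + self.rng.normal(0.0, self.ad[key].scale)
        if not (0.0 < new < _SIG_MAX):
            self._mh(key, -np.inf)
            return
        e = st.eps[r][h]
        ss = float(np.sum(e * e))
        delta = -e.size * math.log(new / old) - 0.5 * ss * (new**-2 - old**-2)
        if self._mh(key, delta):
            st.sig[r][h] = new

    def upd_psi_row(self, age: int, row: int):
        st = self.st
        key = f"z{age}:{row}"
        z = st.z1 if age == 1 else st.z2
        old = z[row].copy()
        z[row] = old + self.rng.normal(0.0, self.ad[key].scale, 2)
        psi_new = _alr_to_simplex(z)
        psi_old = st.psi1 if age == 1 else st.psi2
        dprior = float(np.sum(np.log(psi_new[row])) - np.sum(np.log(psi_old[row])))
        new_ll = {}
        new_caches = {}
        if age == 1:
            new_ll["cmr"] = st.ll_cmr(st.nat["s1"], st.nat["s2"], psi_new, st.psi2, st.pvec)
            if st.has_counts:
                rm = np.einsum("st,sd->dt",
                               st.R[:, :-1] * st.nat["s1"] * st.ntot[:, :-1], psi_new)
                new_ll["rec"] = _pois_sum2d(st.n1[:, 1:], rm)
                new_caches["rec_mean"] = rm
        else:
            new_ll["cmr"] = st.ll_cmr(st.nat["s1"], st.nat["s2"], st.psi1, psi_new, st.pvec)
            if st.has_counts:
                q = np.ascontiguousarray(st.nat["s2"][:, None, :] * psi_new[:, :, None])
                new_ll["b2"] = _bin_sum_b2(st.b2, st.ntot, q)
        delta = dprior + sum(new_ll.values()) - sum(st.ll[k] for k in new_ll)
        if self._mh(key, delta):
            if age == 1:
                st.psi1 = psi_new
            else:
                st.psi2 = psi_new
            st.ll.update(new_ll)
            if "rec_mean" in new_caches:
                st.rec_mean = new_caches["rec_mean"]
        else:
            z[row] = old

    def upd_p(self):
        st = self.st
        # intercept
        key = "mu_p"
        old = st.mu_p
        new = old + self.rng.normal(0.0, self.ad[key].scale)
        p_new = expit(new + st.eps_p)
        delta = -0.5 * (new**2 - old**2) / _SLOPE_SD**2
        ll_new = st.ll_cmr(st.nat["s1"], st.nat["s2"], st.psi1, st.psi2, p_new)
        delta += ll_new - st.ll["cmr"]
        if self._mh(key, delta):
            st.mu_p, st.pvec, st.ll["cmr"] = new, p_new, ll_new
        # year effects (block)
        key = "eps_p"
        old_e = st.eps_p.copy()
        st.eps_p = old_e + self.rng.normal(0.0, self.ad[key].scale, old_e.size)
        dprior = -0.5 * float(np.sum(st.eps_p**2 - old_e**2)) / st.sig_p**2
        p_new = expit(st.mu_p + st.eps_p)
        ll_new = st.ll_cmr(st.nat["s1"], st.nat["s2"], st.psi1, st.psi2, p_new)
        if self._mh(key, dprior + ll_new - st.ll["cmr"]):
            st.pvec, st.ll["cmr"] = p_new, ll_new
        else:
            st.eps_p = old_e
        # sd of year effects
        key = "sig_p"
        old = st.sig_p
        new = old + self.rng.normal(0.0, self.ad[key].scale)
        if not (0.0 < new < _SIG_MAX):
            self._mh(key, -np.inf)
        else:
            ss = float(np.sum(st.eps_p**2))
            delta = -st.eps_p.size * math.log(new / old) \
                - 0.5 * ss * (new**-2 - old**-2)
            if self._mh(key, delta):
                st.sig_p = new
        # group scale move on (sig_p, eps_p)
        key = "ss:p"
        z = self.rng.normal(0.0, self.ad[key].scale)
        c = math.exp(z)
        if not (0.0 < st.sig_p * c < _SIG_MAX):
            self._mh(key, -np.inf)
            return
        eps_new = st.eps_p * c
        p_new = expit(st.mu_p + eps_new)
        ll_new = st.ll_cmr(st.nat["s1"], st.nat["s2"], st.psi1, st.psi2, p_new)
        if self._mh(key, z + ll_new - st.ll["cmr"]):
            st.sig_p *= c
            st.eps_p = eps_new
            st.pvec, st.ll["cmr"] = p_new, ll_new

    def upd_shape(self):
        st = self.st
        key = "shape"
        old = st.shape
        new = old + self.rng.normal(0.0, self.ad[key].scale)
        if not (0.0 < new < _SHAPE_MAX):
            self._mh(key, -np.inf)
            return
        ll_new = st.ll_fled(st.fled_mu, new)
        if self._mh(key, ll_new - st.ll["fled"]):
            st.shape, st.ll["fled"] = new, ll_new

    # -- latent abundance sweep ------------------------------------------------

    def sweep_latents(self):
        st, fd = self.st, self.fd
        crs = np.ascontiguousarray(
            (st.R[:, :-1] * st.nat["s1"])[:, None, :] * st.psi1[:, :, None])
        q2 = np.ascontiguousarray(
            st.nat["s2"][:, None, :] * st.psi2[:, :, None])
        n = self.n_lat_sites
        _latent_sweep_nb(
            st.n1, st.n2, st.ni, st.ntot, st.b2, st.rec_mean,
            crs, q2, np.ascontiguousarray(st.nat["omega"]),
            fd.counts, st.init_ub,
            self.sc_n1, self.sc_ni, self.sc_n2, self.sc_b2,
            self.ct_n1, self.ct_ni, self.ct_n2, self.ct_b2,
            self.adapting,
            self.rng.standard_normal(n), self.rng.random(n), self.rng.random(n),
        )
        # refresh aggregate components after the sweep (cheap, avoids drift)
        st.ll.update(st.state_parts())

    # -- one full iteration ----------------------------------------------------

    def iterate(self):
        st, fd = self.st, self.fd
        self.it += 1
        for r in RATE_NAMES:
            if r == "omega" and self.freeze_omega:
                continue
            for h in range(N_HAB):
                self.upd_coef(r, "a", h)
            for k in range(fd.designs[r].K):
                self.upd_coef(r, "b", k)
            if r in st.eps:
                if r in ("s1", "s2"):
                    for h in range(N_HAB):
                        self.upd_eps_block(r, h)
                else:
                    for h in range(N_HAB):
                        self.upd_eps_vec(r, h)
                for h in range(N_HAB):
                    self.upd_recenter(r, h)
                    self.upd_sigma(r, h)
                    # the costly non-centred scale move (a full dependent-
                    # likelihood evaluation) runs on alternate iterations
                    # for the CMR-informed rates, every iteration otherwise
                    if r not in ("s1", "s2") or (self.it + h) % 2 == 0:
                        self.upd_sig_scale(r, h)
        # immigration mixes far more slowly than anything else (rate, latent
        # counts and allocation are mutually confounded), so its cheap moves
        # run several rounds per iteration
        if not self.freeze_omega:
            for _ in range(2):
                for h in range(N_HAB):
                    self.upd_omega_exchange(h, "rec")
                    self.upd_omega_exchange(h, "adult")
                    self.upd_omega_exchange(h, "rec", scale=1.5)
                    self.upd_omega_exchange(h, "adult", scale=1.5)
        for row in range(N_HAB):
            self.upd_psi_row(1, row)
            self.upd_psi_row(2, row)
        self.upd_p()
        self.upd_recenter_p()
        self.upd_shape()
        if st.has_counts:
            self.sweep_latents()

    # -- recording -------------------------------------------------------------

    def snapshot(self) -> dict:
        st = self.st
        out = {
            "s1": st.nat["s1"].copy(), "s2": st.nat["s2"].copy(),
            "succ": st.nat["succ"].copy(), "fled": st.nat["fled"].copy(),
            "omega": st.nat["omega"].copy(),
            "psi1": st.psi1.copy(), "psi2": st.psi2.copy(),
            "p": st.pvec.copy(), "shape": st.shape,
            "a_succ": expit(st.a["succ"]), "a_fled": st.a["fled"].copy(),
            "a_s1": expit(st.a["s1"]), "a_s2": expit(st.a["s2"]),
            "a_omega": expit(st.a["omega"]),
            "mean_p": float(expit(st.mu_p)),
        }
        for r in RATE_NAMES:
            if self.fd.designs[r].K:
                out[f"beta_{r}"] = st.beta[r].copy()
            if r in st.sig:
                out[f"sig_{r}"] = st.sig[r].copy()
            # systematic (intercept + covariate/trend) part of the rate,
            # excluding year random deviations — the component the
            # variance-explained attribution projects with
            eta_sys = st.eta_grid(r)
            if r in st.eps:
                eta_sys = eta_sys - st.eps[r]
            out[f"sys_{r}"] = expit(eta_sys) if r in _EXPIT_RATES else eta_sys
        out["sig_p"] = st.sig_p
        if st.has_counts:
            out["N1"] = st.n1.copy()
            out["N2"] = st.n2.copy()
            out["Ni"] = st.ni.copy()
            out["Ntot"] = st.ntot.copy()
        return out


def _eta_row(self, r, h):
    """Link-scale predictor row (one habitat, all years) of rate r."""
    fd = self.fd
    d = fd.designs[r]
    eta = np.full(d.grids.shape[2] if d.grids is not None else fd.T, self.a[r][h])
    if d.K:
        eta = eta + self.beta[r] @ d.grids[:, h, :]
    if r in self.eps:
        eta = eta + self.eps[r][h]
    return eta


ChainState.eta_row = _eta_row


def run_chain(fd: FitData, seed_seq, n_iter: int, n_burn: int,
              progress: bool = False) -> tuple[dict, "IPMSampler"]:
    """Run one chain; returns (samples dict of stacked arrays, sampler)."""
    smp = IPMSampler(fd, seed_seq)
    draws = []
    for it in range(n_iter):
        smp.adapting = it < n_burn
        smp.freeze_omega = smp.st.has_counts and it < n_burn // 5
        smp.iterate()
        if it >= n_burn:
            draws.append(smp.snapshot())
    if not draws:
        return {}, smp
    keys = draws[0].keys()
    out = {k: np.array([d[k] for d in draws]) for k in keys}
    return out, smp
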