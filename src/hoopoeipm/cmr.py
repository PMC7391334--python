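"""Multistate capture–recapture likelihood.

Latent states are the three habitat-quality classes plus dead; transition
probabilities factor into apparent survival times movement, both
age-specific (first interval after a nestling marking uses first-year rates,
everything else adult rates).  Recapture probability is shared across live
states and habitats and varies by occasion (year random effect on the logit
scale in the fitted model).  The likelihood of a history conditions on the
state at first capture and marginalises the latent states with a forward
algorithm; an exact path-enumeration oracle is provided for testing.

Observation codes: 0 = not seen, 1..3 = seen in habitat H/M/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .params import N_HAB, CaptureHistorySet, validate_stochastic_rows

DEAD = N_HAB  # index of the absorbing dead state


@dataclass
class MSParams:
    """Parameters of the multistate model.

    ``s1``/``s2`` may be (3,) time-constant or (3, n_intervals); ``p`` may be
    scalar or per-occasion of length n_intervals (entry j is the recapture
    probability at occasion j+1).
    """

    s1: np.ndarray
    s2: np.ndarray
    psi1: np.ndarray
    psi2: np.ndarray
    p: np.ndarray

    def expanded(self, n_occasions: int):
        """Return (s1, s2, psi1, psi2, p) with survival (3, T-1), p (T-1,)."""
        n_int = n_occasions - 1

        def exp_s(s):
            s = np.asarray(s, dtype=float)
            if s.ndim == 1:
                s = np.repeat(s[:, None], n_int, axis=1)
            if s.shape != (N_HAB, n_int):
                raise ValueError(f"survival must be (3,) or (3, {n_int})")
            if np.any(s < 0) or np.any(s > 1):
                raise ValueError("survival probabilities must lie in [0, 1]")
            return s

        psi1 = validate_stochastic_rows(self.psi1, "psi1")
        psi2 = validate_stochastic_rows(self.psi2, "psi2")
        p = np.asarray(self.p, dtype=float)
        if p.ndim == 0:
            p = np.full(n_int, float(p))
        if p.shape != (n_int,):
            raise ValueError(f"p must be scalar or length {n_int}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("recapture probabilities must lie in [0, 1]")
        return exp_s(self.s1), exp_s(self.s2), psi1, psi2, p


def transition_matrix(age: str, params: MSParams, t: int,
                      n_occasions: int | None = None) -> np.ndarray:
    """4x4 latent-state transition matrix for interval [t, t+1).

    Entry (h, h') = S_h * psi[h, h'] for live states, (h, dead) = 1 - S_h,
    dead is absorbing.
    """
    if age not in ("first-year", "adult"):
        raise ValueError("age must be 'first-year' or 'adult'")
    n_occ = n_occasions if n_occasions is not None else t + 2
    s1, s2, psi1, psi2, _ = params.expanded(n_occ)
    s = (s1 if age == "first-year" else s2)[:, t]
    psi = psi1 if age == "first-year" else psi2
    m = np.zeros((N_HAB + 1, N_HAB + 1))
    m[:N_HAB, :N_HAB] = s[:, None] * psi
    m[:N_HAB, DEAD] = 1.0 - s
    m[DEAD, DEAD] = 1.0
    return m


def _history_arrays(history):
    if isinstance(history, tuple):
        first_occ, first_age, obs = history
    else:
        first_occ, first_age, obs = history.first_occ, history.first_age, history.obs
    return int(first_occ), int(first_age), np.asarray(obs, dtype=int)


def forward_loglik(history, params: MSParams) -> float:
    """Log-probability of the observations after first capture.

    Conditions on being alive in the first-capture state at the first
    occasion.  Non-detection contributes (1 - p_t) while alive and 1 while
    dead; a sighting contributes p_t in the latent habitat and is impossible
    in any other state.  Returns -inf for histories impossible under the
    parameters.
    """
    first_occ, first_age, obs = _history_arrays(history)
    T = obs.size
    s1, s2, psi1, psi2, p = params.expanded(T)

    alpha = np.zeros(N_HAB + 1)
    alpha[obs[first_occ] - 1] = 1.0
    ll = 0.0
    for t in range(first_occ, T - 1):
        juv = first_age == 0 and t == first_occ
        s = (s1 if juv else s2)[:, t]
        psi = psi1 if juv else psi2
        m = np.zeros((N_HAB + 1, N_HAB + 1))
        m[:N_HAB, :N_HAB] = s[:, None] * psi
        m[:N_HAB, DEAD] = 1.0 - s
        m[DEAD, DEAD] = 1.0
        alpha = alpha @ m
        o = obs[t + 1]
        if o == 0:
            alpha[:N_HAB] *= 1.0 - p[t]
        else:
            keep = alpha[o - 1] * p[t]
            alpha = np.zeros(N_HAB + 1)
            alpha[o - 1] = keep
        tot = alpha.sum()
        if tot <= 0.0:
            return -np.inf
        ll += np.log(tot)
        alpha /= tot
    return float(ll)


MAX_BRUTE_OCCASIONS = 8


@njit(cache=True)
def _enumerate_paths(first_occ, first_age, obs, s1, s2, psi1, psi2, p):  # pragma: no cover - numba
    """Total probability by explicit summation over every latent state path
    (states indexed 0..2 live, 3 dead), encoded in base 4."""
    T = obs.size
    n_steps = T - 1 - first_occ
    start = obs[first_occ] - 1
    total = 0.0
    n_paths = (N_HAB + 1) ** n_steps
    for code in range(n_paths):
        prob = 1.0
        state = start
        c = code
        for k in range(n_steps):
            nxt = c % (N_HAB + 1)
            c //= N_HAB + 1
            t = first_occ + k
            juv = first_age == 0 and t == first_occ
            if state == DEAD:
                prob *= 1.0 if nxt == DEAD else 0.0
            elif nxt == DEAD:
                prob *= 1.0 - (s1[state, t] if juv else s2[state, t])
            else:
                if juv:
                    prob *= s1[state, t] * psi1[state, nxt]
                else:
                    prob *= s2[state, t] * psi2[state, nxt]
            if prob == 0.0:
                break
            o = obs[t + 1]
            if o == 0:
                if nxt != DEAD:
                    prob *= 1.0 - p[t]
            else:
                prob *= p[t] if nxt == o - 1 else 0.0
            if prob == 0.0:
                break
            state = nxt
        total += prob
    return total


def brute_force_loglik(history, params: MSParams) -> float:
    """Exact enumeration over all latent state paths (testing oracle).

    Refuses histories spanning more than ``MAX_BRUTE_OCCASIONS`` occasions.
    """
    first_occ, first_age, obs = _history_arrays(history)
    T = obs.size
    if T - first_occ > MAX_BRUTE_OCCASIONS:
        raise ValueError("history too long for brute-force enumeration")
    s1, s2, psi1, psi2, p = params.expanded(T)
    total = _enumerate_paths(
        first_occ, first_age, obs,
        np.ascontiguousarray(s1), np.ascontiguousarray(s2),
        np.ascontiguousarray(psi1), np.ascontiguousarray(psi2),
        np.ascontiguousarray(p),
    )
    return float(np.log(total)) if total > 0 else -np.inf


@njit(cache=True)
def _forward_batch(first_occ, first_age, obs, weight, s1, s2, psi1, psi2, p):  # pragma: no cover - numba
    n, T = obs.shape
    total = 0.0
    alpha = np.zeros(N_HAB + 1)
    for i in range(n):
        f = first_occ[i]
        for k in range(N_HAB + 1):
            alpha[k] = 0.0
        alpha[obs[i, f] - 1] = 1.0
        ll = 0.0
        dead_flag = False
        for t in range(f, T - 1):
            juv = first_age[i] == 0 and t == f
            new = np.zeros(N_HAB + 1)
            for src in range(N_HAB):
                a = alpha[src]
                if a == 0.0:
                    continue
                s = s1[src, t] if juv else s2[src, t]
                for dst in range(N_HAB):
                    psi = psi1[src, dst] if juv else psi2[src, dst]
                    new[dst] += a * s * psi
                new[DEAD] += a * (1.0 - s)
            new[DEAD] += alpha[DEAD]
            o = obs[i, t + 1]
            if o == 0:
                for k in range(N_HAB):
                    new[k] *= 1.0 - p[t]
            else:
                keep = new[o - 1] * p[t]
                for k in range(N_HAB + 1):
                    new[k] = 0.0
                new[o - 1] = keep
            tot = 0.0
            for k in range(N_HAB + 1):
                tot += new[k]
            if tot <= 0.0:
                dead_flag = True
                break
            ll += np.log(tot)
            for k in range(N_HAB + 1):
                alpha[k] = new[k] / tot
        if dead_flag:
            return -np.inf
        total += weight[i] * ll
    return total


class CompressedHistories:
    """Unique (first_occ, first_age, observations) patterns with counts.

    The dataset likelihood is linear in the multiplicity of each pattern, so
    pooling identical histories makes repeated likelihood evaluations inside
    the sampler much cheaper.
    """

    def __init__(self, histories: CaptureHistorySet):
        self.n_occasions = histories.n_occasions
        if histories.n_individuals == 0:
            self.first_occ = np.zeros(0, dtype=np.int64)
            self.first_age = np.zeros(0, dtype=np.int64)
            self.obs = np.zeros((0, self.n_occasions), dtype=np.int64)
            self.weight = np.zeros(0)
            return
        key = np.column_stack(
            [histories.first_occ, histories.first_age, histories.obs]
        )
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        self.first_occ = uniq[:, 0].astype(np.int64)
        self.first_age = uniq[:, 1].astype(np.int64)
        self.obs = uniq[:, 2:].astype(np.int64)
        self.weight = counts.astype(float)

    def loglik(self, params: MSParams) -> float:
        if self.obs.shape[0] == 0:
            return 0.0
        s1, s2, psi1, psi2, p = params.expanded(self.n_occasions)
        return float(
            _forward_batch(
                self.first_occ, self.first_age, self.obs, self.weight,
                np.ascontiguousarray(s1), np.ascontiguousarray(s2),
                np.ascontiguousarray(psi1), np.ascontiguousarray(psi2), p,
            )
        )


def cmr_dataset_loglik(histories: CaptureHistorySet, params: MSParams) -> float:
    """Sum of per-individual forward log-likelihoods (compressed evaluation)."""
    return CompressedHistories(histories).loglik(params)


def m_array(histories: CaptureHistorySet) -> pd.DataFrame:
    """Diagnostic transition-count table.

    One row per (release occasion, release state, age at release); columns
    count the occasion and habitat state of the next re-encounter, plus the
    number never seen again.
    """
    T = histories.n_occasions
    rows = {}
    for i in range(histories.n_individuals):
        occs = np.flatnonzero(histories.obs[i])
        for k, t in enumerate(occs):
            age = ("juv" if histories.first_age[i] == 0 and t == histories.first_occ[i]
                   else "adult")
            key = (int(t), int(histories.obs[i, t]), age)
            rec = rows.setdefault(key, {"never": 0})
            if k + 1 < len(occs):
                nxt = occs[k + 1]
                col = f"t{int(nxt)}_s{int(histories.obs[i, nxt])}"
                rec[col] = rec.get(col, 0) + 1
            else:
                rec["never"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["occasion", "state", "age"])
    return out.sort_index()
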