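"""Transient life-table response experiment (LTRE) decompositions.

The realized annual growth rate of the whole population satisfies

    lambda_t = sum_h pi_{h,t} (R_{h,t} S1_{h,t} + S2_{h,t} + omega_{h,t})

in expectation, where pi_{h,t} is the share of the population in habitat h
(movement between habitats cancels when habitats are summed).  Two
retrospective decompositions are provided:

* the temporal variance of lambda into per-parameter contributions
  c_i = sum_j cov(x_i, x_j) s_i s_j with analytic sensitivities s evaluated
  at the temporal means (first order), and
* the difference in mean log lambda between two periods into direct
  contributions (mean differences times gradient of log lambda at the
  across-period midpoint) plus indirect second-order contributions from the
  change in within-period covariances.

Both report their approximation residual so the adequacy of the expansion
is observable.  Population structure enters through all three pi_h with the
sum-to-one constraint handled by projecting the pi-sensitivities onto the
simplex tangent space (a "drop one habitat" parameterisation is available
behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import HABITATS, N_HAB

PARAM_KINDS = ("R", "s1", "s2", "omega", "pi")
#: flat order of the 15 LTRE parameters
PARAM_NAMES = [f"{k}:{hab}" for k in PARAM_KINDS for hab in HABITATS]
_NP = len(PARAM_NAMES)


@dataclass
class GrowthSeries:
    """Realized growth rates lambda_t = Ntot[t+1] / Ntot[t]."""

    lam: np.ndarray
    years: np.ndarray | None = None

    @property
    def log_lam(self) -> np.ndarray:
        return np.log(self.lam)


def realized_lambda(ntot, years=None) -> GrowthSeries:
    """Elementwise ratio of successive totals (habitats summed if 2-D)."""
    ntot = np.asarray(ntot, dtype=float)
    if ntot.ndim == 2:
        ntot = ntot.sum(axis=0)
    if ntot.size < 2:
        raise ValueError("need at least two years of totals")
    if np.any(ntot <= 0):
        raise ValueError("totals must be positive to form growth rates")
    lam = ntot[1:] / ntot[:-1]
    return GrowthSeries(lam=lam, years=None if years is None else np.asarray(years)[:-1])


def _stack(series: dict) -> np.ndarray:
    """(15, T') flat parameter array from a dict of (3, T') series."""
    out = [np.asarray(series[k], dtype=float) for k in PARAM_KINDS]
    T = out[0].shape[1]
    if any(a.shape != (N_HAB, T) for a in out):
        raise ValueError("all series must share one (3, T) shape")
    return np.concatenate(out, axis=0)


def lambda_from_rates(theta: dict | np.ndarray, pi=None) -> float | np.ndarray:
    """Growth rate implied by per-habitat rates and population structure.

    Accepts either a dict {R, s1, s2, omega} of length-3 (or (3, T)) arrays
    plus ``pi``, or a flat (15,) / (15, T) array in :data:`PARAM_NAMES`
    order.
    """
    if isinstance(theta, dict):
        x = np.concatenate([np.atleast_1d(np.asarray(theta[k], dtype=float))
                            for k in ("R", "s1", "s2", "omega")]
                           + [np.atleast_1d(np.asarray(pi, dtype=float))])
    else:
        x = np.asarray(theta, dtype=float)
    R, s1, s2, om, pi_ = (x[i * N_HAB:(i + 1) * N_HAB] for i in range(5))
    if not np.allclose(pi_.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("population structure must sum to 1")
    lam = (pi_ * (R * s1 + s2 + om)).sum(axis=0)
    return float(lam) if np.ndim(lam) == 0 else lam


def _gradient(x: np.ndarray, project_pi: bool = True) -> np.ndarray:
    """d lambda / d x at the flat parameter vector x (15,)."""
    R, s1, s2, om, pi = (x[i * N_HAB:(i + 1) * N_HAB] for i in range(5))
    g = np.empty(_NP)
    g[0:3] = pi * s1
    g[3:6] = pi * R
    g[6:9] = pi
    g[9:12] = pi
    g_pi = R * s1 + s2 + om
    if project_pi:
        g_pi = g_pi - g_pi.mean()
    g[12:15] = g_pi
    return g


def _hessian(x: np.ndarray, project_pi: bool = True) -> np.ndarray:
    """d^2 lambda / dx dx' (15 x 15); only R-s1 and pi-rate cross terms are
    non-zero."""
    R, s1, s2, om, pi = (x[i * N_HAB:(i + 1) * N_HAB] for i in range(5))
    H = np.zeros((_NP, _NP))
    for h in range(N_HAB):
        iR, iS1, iS2, iOm, iPi = (h, 3 + h, 6 + h, 9 + h, 12 + h)
        H[iR, iS1] = H[iS1, iR] = pi[h]
        H[iPi, iR] = H[iR, iPi] = s1[h]
        H[iPi, iS1] = H[iS1, iPi] = R[h]
        H[iPi, iS2] = H[iS2, iPi] = 1.0
        H[iPi, iOm] = H[iOm, iPi] = 1.0
    if project_pi:
        # project the pi rows/columns onto the simplex tangent space
        P = np.eye(_NP)
        P[12:15, 12:15] -= 1.0 / N_HAB
        H = P @ H @ P.T
    return H


@dataclass
class LTREOutput:
    """Per-parameter contributions with their target quantity and residual."""

    contributions: dict
    target: float  # var(lambda) or Delta mean log lambda
    residual: float
    kind: str
    extras: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.contributions.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [(k.split(":")[0], k.split(":")[1], v)
                for k, v in self.contributions.items()]
        return pd.DataFrame(rows, columns=["parameter", "habitat", "contribution"])


def contributions_variance(series: dict, project_pi: bool = True) -> LTREOutput:
    """First-order transient LTRE of var(lambda) over the series years.

    ``series`` maps {"R", "s1", "s2", "omega", "pi"} to (3, T') arrays of
    annual realized values (T' >= 3).
    """
    X = _stack(series)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 years of rates")
    s = _gradient(X.mean(axis=1), project_pi)
    C = np.cov(X)
    contr = (C * np.outer(s, s)).sum(axis=1)
    lam_t = lambda_from_rates(X)
    var_lam = float(np.var(lam_t, ddof=1))
    contributions = dict(zip(PARAM_NAMES, contr))
    return LTREOutput(
        contributions=contributions,
        target=var_lam,
        residual=float(sum(contr) - var_lam),
        kind="variance",
        extras={"lambda_t": lam_t},
    )


def contributions_difference(series: dict, period_a, period_b,
                             years=None, project_pi: bool = True) -> LTREOutput:
    """Decomposition of the difference in mean log growth between periods.

    Periods are (first_year, last_year) pairs on the calendar axis (or index
    pairs when ``years`` is None); the growth intervals used are those whose
    source year lies in [first_year, last_year).  Direct contributions are
    mean differences times the gradient of log lambda at the across-period
    midpoint; indirect contributions are second order in the change of the
    within-period covariances.
    """
    X = _stack(series)
    T = X.shape[1]
    axis = np.asarray(years)[:T] if years is not None else np.arange(T)

    def sel(period):
        a, b = period
        idx = np.flatnonzero((axis >= a) & (axis < b))
        if idx.size == 0:
            raise ValueError(f"period {period} selects no growth intervals")
        return idx

    ia, ib = sel(period_a), sel(period_b)
    if np.intersect1d(ia, ib).size and not np.array_equal(ia, ib):
        raise ValueError("periods overlap")
    Xa, Xb = X[:, ia], X[:, ib]
    ma, mb = Xa.mean(axis=1), Xb.mean(axis=1)
    mid = 0.5 * (ma + mb)
    lam_mid = lambda_from_rates(mid)
    g = _gradient(mid, project_pi) / lam_mid
    H_log = _hessian(mid, project_pi) / lam_mid - np.outer(g, g)
    direct = (mb - ma) * g
    dC = np.cov(Xb) - np.cov(Xa)
    indirect = 0.5 * (dC * H_log).sum(axis=1)
    dlog = float(np.mean(np.log(lambda_from_rates(Xb)))
                 - np.mean(np.log(lambda_from_rates(Xa))))
    contributions = dict(zip(PARAM_NAMES, direct))
    return LTREOutput(
        contributions=contributions,
        target=dlog,
        residual=float(direct.sum() + indirect.sum() - dlog),
        kind="difference",
        extras={"indirect": dict(zip(PARAM_NAMES, indirect)),
                "total_with_indirect": float(direct.sum() + indirect.sum())},
    )


def ltre_from_posterior(post, period_a=(2002, 2005), period_b=(2013, 2016),
                        project_pi: bool = True):
    """Run both decompositions for every posterior draw of a variant-I fit.

    Returns a dict with per-draw contribution arrays and a tidy summary
    DataFrame (posterior mean and 95% interval per parameter x habitat).
    """
    draws = post.rate_series_draws()
    n_draws = draws["R"].shape[0]
    years = post.years[:-1]
    var_c = np.empty((n_draws, _NP))
    var_lam = np.empty(n_draws)
    diff_c = np.empty((n_draws, _NP))
    diff_ind = np.empty((n_draws, _NP))
    dlog = np.empty(n_draws)
    for i in range(n_draws):
        series = {k: draws[k][i] for k in PARAM_KINDS}
        v = contributions_variance(series, project_pi)
        var_c[i] = [v.contributions[n] for n in PARAM_NAMES]
        var_lam[i] = v.target
        d = contributions_difference(series, period_a, period_b, years, project_pi)
        diff_c[i] = [d.contributions[n] for n in PARAM_NAMES]
        diff_ind[i] = [d.extras["indirect"][n] for n in PARAM_NAMES]
        dlog[i] = d.target

    def tidy(arr, label):
        lo, hi = np.quantile(arr, [0.025, 0.975], axis=0)
        return pd.DataFrame({
            "quantity": label,
            "parameter": [n.split(":")[0] for n in PARAM_NAMES],
            "habitat": [n.split(":")[1] for n in PARAM_NAMES],
            "mean": arr.mean(axis=0), "lo95": lo, "hi95": hi,
        })

    summary = pd.concat(
        [tidy(var_c, "var_lambda"), tidy(diff_c, "dlog_direct"),
         tidy(diff_ind, "dlog_indirect")],
        ignore_index=True,
    )
    return {
        "summary": summary,
        "var_contributions": var_c,
        "var_lambda": var_lam,
        "diff_direct": diff_c,
        "diff_indirect": diff_ind,
        "dlog_lambda": dlog,
        "param_names": list(PARAM_NAMES),
    }


def plot_contributions(result, path=None):
    """Bar plot of posterior-mean contributions (layout: variance panel and
    period-difference panel, habitats side by side)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = result["summary"]
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    for ax, qty, title in zip(
        axes, ["var_lambda", "dlog_direct"],
        ["contributions to var(lambda)",
         "direct contributions to Delta log lambda"],
    ):
        sub = summary[summary["quantity"] == qty]
        kinds = [k for k in PARAM_KINDS]
        width = 0.25
        for j, hab in enumerate(HABITATS):
            s = sub[sub["habitat"] == hab].set_index("parameter")
            pos = np.arange(len(kinds)) + (j - 1) * width
            ax.bar(pos, s.loc[kinds, "mean"], width=width, label=hab)
            ax.errorbar(pos, s.loc[kinds, "mean"],
                        yerr=[s.loc[kinds, "mean"] - s.loc[kinds, "lo95"],
                              s.loc[kinds, "hi95"] - s.loc[kinds, "mean"]],
                        fmt="none", ecolor="k", lw=0.8)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xticks(np.arange(len(kinds)))
        ax.set_xticklabels(kinds)
        ax.set_title(title)
    axes[0].legend(title="habitat")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
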