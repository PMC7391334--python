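"""Leave-one-covariate-out attribution of population variance and trend.

How much of the temporal variation in population size, and of the decline in
the growth rate, do the retained covariates explain?  The total variance
explained is

    R2_tot = 1 - var(observed - fitted) / var(observed),

where "fitted" population sizes are the deterministic expectation projection
of the model from its estimated initial abundances under the covariate-driven
posterior-mean rates.  (The smoothed latent abundances track the observed
counts nearly regardless of covariates and would make every share vanish;
the projection is what the covariates can or cannot explain.)  Each
covariate's share is obtained by refitting the model without it:

    share_v = (R2_tot - R2_{-v}) / R2_tot,

and its trend share analogously from the least-squares slope of fitted
log lambda_t on calendar year from a reference year onward.  Shares of
non-orthogonal covariates need not sum to one; raw and normalised shares
are both reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def r2_total(observed, fitted) -> float:
    """Proportion of temporal variance of the observed totals captured by
    the fitted totals: 1 - var(residuals) / var(observed)."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted series differ in length")
    v = np.var(observed)
    if v == 0:
        raise ValueError("observed series is constant; R2 undefined")
    return float(1.0 - np.var(observed - fitted) / v)


def _fitted_totals(post) -> np.ndarray:
    return post.project_expected().sum(axis=0)


def _check_same_axis(fit_full, fit_without):
    if not np.array_equal(fit_full.years, fit_without.years):
        raise ValueError("fits were not run on the same year axis")


def covariate_share(fit_full, fit_without, observed) -> float:
    """(R2_tot - R2_{-v}) / R2_tot for one left-out covariate.

    May be negative with noisy refits; reported as-is.
    """
    _check_same_axis(fit_full, fit_without)
    observed = np.asarray(observed, dtype=float)
    if observed.ndim == 2:
        observed = observed.sum(axis=0)
    r2_full = r2_total(observed, _fitted_totals(fit_full))
    r2_wo = r2_total(observed, _fitted_totals(fit_without))
    if r2_full == 0:
        raise ValueError("full model explains no variance")
    return float((r2_full - r2_wo) / r2_full)


def fitted_trend(post, from_year: int) -> float:
    """OLS slope of fitted log lambda_t on calendar year from from_year on."""
    tot = _fitted_totals(post)
    years = np.asarray(post.years)
    lam = tot[1:] / tot[:-1]
    src = years[:-1]
    keep = src >= from_year
    if keep.sum() < 3:
        raise ValueError("need at least 3 growth intervals after from_year")
    return float(np.polyfit(src[keep].astype(float), np.log(lam[keep]), 1)[0])


def trend_share(fit_full, fit_without, from_year: int = 2005) -> float:
    """(trend_tot - trend_{-v}) / trend_tot on the fitted growth series."""
    _check_same_axis(fit_full, fit_without)
    t_full = fitted_trend(fit_full, from_year)
    t_wo = fitted_trend(fit_without, from_year)
    if t_full == 0:
        raise ValueError("full model has zero fitted trend")
    return float((t_full - t_wo) / t_full)


def drop_covariate(spec, name: str):
    """A copy of the model spec with covariate ``name`` removed from every
    rate's formula."""
    new = spec.copy()
    found = False
    for formula in new.formulas.values():
        term = formula.term(name)
        if term is not None:
            formula.terms.remove(term)
            found = True
    if not found:
        raise ValueError(f"covariate '{name}' not present in the model spec")
    return new


@dataclass
class AttributionResult:
    r2_tot: float
    shares: dict
    trend_tot: float
    trend_shares: dict
    from_year: int
    meta: dict = field(default_factory=dict)

    @property
    def shares_normalised(self) -> dict:
        pos = {k: max(v, 0.0) for k, v in self.shares.items()}
        tot = sum(pos.values())
        return {k: (v / tot if tot > 0 else np.nan) for k, v in pos.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [(v, self.shares[v], self.shares_normalised[v],
                 self.trend_shares[v]) for v in self.shares]
        return pd.DataFrame(
            rows, columns=["covariate", "var_share", "var_share_norm",
                           "trend_share"])


def plot_attribution(result: "AttributionResult", path=None):
    """Bar chart of per-covariate shares of explained population-size
    variance and of the growth-rate trend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    covs = list(result.shares)
    x = np.arange(len(covs))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(x - 0.2, [result.shares[v] for v in covs], width=0.4,
           label="share of explained variance")
    ax.bar(x + 0.2, [result.trend_shares[v] for v in covs], width=0.4,
           label=f"share of trend from {result.from_year}")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xticks(x)
    ax.set_xticklabels(covs)
    ax.set_ylabel("share")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def attribute(bundle, spec, covariates=("temp", "prec", "del"),
              fit_fn=None, from_year: int = 2005, **fit_kwargs) -> AttributionResult:
    """Fit the full covariate model and one reduced model per covariate, and
    derive variance and trend shares."""
    if fit_fn is None:
        from .ipm import fit as fit_fn  # late import to avoid a cycle
    observed = bundle.counts.counts.sum(axis=0)
    full = fit_fn(spec, bundle, **fit_kwargs)
    r2_full = r2_total(observed, _fitted_totals(full))
    t_full = fitted_trend(full, from_year)
    shares, tshares = {}, {}
    for v in covariates:
        reduced = fit_fn(drop_covariate(spec, v), bundle, **fit_kwargs)
        shares[v] = covariate_share(full, reduced, observed)
        tshares[v] = trend_share(full, reduced, from_year)
    return AttributionResult(
        r2_tot=r2_full, shares=shares, trend_tot=t_full, trend_shares=tshares,
        from_year=from_year,
        meta={"covariates": list(covariates), "fit_kwargs": dict(fit_kwargs)},
    )
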