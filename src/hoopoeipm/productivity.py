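"""Productivity submodels.

Annual productivity per female decomposes into the probability of raising at
least one fledgling in the season (Bernoulli, logit link) and the total
number of fledglings a successful female raises over all her broods (gamma,
identity link, mean/shape parameterisation with a single shared shape).
Female recruits per female are half the product of the two components,
assuming a balanced birth sex ratio.

The research-activity covariate "capture delay" (days between the mother's
capture and hatching of her last egg) enters through a threshold term: the
slope is fixed to zero for non-negative delays and estimated for negative
ones, so only captures before hatching of the last egg can depress the rate.
The delay is used on the raw day scale — standardising it would move the
threshold away from zero days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._dist import bernoulli_logpmf, expit, gamma_logpdf_mean_shape
from .modelspec import ModelSpec, RateFormula, Term
from .params import HABITATS, N_HAB

_HAB_INDEX = {h: i for i, h in enumerate(HABITATS)}


def threshold_delay_term(del_days, slope):
    """Linear-predictor contribution of the capture delay.

    Returns ``slope * del`` where the delay is negative (mother captured
    before hatching of the last egg) and exactly 0 otherwise.
    """
    d = np.asarray(del_days, dtype=float)
    out = np.where(d < 0, slope * d, 0.0)
    return out if out.ndim else float(out)


def annual_R(psucc, mu):
    """Female recruits per female and year: R = 0.5 * psucc * mu."""
    return 0.5 * np.asarray(psucc, dtype=float) * np.asarray(mu, dtype=float)


@dataclass
class ProductivityParams:
    """Coefficients of both productivity submodels.

    ``coefs`` maps coefficient names ("temp", "temp2", "hat", "del", ...) to
    a scalar (shared across habitats) or a length-3 array (habitat
    interaction).  ``*_year_eff`` are (3, T) annual deviations aligned with
    ``years``; ``*_trend`` are per-habitat slopes on the standardised year.
    """

    succ_intercept: np.ndarray  # (3,) logit scale
    fled_intercept: np.ndarray  # (3,) identity scale
    shape: float
    years: np.ndarray
    succ_year_eff: Optional[np.ndarray] = None
    fled_year_eff: Optional[np.ndarray] = None
    succ_trend: Optional[np.ndarray] = None
    fled_trend: Optional[np.ndarray] = None
    coefs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")
        for name, v in self.coefs.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite coefficient {name}")


def _year_std(years: np.ndarray) -> np.ndarray:
    y = np.asarray(years, dtype=float)
    return (y - y.mean()) / y.std(ddof=0)


def _habitat_index(table: pd.DataFrame) -> np.ndarray:
    try:
        return table["habitat"].map(_HAB_INDEX).to_numpy(dtype=int)
    except (KeyError, TypeError, ValueError) as e:
        raise ValueError("table needs a 'habitat' column with codes H/M/L") from e


def _year_index(table: pd.DataFrame, years: np.ndarray) -> np.ndarray:
    lookup = {int(y): i for i, y in enumerate(years)}
    try:
        return table["year"].map(lookup).to_numpy(dtype=int)
    except (KeyError, ValueError) as e:
        raise ValueError("table has years outside the model's year axis") from e


def _coef(coefs: dict, name: str, hab: np.ndarray) -> np.ndarray:
    c = np.asarray(coefs.get(name, 0.0), dtype=float)
    return c[hab] if c.ndim else np.full(hab.shape, float(c))


def _term_contribution(term: Term, table: pd.DataFrame, coefs: dict,
                       hab: np.ndarray) -> np.ndarray:
    x = table[term.name].to_numpy(dtype=float)
    if term.threshold:
        x = np.asarray(threshold_delay_term(x, 1.0))
    eta = _coef(coefs, term.name, hab) * x
    if term.quadratic:
        eta = eta + _coef(coefs, term.name + "2", hab) * x**2
    return eta


def _linear_predictor(table: pd.DataFrame, intercept, year_eff, trend,
                      formula: RateFormula, coefs: dict, years) -> np.ndarray:
    hab = _habitat_index(table)
    ti = _year_index(table, years)
    eta = np.asarray(intercept, dtype=float)[hab]
    if formula.year_re:
        if year_eff is None:
            raise ValueError("formula has year random effects but none supplied")
        eta = eta + year_eff[hab, ti]
    if formula.year_trend != "none":
        if trend is None:
            raise ValueError("formula has a year trend but no slope supplied")
        eta = eta + np.asarray(trend, dtype=float)[hab] * _year_std(years)[ti]
    for term in formula.terms:
        eta = eta + _term_contribution(term, table, coefs, hab)
    return eta


def attach_year_covariates(table: pd.DataFrame, cov: pd.DataFrame) -> pd.DataFrame:
    """Merge the annual weather covariates onto a brood table by year."""
    keep = [c for c in ("year", "temp", "prec") if c in cov.columns]
    return table.merge(cov[keep], on="year", how="left", validate="many_to_one")


def success_probability(table: pd.DataFrame, params: ProductivityParams,
                        spec: ModelSpec) -> np.ndarray:
    eta = _linear_predictor(
        table, params.succ_intercept, params.succ_year_eff, params.succ_trend,
        spec.formula("succ"), params.coefs, params.years,
    )
    return expit(eta)


def success_loglik(table: pd.DataFrame, params: ProductivityParams,
                   spec: ModelSpec) -> float:
    """Bernoulli log-likelihood of the success indicators."""
    p = success_probability(table, params, spec)
    y = table["success"].to_numpy(dtype=float)
    return float(np.sum(bernoulli_logpmf(y, p)))


def fledglings_mean(record, params: ProductivityParams, spec: ModelSpec) -> np.ndarray:
    """Identity-link expected fledgling number per record.

    Accepts a DataFrame (vectorised) or a single Series/dict-like record.
    The mean must be positive to be a valid gamma mean; callers evaluating
    the likelihood treat non-positive means as a validation error.
    """
    single = not isinstance(record, pd.DataFrame)
    table = pd.DataFrame([record]) if single else record
    mean = _linear_predictor(
        table, params.fled_intercept, params.fled_year_eff, params.fled_trend,
        spec.formula("fled"), params.coefs, params.years,
    )
    return float(mean[0]) if single else mean


def fledglings_loglik(table: pd.DataFrame, params: ProductivityParams,
                      spec: ModelSpec) -> float:
    """Gamma log-likelihood of fledgling counts of successful females.

    Only success == 1 records enter; a non-positive fitted mean yields -inf
    rather than an exception (the sampler must be able to reject such
    proposals), but a non-positive observation is a data error.
    """
    sub = table[table["success"] == 1]
    y = sub["fledglings"].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("successful records must carry positive fledgling counts")
    mean = fledglings_mean(sub, params, spec)
    return float(np.sum(gamma_logpdf_mean_shape(y, mean, params.shape)))
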