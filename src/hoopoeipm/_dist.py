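"""Vectorised log-densities used throughout the likelihood code.

scipy.stats has all of these, but its dispatch overhead dominates inside the
MCMC inner loops, so the pmfs the sampler hammers are written directly on top
of ``scipy.special.gammaln``.  They accept numpy arrays or scalars and return
``-inf`` outside the support instead of raising.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln  # noqa: F401  (expit re-exported)

_NEG_INF = -np.inf


def poisson_logpmf(k, mu):
    """log Poisson(k; mu); mu == 0 allowed (point mass at 0)."""
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = k * np.log(mu) - mu - gammaln(k + 1.0)
    out = np.where((mu == 0) & (k == 0), 0.0, out)
    out = np.where((mu == 0) & (k > 0), _NEG_INF, out)
    bad = (k < 0) | (k != np.floor(k)) | (mu < 0) | ~np.isfinite(mu)
    return np.where(bad, _NEG_INF, out)


def binomial_logpmf(k, n, p):
    """log Binomial(k; n, p) with the usual 0*log(0) = 0 conventions."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(n + 1.0)
            - gammaln(k + 1.0)
            - gammaln(n - k + 1.0)
            + k * np.log(p)
            + (n - k) * np.log1p(-p)
        )
    out = np.where((p == 0) & (k == 0), 0.0, out)
    out = np.where((p == 1) & (k == n), 0.0, out)
    bad = (
        (k < 0)
        | (k > n)
        | (k != np.floor(k))
        | (n < 0)
        | (n != np.floor(n))
        | (p < 0)
        | (p > 1)
    )
    return np.where(bad, _NEG_INF, out)


def bernoulli_logpmf(y, p):
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        out = y * np.log(p) + (1.0 - y) * np.log1p(-p)
    out = np.where((p == 0) & (y == 0), 0.0, out)
    out = np.where((p == 1) & (y == 1), 0.0, out)
    return np.where((p < 0) | (p > 1), _NEG_INF, out)


def gamma_logpdf_mean_shape(y, mean, shape):
    """log Gamma(y; shape, rate=shape/mean) — mean/shape parameterisation."""
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    shape = np.asarray(shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = shape / mean
        out = (
            shape * np.log(rate)
            - gammaln(shape)
            + (shape - 1.0) * np.log(y)
            - rate * y
        )
    bad = (y <= 0) | (mean <= 0) | (shape <= 0)
    return np.where(bad, _NEG_INF, out)


def normal_logpdf(x, mu, sd):
    x = np.asarray(x, dtype=float)
    sd = np.asarray(sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2
    return np.where(sd <= 0, _NEG_INF, out)


def logit(p):
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        return np.log(p) - np.log1p(-p)
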