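"""Parameter and data containers shared by the simulator and the model.

Habitat order is fixed as (H, M, L) — high, medium, low quality — in every
array in the package.  Stage order in abundance arrays is (recruits N1,
experienced adults N2, immigrants Ni).  Years are calendar-labelled but all
arrays are 0-indexed from the first year; survival/movement/immigration for
the interval [t, t+1) between prebreeding censuses are indexed by the source
year t.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._dist import logit

HABITATS: tuple[str, str, str] = ("H", "M", "L")
N_HAB = 3
STAGES: tuple[str, str, str] = ("N1", "N2", "Ni")

#: record-level brood covariates usable in the fledgling linear predictor
RECORD_COVARIATES = ("hat", "cs", "del", "meth", "partag")
#: annual weather covariates (standardised spring means/sums)
YEAR_COVARIATES = ("temp", "prec")


def _as3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 0:
        a = np.repeat(a, N_HAB)
    if a.shape != (N_HAB,):
        raise ValueError(f"expected scalar or length-3 array, got shape {a.shape}")
    return a


def validate_stochastic_rows(m: np.ndarray, name: str = "psi", atol: float = 1e-8):
    m = np.asarray(m, dtype=float)
    if m.shape != (N_HAB, N_HAB):
        raise ValueError(f"{name} must be 3x3, got {m.shape}")
    if np.any(m < -atol) or np.any(m > 1 + atol):
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=atol):
        raise ValueError(f"rows of {name} must sum to 1")
    return m


@dataclass
class TrueParams:
    """Generating parameters of the habitat-stratified population model.

    Probabilities are on the natural scale; ``p_mean`` is the recapture
    intercept on the logit scale with annual logit-normal deviations of
    standard deviation ``p_sd``.  The ``sigma_*`` fields are the standard
    deviations of annual random deviations of each vital rate (logit scale,
    except fledglings which use the identity scale).  ``trend`` and
    ``covariate_effects`` optionally impose linear year trends (per decade of
    standardised year) and covariate effects on the link scale, mirroring the
    structures of the trend and covariate model variants.
    """

    s1: np.ndarray = field(default_factory=lambda: _as3(0.20))
    s2: np.ndarray = field(default_factory=lambda: _as3(0.35))
    psucc: np.ndarray = field(default_factory=lambda: _as3(0.80))
    # (H, M, L); high-quality habitat is the most productive
    mu_fled: np.ndarray = field(default_factory=lambda: _as3((6.7, 6.0, 5.9)))
    shape_fled: float = 6.0
    omega: np.ndarray = field(default_factory=lambda: _as3(0.15))
    # movement: most birds stay in their habitat class (nest boxes are split
    # equally among the classes, so populations stay comparable); first-years
    # disperse more than adults and movement skews toward higher quality
    psi1: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.75, 0.15, 0.10], [0.20, 0.65, 0.15], [0.15, 0.20, 0.65]]
        )
    )
    psi2: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.92, 0.05, 0.03], [0.08, 0.87, 0.05], [0.05, 0.08, 0.87]]
        )
    )
    p_mean: float = float(logit(0.81))
    p_sd: float = 0.30
    sigma_s1: np.ndarray = field(default_factory=lambda: _as3(0.15))
    sigma_s2: np.ndarray = field(default_factory=lambda: _as3(0.12))
    sigma_succ: np.ndarray = field(default_factory=lambda: _as3(0.20))
    sigma_fled: np.ndarray = field(default_factory=lambda: _as3(0.35))
    sigma_omega: np.ndarray = field(default_factory=lambda: _as3(0.15))
    init_N: np.ndarray = field(
        default_factory=lambda: np.array([[6, 10, 4], [6, 10, 4], [6, 10, 4]])
    )
    # marked cohorts: expected new marks per capita of N_tot per year
    # (roughly half the female fledglings are ringed, plus adult first
    # captures; over 16 years this yields a low-thousands marked sample)
    mark_rate_juv: float = 0.45
    mark_rate_adult: float = 0.12
    # fraction of breeding females contributing a brood record each year
    # (the census totals still define the breeding population)
    brood_fraction: float = 1.0
    # deterministic structure on the link scale:
    #   trend[rate] = per-habitat slope on standardised year
    #   covariate_effects[rate][cov] = scalar or per-habitat length-3 coefficient
    # Default trends emulate the observed declines in fledgling production
    # (~25% over the period) and first-year survival (~31%), plus the strong
    # immigration of the early colonisation years (the population grew
    # several-fold after nest boxes were installed — growth only immigration
    # can supply, since local recruitment plus survival cannot exceed
    # lambda ~ 1) that later levelled off at a low rate.  Together they make
    # the default population rise steeply, peak, and decline — the regime in
    # which count data identify immigration.
    trend: dict = field(default_factory=lambda: {
        "fled": -0.5, "s1": -0.15, "s2": -0.08, "omega": -0.8})
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s1 = _as3(self.s1)
        self.s2 = _as3(self.s2)
        self.psucc = _as3(self.psucc)
        self.mu_fled = _as3(self.mu_fled)
        self.omega = _as3(self.omega)
        for name in ("sigma_s1", "sigma_s2", "sigma_succ", "sigma_fled", "sigma_omega"):
            setattr(self, name, _as3(getattr(self, name)))
        self.psi1 = validate_stochastic_rows(self.psi1, "psi1")
        self.psi2 = validate_stochastic_rows(self.psi2, "psi2")
        for name in ("s1", "s2", "psucc", "omega"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.mu_fled <= 0):
            raise ValueError("mu_fled must be positive")
        if self.shape_fled <= 0:
            raise ValueError("shape_fled must be positive")
        self.init_N = np.asarray(self.init_N)
        if self.init_N.shape != (N_HAB, 3):
            raise ValueError("init_N must be (habitat, stage) = 3x3")
        if np.any(self.init_N < 0) or not np.issubdtype(self.init_N.dtype, np.integer):
            if np.any(self.init_N != np.floor(self.init_N)) or np.any(self.init_N < 0):
                raise ValueError("init_N must be non-negative integers")
            self.init_N = self.init_N.astype(int)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParams":
        return cls(**{k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d.items()})


@dataclass
class AnnualRates:
    """Realised per-habitat, per-year demographic rates of one trajectory.

    Shapes: rates tied to the census year have (3, T); rates tied to the
    interval [t, t+1) have (3, T-1); recapture ``p`` has (T-1,), entry j
    being the recapture probability at occasion j+1.
    """

    s1: np.ndarray
    s2: np.ndarray
    psucc: np.ndarray
    mu_fled: np.ndarray
    omega: np.ndarray
    p: np.ndarray

    @property
    def R(self) -> np.ndarray:
        """Female recruits per female: 0.5 * psucc * mu (balanced sex ratio)."""
        return 0.5 * self.psucc * self.mu_fled

    @property
    def n_years(self) -> int:
        return self.psucc.shape[1]


@dataclass
class PopulationTrajectory:
    """Latent habitat-stratified abundances at the prebreeding census."""

    N1: np.ndarray  # (3, T) local recruits
    N2: np.ndarray  # (3, T) experienced adults
    Ni: np.ndarray  # (3, T) immigrants
    years: np.ndarray  # (T,) calendar labels
    rates: Optional[AnnualRates] = None  # realised annual rates, if simulated

    def __post_init__(self):
        for a in (self.N1, self.N2, self.Ni):
            if np.asarray(a).shape != self.N1.shape:
                raise ValueError("stage arrays must share one (3, T) shape")
        if np.any(self.N1 < 0) or np.any(self.N2 < 0) or np.any(self.Ni < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def Ntot(self) -> np.ndarray:
        return self.N1 + self.N2 + self.Ni

    @property
    def n_years(self) -> int:
        return self.N1.shape[1]


@dataclass
class CountTable:
    """Annual per-habitat population index (simultaneous active broods)."""

    counts: np.ndarray  # (3, T) integers
    years: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class CaptureHistorySet:
    """Individual multistate capture histories over T annual occasions.

    ``obs`` uses codes 0 = not seen, 1 = H, 2 = M, 3 = L.  ``first_age`` is 0
    for birds first captured as nestlings/first-years and 1 for adults.
    ``obs[i, first_occ[i]]`` holds the state at first capture.
    """

    first_occ: np.ndarray  # (n,) int
    first_age: np.ndarray  # (n,) int, 0 = first-year, 1 = adult
    obs: np.ndarray  # (n, T) int codes 0..3

    def __post_init__(self):
        self.first_occ = np.asarray(self.first_occ, dtype=int)
        self.first_age = np.asarray(self.first_age, dtype=int)
        self.obs = np.asarray(self.obs, dtype=int)
        n, T = self.obs.shape
        if self.first_occ.shape != (n,) or self.first_age.shape != (n,):
            raise ValueError("inconsistent history array shapes")
        rows = np.arange(n)
        if np.any(self.obs[rows, self.first_occ] == 0):
            raise ValueError("observation at first_occ must record a habitat state")
        before = np.arange(T)[None, :] < self.first_occ[:, None]
        if np.any(self.obs[before] != 0):
            raise ValueError("no observations allowed before first capture")

    @property
    def n_individuals(self) -> int:
        return self.obs.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.obs.shape[1]
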