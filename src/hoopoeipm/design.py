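"""Preprocessing of a data bundle into the arrays the sampler consumes.

Each vital rate's linear predictor is ``intercept[h] (+ annual random effect)
(+ covariate terms)``.  Year trends and covariates are folded into one
coefficient vector per rate with named entries ("year", "temp2:H", "del",
...).  Every coefficient has two faces:

* a record-level design column for the productivity submodels (reproductive
  success and fledglings are modelled per brood record), and
* a (habitat, year) grid giving the coefficient's contribution to the
  population-level rate used by the state-space process.  For record-level
  covariates (hatching date, clutch size, capture delay, tagging flags) the
  grid holds annual habitat-level means of the transformed covariate, which
  is also how those research-activity covariates reach the survival models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmr import CompressedHistories
from .modelspec import ModelSpec, RateFormula, YEAR_TERMS
from .params import HABITATS, N_HAB
from .productivity import threshold_delay_term

_HAB_INDEX = {h: i for i, h in enumerate(HABITATS)}


@dataclass
class RateDesign:
    """Named coefficients of one rate with record columns and year grids."""

    names: list = field(default_factory=list)
    grids: np.ndarray | None = None  # (K, 3, T') population-level regressors
    Xrec: np.ndarray | None = None  # (n_records, K) record-level regressors

    @property
    def K(self) -> int:
        return len(self.names)


def _record_transform(broods: pd.DataFrame, name: str) -> np.ndarray:
    if name == "del":
        return np.asarray(threshold_delay_term(broods["del"].to_numpy(float), 1.0))
    if name == "tag" and "tag" not in broods.columns:
        return np.zeros(len(broods))
    return broods[name].to_numpy(float)


def _cell_means(values: np.ndarray, hab: np.ndarray, ti: np.ndarray,
                n_years: int) -> np.ndarray:
    """(3, T) means of a record-level quantity per habitat-year cell; empty
    cells fall back to the overall mean."""
    out = np.full((N_HAB, n_years), values.mean() if values.size else 0.0)
    sums = np.zeros((N_HAB, n_years))
    cnt = np.zeros((N_HAB, n_years))
    np.add.at(sums, (hab, ti), values)
    np.add.at(cnt, (hab, ti), 1.0)
    nz = cnt > 0
    out[nz] = sums[nz] / cnt[nz]
    return out


def year_std(years: np.ndarray) -> np.ndarray:
    y = np.asarray(years, dtype=float)
    return (y - y.mean()) / y.std(ddof=0)


class FitData:
    """Arrays extracted once from a data bundle for a given model spec."""

    def __init__(self, bundle, spec: ModelSpec):
        self.spec = spec
        self.years = np.asarray(bundle.years)
        self.T = len(self.years)
        self.ys = year_std(self.years)

        self.ch = CompressedHistories(bundle.histories) if bundle.histories is not None else None

        broods = bundle.broods
        if broods is None or len(broods) == 0:
            broods = pd.DataFrame(
                columns=["female_id", "year", "habitat", "success", "fledglings",
                         "cs", "hat", "del", "meth", "partag"]
            )
        self.broods = broods.reset_index(drop=True)
        self.hab = self.broods["habitat"].map(_HAB_INDEX).to_numpy(dtype=int) \
            if len(self.broods) else np.zeros(0, dtype=int)
        lookup = {int(y): i for i, y in enumerate(self.years)}
        self.ti = self.broods["year"].map(lookup).to_numpy(dtype=int) \
            if len(self.broods) else np.zeros(0, dtype=int)
        self.succ_y = self.broods["success"].to_numpy(float) if len(self.broods) else np.zeros(0)
        self.idx_succ = np.flatnonzero(self.succ_y == 1)
        self.fled_y = self.broods["fledglings"].to_numpy(float)[self.idx_succ] \
            if len(self.broods) else np.zeros(0)
        self.hab1 = self.hab[self.idx_succ]
        self.ti1 = self.ti[self.idx_succ]

        # record indices per habitat-year cell for local sampler updates
        self.cell_rec = [[np.flatnonzero((self.hab == h) & (self.ti == t))
                          for t in range(self.T)] for h in range(N_HAB)]
        self.cell_rec1 = [[np.flatnonzero((self.hab1 == h) & (self.ti1 == t))
                           for t in range(self.T)] for h in range(N_HAB)]
        self.hab_rec = [np.flatnonzero(self.hab == h) for h in range(N_HAB)]
        self.hab_rec1 = [np.flatnonzero(self.hab1 == h) for h in range(N_HAB)]

        self.counts = None
        if bundle.counts is not None:
            self.counts = np.asarray(bundle.counts.counts, dtype=int)
        self.cov = bundle.covariates

        self.designs = {r: self._build_design(r, spec.formula(r))
                        for r in ("succ", "fled", "s1", "s2", "omega")}

    # -- design construction -------------------------------------------------

    def _year_series(self, name: str) -> np.ndarray:
        if name == "year":
            return self.ys
        if self.cov is None or name not in self.cov.columns:
            raise ValueError(f"covariate table lacks required column '{name}'")
        return self.cov[name].to_numpy(float)[: self.T]

    def _coef_entries(self, formula: RateFormula):
        """Yield (coef_name, record_values or None, year_series or cell_means,
        habitat or None)."""
        if formula.year_trend == "shared":
            yield "year", None, self.ys, None
        elif formula.year_trend == "by_habitat":
            for h, hab in enumerate(HABITATS):
                yield f"year:{hab}", None, self.ys, h
        for term in formula.terms:
            for cname in term.coef_names():
                power = 2 if cname.endswith("2") else 1
                if term.name in YEAR_TERMS:
                    x = self._year_series(term.name) ** power
                    rec, grid = None, x
                else:
                    rec = _record_transform(self.broods, term.name) ** power
                    grid = None
                if term.by_habitat:
                    for h, hab in enumerate(HABITATS):
                        yield f"{cname}:{hab}", rec, grid, h
                else:
                    yield cname, rec, grid, None

    def _build_design(self, rate: str, formula: RateFormula) -> RateDesign:
        Tg = self.T if rate in ("succ", "fled") else self.T - 1
        record_level = rate in ("succ", "fled")
        n = len(self.broods)
        names, grids, cols = [], [], []
        for cname, rec, yearx, h in self._coef_entries(formula):
            names.append(cname)
            if rec is None and yearx is not None:
                col = yearx[self.ti]
                grid = np.tile(yearx[:Tg], (N_HAB, 1))
            else:
                col = rec
                grid = _cell_means(rec, self.hab, self.ti, self.T)[:, :Tg]
            if h is not None:
                mask = (self.hab == h).astype(float)
                col = col * mask
                g = np.zeros_like(grid)
                g[h] = grid[h]
                grid = g
            grids.append(grid)
            if record_level:
                cols.append(col)
        design = RateDesign(names=names)
        design.grids = np.array(grids) if grids else np.zeros((0, N_HAB, Tg))
        if record_level:
            design.Xrec = (np.column_stack(cols) if cols else np.zeros((n, 0)))
        return design
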