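"""Readers, writers and validation for the four linked data tables.

On disk a bundle is a directory of plain CSV files:

* ``captures.csv`` — wide capture-history format: ``id``, ``age_first``
  (``juv``/``adult``) and one column per year holding the codes
  0 = not seen, 1 = H, 2 = M, 3 = L,
* ``broods.csv``   — one row per female and year,
* ``counts.csv``   — ``year`` plus one count column per habitat,
* ``covariates.csv`` — annual covariates,
* ``meta.yaml``    — provenance (seed, scenario parameters if synthetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .params import HABITATS, CaptureHistorySet, CountTable

BROOD_COLUMNS = ["female_id", "year", "habitat", "success", "fledglings",
                 "cs", "hat", "del", "meth", "partag"]


class BundleValidationError(ValueError):
    """A data table violated the bundle schema; message names the rows."""


@dataclass
class DataBundle:
    """The four data tables of the integrated model on a shared year axis."""

    histories: Optional[CaptureHistorySet]
    broods: Optional[pd.DataFrame]
    counts: Optional[CountTable]
    covariates: Optional[pd.DataFrame]
    years: np.ndarray
    meta: dict = field(default_factory=dict)


def validate_bundle(bundle: DataBundle) -> None:
    """Raise :class:`BundleValidationError` on any schema violation."""
    problems = []
    years = np.asarray(bundle.years)
    b = bundle.broods
    if b is not None and len(b):
        missing = [c for c in BROOD_COLUMNS if c not in b.columns]
        if missing:
            problems.append(f"brood table missing columns {missing}")
        else:
            bad_hab = ~b["habitat"].isin(HABITATS)
            if bad_hab.any():
                rows = list(b.index[bad_hab][:5])
                problems.append(f"unknown habitat codes in brood rows {rows}")
            failed_with_fled = (b["success"] == 0) & b["fledglings"].notna()
            if failed_with_fled.any():
                rows = list(b.index[failed_with_fled][:5])
                problems.append(
                    f"fledglings recorded for failed broods in rows {rows}"
                )
            succ_no_fled = (b["success"] == 1) & (
                b["fledglings"].isna() | (b["fledglings"] <= 0)
            )
            if succ_no_fled.any():
                rows = list(b.index[succ_no_fled][:5])
                problems.append(
                    f"successful broods without positive fledglings in rows {rows}"
                )
            off_axis = ~b["year"].isin(years)
            if off_axis.any():
                rows = list(b.index[off_axis][:5])
                problems.append(f"brood rows outside the year axis: {rows}")
    if bundle.counts is not None:
        if bundle.counts.counts.shape != (len(HABITATS), len(years)):
            problems.append("count table does not match the (habitat, year) axis")
        if not np.array_equal(np.asarray(bundle.counts.years), years):
            problems.append("count table year axis mismatch")
    if bundle.covariates is not None:
        if "year" not in bundle.covariates.columns:
            problems.append("covariate table missing 'year' column")
        elif not np.array_equal(bundle.covariates["year"].to_numpy(), years):
            problems.append("covariate table year axis mismatch")
    if bundle.histories is not None and bundle.histories.n_individuals:
        if bundle.histories.n_occasions != len(years):
            problems.append("capture histories do not span the year axis")
    if problems:
        raise BundleValidationError("; ".join(problems))


def write_bundle(bundle: DataBundle, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    years = [int(y) for y in bundle.years]
    if bundle.histories is not None:
        h = bundle.histories
        df = pd.DataFrame(h.obs, columns=[f"y{y}" for y in years])
        df.insert(0, "age_first", np.where(h.first_age == 0, "juv", "adult"))
        df.insert(0, "id", np.arange(h.n_individuals))
        df.to_csv(outdir / "captures.csv", index=False)
    if bundle.broods is not None:
        bundle.broods.to_csv(outdir / "broods.csv", index=False)
    if bundle.counts is not None:
        cdf = pd.DataFrame({"year": years})
        for i, hab in enumerate(HABITATS):
            cdf[hab] = bundle.counts.counts[i]
        cdf.to_csv(outdir / "counts.csv", index=False)
    if bundle.covariates is not None:
        bundle.covariates.to_csv(outdir / "covariates.csv", index=False)
    with open(outdir / "meta.yaml", "w") as fh:
        yaml.safe_dump(bundle.meta, fh)
    return outdir


def read_bundle(indir) -> DataBundle:
    """Load and validate a bundle directory written by :func:`write_bundle`."""
    indir = Path(indir)
    meta = {}
    if (indir / "meta.yaml").exists():
        with open(indir / "meta.yaml") as fh:
            meta = yaml.safe_load(fh) or {}

    counts = covariates = histories = broods = None
    years = None
    if (indir / "counts.csv").exists():
        cdf = pd.read_csv(indir / "counts.csv")
        missing = [h for h in HABITATS if h not in cdf.columns]
        if missing:
            raise BundleValidationError(f"counts.csv missing habitat columns {missing}")
        years = cdf["year"].to_numpy(dtype=int)
        counts = CountTable(
            counts=np.vstack([cdf[h].to_numpy(dtype=int) for h in HABITATS]),
            years=years,
        )
    if (indir / "covariates.csv").exists():
        covariates = pd.read_csv(indir / "covariates.csv")
        if years is None:
            years = covariates["year"].to_numpy(dtype=int)
    if (indir / "captures.csv").exists():
        df = pd.read_csv(indir / "captures.csv")
        ycols = [c for c in df.columns if c.startswith("y") and c[1:].isdigit()]
        hyears = np.array([int(c[1:]) for c in ycols])
        if years is None:
            years = hyears
        obs = df[ycols].to_numpy(dtype=int)
        seen = obs != 0
        if np.any(~seen.any(axis=1)):
            rows = list(np.flatnonzero(~seen.any(axis=1))[:5])
            raise BundleValidationError(f"capture rows never observed: {rows}")
        first_occ = seen.argmax(axis=1)
        first_age = np.where(df["age_first"].to_numpy() == "juv", 0, 1)
        histories = CaptureHistorySet(first_occ=first_occ, first_age=first_age, obs=obs)
    if (indir / "broods.csv").exists():
        broods = pd.read_csv(indir / "broods.csv")
        if years is None and len(broods):
            years = np.arange(broods["year"].min(), broods["year"].max() + 1)
    if years is None:
        raise BundleValidationError(f"no data tables found under {indir}")

    bundle = DataBundle(
        histories=histories, broods=broods, counts=counts,
        covariates=covariates, years=years, meta=meta,
    )
    validate_bundle(bundle)
    return bundle
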