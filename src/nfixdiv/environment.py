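"""Per-site environmental series and the three change predictors.

Each study site carries annual series of nitrogen deposition rate
(g N m^-2 yr^-1), mean annual temperature (deg C), precipitation (mm) and
potential evapotranspiration (mm).  From these the analysis derives, per
site and survey interval:

* cumulative N deposition between the two surveys (g N m^-2), with the
  last available year's rate re-used for any interval years past the end
  of the series (deposition data end before some resurveys);
* the change in mean annual temperature between two 5-year windows, each
  covering a survey year and its four preceding years;
* the change in the UNEP aridity index AI = P / PET, computed per year
  and then averaged over the same 5-year windows (higher AI = wetter).

All plots within a site share the site's environmental values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnvChange",
    "aridity_index",
    "moving_mean_5yr",
    "cumulative_n",
    "env_change",
    "read_environment_csv",
]

ENV_COLUMNS = ["site", "year", "n_dep", "temp", "precip", "pet"]


@dataclass(frozen=True)
class EnvChange:
    """Predictors for one site and survey interval."""

    site: str
    cum_n: float  # g N m^-2 accumulated between surveys
    delta_t: float  # deg C
    delta_ai: float  # dimensionless

    def __post_init__(self):
        if not np.isfinite([self.cum_n, self.delta_t, self.delta_ai]).all():
            raise ValueError(f"non-finite environmental change for site {self.site}")
        if self.cum_n < 0:
            raise ValueError("cumulative deposition cannot be negative")


def aridity_index(precip, pet):
    """UNEP aridity index P / PET; higher values mean lower aridity."""
    precip = np.asarray(precip, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if np.any(pet <= 0):
        raise ValueError("PET must be positive")
    return precip / pet


def _series_lookup(series: pd.Series, years: np.ndarray, what: str) -> np.ndarray:
    missing = [int(y) for y in years if y not in series.index]
    if missing:
        raise ValueError(f"{what}: missing years {missing}")
    return series.loc[years].to_numpy(dtype=float)


def moving_mean_5yr(series: pd.Series, survey_year: int) -> float:
    """Mean of the five annual values [survey_year - 4, survey_year].

    `series` is indexed by calendar year.  Every year in the window must
    be present; a silent shorter window would bias the change estimates.
    """
    window = np.arange(survey_year - 4, survey_year + 1)
    vals = _series_lookup(series, window, f"5-year window ending {survey_year}")
    return float(vals.mean())


def cumulative_n(
    series: pd.Series,
    baseline_year: int,
    resurvey_year: int,
    *,
    interval: str = "half-open",
) -> float:
    """Cumulative N deposition over the survey interval (g N m^-2).

    Annual rates are summed over the interval years.  For years beyond the
    last year in `series`, the last year's rate is carried forward (the
    deposition record ends before some resurveys and the rate is assumed
    not to change notably afterwards).

    Parameters
    ----------
    interval : {"half-open", "closed"}
        "half-open" sums years (baseline, resurvey] — deposition accrued
        after the baseline census; additive over concatenated intervals.
        "closed" also counts the baseline year.
    """
    if baseline_year >= resurvey_year:
        raise ValueError("baseline year must precede resurvey year")
    if interval not in ("half-open", "closed"):
        raise ValueError(f"unknown interval convention {interval!r}")
    series = series.sort_index()
    first, last = int(series.index[0]), int(series.index[-1])
    if baseline_year < first:
        raise ValueError(
            f"baseline year {baseline_year} precedes series start {first}"
        )
    start = baseline_year if interval == "closed" else baseline_year + 1
    years = np.arange(start, resurvey_year + 1)
    clamped = np.minimum(years, last)
    rates = series.loc[clamped].to_numpy(dtype=float)
    if np.any(rates < 0):
        raise ValueError("negative deposition rate")
    return float(rates.sum())


def env_change(
    site_series: pd.DataFrame,
    baseline_year: int,
    resurvey_year: int,
    *,
    interval: str = "half-open",
) -> EnvChange:
    """Derive the three predictors for one site's survey interval.

    `site_series` holds one site's annual rows with the columns
    ``site, year, n_dep, temp, precip, pet``.  The deposition clamp
    applies only to ``n_dep``; temperature and aridity windows must be
    fully covered by the series.
    """
    df = site_series.sort_values("year").set_index("year")
    sites = df["site"].unique()
    if len(sites) != 1:
        raise ValueError(f"expected a single site, got {sites.tolist()}")
    ai = pd.Series(
        aridity_index(df["precip"], df["pet"]), index=df.index, name="ai"
    )
    delta_t = moving_mean_5yr(df["temp"], resurvey_year) - moving_mean_5yr(
        df["temp"], baseline_year
    )
    delta_ai = moving_mean_5yr(ai, resurvey_year) - moving_mean_5yr(
        ai, baseline_year
    )
    cum_n = cumulative_n(df["n_dep"], baseline_year, resurvey_year, interval=interval)
    return EnvChange(
        site=str(sites[0]), cum_n=cum_n, delta_t=float(delta_t), delta_ai=float(delta_ai)
    )


def read_environment_csv(path) -> pd.DataFrame:
    """Read the per-site annual environment table.

    Expected columns: ``site, year, n_dep, temp, precip, pet`` with units
    g N m^-2 yr^-1, deg C, mm, mm.  Years must be consecutive within each
    site; deposition and precipitation non-negative, PET positive.
    """
    df = pd.read_csv(path)
    missing = set(ENV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"environment table missing columns: {sorted(missing)}")
    df = df[ENV_COLUMNS].copy()
    df["site"] = df["site"].astype(str)
    df["year"] = df["year"].astype(int)
    for site, grp in df.groupby("site"):
        years = grp["year"].sort_values().to_numpy()
        if len(years) != len(set(years)) or np.any(np.diff(years) != 1):
            raise ValueError(f"site {site}: years must be consecutive and unique")
    if (df["n_dep"] < 0).any():
        raise ValueError("n_dep must be non-negative")
    if (df["pet"] <= 0).any():
        raise ValueError("pet must be positive")
    if (df["precip"] < 0).any():
        raise ValueError("precip must be non-negative")
    return df
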