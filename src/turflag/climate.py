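"""Yearly climate drivers: site calibration against a reference station and
scenario generators (gradual warming curves, stepwise jumps, constants).

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ClimateSeries",
    "SiteCalibration",
    "fit_site_calibration",
    "gradual_scenario",
    "stepwise_scenario",
    "constant_scenario",
    "SHAPES",
]

SHAPES = ("linear", "plateau", "accelerating")

#: default temperature offsets (K) of synthetic transplant sites relative to
#: the home site, spanning ~0-5.5 K of warming.
DEFAULT_SITE_OFFSETS = (0.0, 2.2, 3.3, 5.5)


@dataclass
class ClimateSeries:
    """Yearly driver sequence for one site or scenario."""

    series_id: str
    years: np.ndarray
    t_summer: np.ndarray
    moisture: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.t_summer = np.asarray(self.t_summer, dtype=float)
        if self.moisture is None:
            self.moisture = np.full(self.years.shape, 0.5)
        self.moisture = np.asarray(self.moisture, dtype=float)
        if self.years.ndim != 1 or len(self.years) == 0:
            raise ValueError("years must be a non-empty 1-d sequence")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be strictly increasing and consecutive")
        if self.t_summer.shape != self.years.shape or self.moisture.shape != self.years.shape:
            raise ValueError("t_summer/moisture must align with years")
        if not np.all(np.isfinite(self.t_summer)):
            raise ValueError("temperatures must be finite")

    def __len__(self) -> int:
        return len(self.years)

    def slice(self, year_start: int, year_end: int) -> "ClimateSeries":
        """Inclusive year-range slice."""
        sel = (self.years >= year_start) & (self.years <= year_end)
        if not sel.any():
            raise ValueError(f"no years in [{year_start}, {year_end}]")
        return ClimateSeries(
            self.series_id, self.years[sel], self.t_summer[sel], self.moisture[sel]
        )


@dataclass(frozen=True)
class SiteCalibration:
    """Linear maps from station weather to site weather (OLS per variable)."""

    t_intercept: float
    t_slope: float
    t_resid_sd: float
    t_intercept_se: float
    t_slope_se: float
    m_intercept: Optional[float] = None
    m_slope: Optional[float] = None
    m_resid_sd: Optional[float] = None

    def predict_temperature(self, station_t):
        return self.t_intercept + self.t_slope * np.asarray(station_t, dtype=float)

    def predict_moisture(self, station_m):
        if self.m_intercept is None:
            raise ValueError("no moisture calibration fitted")
        return self.m_intercept + self.m_slope * np.asarray(station_m, dtype=float)


def _ols(y: np.ndarray, x: np.ndarray):
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = max(len(y) - 2, 1)
    return res.intercept, res.slope, float(np.sqrt((resid**2).sum() / dof)), res


def fit_site_calibration(
    site_t: Sequence[float],
    station_t: Sequence[float],
    site_m: Optional[Sequence[float]] = None,
    station_m: Optional[Sequence[float]] = None,
) -> SiteCalibration:
    """OLS regression of site weather on paired station weather."""
    y = np.asarray(site_t, dtype=float)
    x = np.asarray(station_t, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("site and station series must be 1-d and aligned")
    if len(y) < 3:
        raise ValueError("need at least 3 paired observations")
    a, b, sd, res = _ols(y, x)
    kwargs = {}
    if site_m is not None:
        ym = np.asarray(site_m, dtype=float)
        xm = np.asarray(station_m, dtype=float)
        if ym.shape != xm.shape or len(ym) < 3:
            raise ValueError("moisture series must be aligned with >= 3 pairs")
        am, bm, sdm, _ = _ols(ym, xm)
        kwargs = {"m_intercept": am, "m_slope": bm, "m_resid_sd": sdm}
    return SiteCalibration(
        t_intercept=a,
        t_slope=b,
        t_resid_sd=sd,
        t_intercept_se=float(res.intercept_stderr),
        t_slope_se=float(res.stderr),
        **kwargs,
    )


def _ramp(years: np.ndarray, year0: int, year_end: int, shape: str, plateau_year: int) -> np.ndarray:
    """Warming fraction in [0, 1] per year under the given qualitative shape."""
    x = (years - year0) / (year_end - year0)
    if shape == "linear":
        return x
    if shape == "accelerating":
        return x**2
    if shape == "plateau":
        # linear rise until the plateau year, flat at full warming afterwards
        xp = (plateau_year - year0) / (year_end - year0)
        if xp <= 0 or xp >= 1:
            return x
        return np.minimum(x / xp, 1.0)
    raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")


def gradual_scenario(
    T0: float,
    delta_end: float,
    year0: int,
    year_end: int,
    shape: str = "linear",
    interannual_sd: float = 0.0,
    seed: Optional[int] = None,
    moisture: float = 0.5,
    plateau_year: int = 2040,
    series_id: Optional[str] = None,
) -> ClimateSeries:
    """Smooth warming from T0 to T0 + delta_end plus seeded interannual noise.

    Shapes mirror the qualitative behaviour of low/mid/high emission
    pathways: ``plateau`` stabilises after ``plateau_year``, ``linear``
    warms steadily, ``accelerating`` warms ever faster.
    """
    if year_end <= year0:
        raise ValueError("year_end must exceed year0")
    if interannual_sd < 0:
        raise ValueError("interannual_sd must be non-negative")
    years = np.arange(year0, year_end + 1)
    mean = T0 + delta_end * _ramp(years, year0, year_end, shape, plateau_year)
    rng = np.random.default_rng(seed)
    temps = mean + rng.normal(0.0, interannual_sd, size=len(years))
    sid = series_id or f"gradual-{shape}-{delta_end:+.1f}K"
    return ClimateSeries(sid, years, temps, np.full(len(years), moisture))


def stepwise_scenario(
    source: ClimateSeries,
    window_start: int,
    window_end: int,
    n_years: int,
    seed: Optional[int] = None,
    start_year: Optional[int] = None,
    series_id: Optional[str] = None,
) -> ClimateSeries:
    """An immediate jump to the statistics of a window of ``source``.

    Draws ``n_years`` i.i.d. Gaussian temperatures with the sample mean and
    variance of the source series inside [window_start, window_end].
    """
    sel = (source.years >= window_start) & (source.years <= window_end)
    if not sel.any():
        raise ValueError("window contains no source years")
    vals = source.t_summer[sel]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    rng = np.random.default_rng(seed)
    temps = rng.normal(mean, sd, size=n_years)
    y0 = source.years[0] if start_year is None else start_year
    years = np.arange(y0, y0 + n_years)
    moist = np.full(n_years, float(source.moisture[sel].mean()))
    sid = series_id or f"stepwise-{window_start}-{window_end}"
    return ClimateSeries(sid, years, temps, moist)


def constant_scenario(
    T_ref: float,
    n_years: int,
    year0: int = 0,
    moisture: float = 0.5,
    series_id: str = "constant",
) -> ClimateSeries:
    """A constant-temperature series (e.g. for burn-in equilibration)."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    years = np.arange(year0, year0 + n_years)
    return ClimateSeries(
        series_id, years, np.full(n_years, float(T_ref)), np.full(n_years, moisture)
    )
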