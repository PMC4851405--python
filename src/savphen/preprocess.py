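"""Raw site series -> aligned 8-day analysis grid.

Day-length computation from solar geometry, NDVI gap-filling and resampling
to an 8-day grid, adaptive Savitzky-Golay smoothing with a jump rule for
rapid green-up, 8-day climate aggregation (median soil moisture, maximum
day length), and correlation-based variable screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from savphen.types import AlignedSeries, SiteRecord, STEP_DAYS

__all__ = [
    "day_length",
    "gapfill_resample",
    "adaptive_savgol",
    "aggregate_climate",
    "screen_variables",
    "align_site",
    "ScreeningReport",
]


def day_length(latitude_deg: float, dates) -> np.ndarray | float:
    """Astronomical day length in hours for a latitude and date(s).

    Uses the Cooper declination delta = 23.44 deg * sin(2*pi*(284 + doy)/365)
    and the sunset hour angle omega = arccos(-tan(phi) * tan(delta)) with the
    cosine argument clamped to [-1, 1], so polar day/night saturate at 24/0 h.
    """
    if not -90 <= latitude_deg <= 90:
        raise ValueError(f"latitude {latitude_deg} outside [-90, 90]")
    scalar = np.isscalar(dates) or isinstance(dates, (pd.Timestamp, str))
    idx = pd.DatetimeIndex([dates]) if scalar else pd.DatetimeIndex(dates)
    doy = idx.dayofyear.to_numpy(dtype=float)
    decl = np.deg2rad(23.44) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    phi = np.deg2rad(latitude_deg)
    cos_omega = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    hours = 24.0 * np.arccos(cos_omega) / np.pi
    return float(hours[0]) if scalar else hours


def gapfill_resample(
    ndvi: pd.DataFrame, step_days: int = STEP_DAYS
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Linearly interpolate composite NDVI onto a regular grid.

    The grid starts at the first acquisition date and advances in
    ``step_days`` increments up to (never beyond) the last acquisition —
    no extrapolation.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(ndvi["acq_date"]))
    values = ndvi["ndvi"].to_numpy(dtype=float)
    if len(dates) < 2:
        raise ValueError("need at least 2 NDVI observations to interpolate")
    day = (dates - dates[0]).days.to_numpy(dtype=float)
    if not (np.diff(day) > 0).all():
        raise ValueError("NDVI acquisition dates must be strictly increasing")
    grid_day = np.arange(0.0, day[-1] + 1.0, float(step_days))
    grid_day = grid_day[grid_day <= day[-1]]
    grid_values = np.interp(grid_day, day, values)
    grid_dates = dates[0] + pd.to_timedelta(grid_day, unit="D")
    return pd.DatetimeIndex(grid_dates), grid_values


def adaptive_savgol(
    series,
    window: int = 7,
    degree: int = 2,
    jump_threshold: float = 0.08,
    small_window: int = 3,
) -> np.ndarray:
    """Savitzky-Golay smoothing that preserves rapid green-up.

    Each midpoint is replaced by the centre value of a degree-``degree``
    least-squares polynomial over ``window`` points.  Points whose RAW value
    differs from either temporal neighbour by more than ``jump_threshold``
    are filtered with ``small_window`` instead, so genuine fast transitions
    survive.  Edge points are fitted with a polynomial over the terminal
    window, preserving polynomial series exactly end to end.
    """
    x = np.asarray(series, dtype=float)
    if window % 2 == 0 or small_window % 2 == 0:
        raise ValueError("window sizes must be odd")
    if small_window > window:
        raise ValueError("small_window must not exceed window")
    if x.ndim != 1 or len(x) < window:
        raise ValueError(f"series must be 1-D with length >= {window}")
    wide = savgol_filter(x, window, degree, mode="interp")
    narrow = savgol_filter(x, small_window, min(degree, small_window - 1), mode="interp")
    jump = np.zeros(len(x), dtype=bool)
    d = np.abs(np.diff(x))
    jump[:-1] |= d > jump_threshold  # vs next neighbour
    jump[1:] |= d > jump_threshold  # vs previous neighbour
    return np.where(jump, narrow, wide)


def aggregate_climate(
    climate: pd.DataFrame,
    latitude: float,
    grid_dates: pd.DatetimeIndex,
    step_days: int = STEP_DAYS,
) -> tuple[np.ndarray, np.ndarray]:
    """8-day climate summaries matched to the NDVI grid.

    Per grid step the soil-moisture median and day-length maximum are taken
    over the half-open daily window [step, step + ``step_days``); a partial
    final window is allowed, an empty one is an error.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(climate["date"]))
    sm_daily = climate["sm_volpct"].to_numpy(dtype=float)
    dayl_daily = day_length(latitude, dates)
    day = (dates - dates[0]).days.to_numpy()
    grid_day = (pd.DatetimeIndex(grid_dates) - dates[0]).days.to_numpy()
    sm_out = np.empty(len(grid_day))
    dayl_out = np.empty(len(grid_day))
    for i, g in enumerate(grid_day):
        lo = np.searchsorted(day, g, side="left")
        hi = np.searchsorted(day, g + step_days, side="left")
        if hi <= lo:
            raise ValueError(
                f"no daily climate values in window starting {grid_dates[i].date()}"
            )
        sm_out[i] = np.median(sm_daily[lo:hi])
        dayl_out[i] = np.max(dayl_daily[lo:hi])
    return sm_out, dayl_out


@dataclass
class ScreeningReport:
    """Outcome of correlation-based variable screening."""

    retained: list[str]
    ndvi_corr: pd.Series  # per-variable mean Pearson r with NDVI
    pair_corr: pd.DataFrame  # mean mutual r between candidates
    dropped: dict[str, str]  # variable -> reason


def screen_variables(
    candidates: Mapping[str, Sequence[np.ndarray]],
    ndvi: Sequence[np.ndarray],
    correlation_threshold: float = 0.7,
) -> ScreeningReport:
    """Drop redundant climate candidates before the model search.

    Each candidate's Pearson correlation with NDVI is computed per site and
    averaged.  For any candidate pair whose mean mutual |r| exceeds
    ``correlation_threshold``, the member with the weaker mean |r| against
    NDVI is dropped.  Constant (zero-variance) series are flagged and
    dropped with a warning.
    """
    names = list(candidates)
    n_sites = len(ndvi)
    if n_sites < 1:
        raise ValueError("need at least one site")
    dropped: dict[str, str] = {}

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    ndvi_corr = {}
    for name in names:
        rs = [_corr(candidates[name][s], ndvi[s]) for s in range(n_sites)]
        if np.isnan(rs).any():
            warnings.warn(f"variable {name!r} is constant on some site; dropped")
            dropped[name] = "constant series; correlation undefined"
            ndvi_corr[name] = np.nan
        else:
            ndvi_corr[name] = float(np.mean(rs))
    ndvi_corr = pd.Series(ndvi_corr, name="mean_r_ndvi")

    pair = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            rs = [_corr(candidates[a][s], candidates[b][s]) for s in range(n_sites)]
            mean_r = float(np.nanmean(rs)) if not np.isnan(rs).all() else 0.0
            pair.loc[a, b] = pair.loc[b, a] = mean_r

    alive = [n for n in names if n not in dropped]
    # repeatedly drop the weaker member of the worst over-threshold pair
    while True:
        worst, worst_r = None, correlation_threshold
        for i, a in enumerate(alive):
            for b in alive[i + 1 :]:
                r = abs(pair.loc[a, b])
                if r > worst_r:
                    worst, worst_r = (a, b), r
        if worst is None:
            break
        a, b = worst
        loser = a if abs(ndvi_corr[a]) < abs(ndvi_corr[b]) else b
        dropped[loser] = (
            f"mean |r|={worst_r:.2f} with {'%s' % (b if loser == a else a)} "
            f"exceeds {correlation_threshold}; weaker NDVI correlation"
        )
        alive.remove(loser)

    return ScreeningReport(alive, ndvi_corr, pair, dropped)


def align_site(
    record: SiteRecord,
    window: int = 7,
    degree: int = 2,
    jump_threshold: float = 0.08,
    small_window: int = 3,
) -> AlignedSeries:
    """Full preprocessing for one site: resample, smooth, aggregate."""
    grid_dates, ndvi_grid = gapfill_resample(record.ndvi)
    ndvi_smooth = adaptive_savgol(
        ndvi_grid,
        window=window,
        degree=degree,
        jump_threshold=jump_threshold,
        small_window=small_window,
    )
    sm, dayl = aggregate_climate(record.climate, record.latitude, grid_dates)
    return AlignedSeries(record.site_id, grid_dates, ndvi_smooth, sm, dayl)
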