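"""Synthetic savannah-site ensembles for exercising the pipeline.

Soil moisture comes from a pulsed bucket model (Poisson rain events inside a
wet-season window, exponential depths, exponential storage decay), day length
from solar geometry, and NDVI from a lagged log-linear response plus Gaussian
noise, sampled composite-style with acquisition-date jitter and random gaps.

Two generation paths are provided:

* :func:`generate_site` / :func:`generate_ensemble` — daily latent NDVI
  composited into a raw :class:`~savphen.types.SiteRecord`, so preprocessing
  is genuinely exercised end to end;
* :func:`generate_aligned_ensemble` — NDVI written as an *exact* (up to
  noise) function of the lagged 8-day aggregated climate, the bedrock for
  coefficient-recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from savphen.preprocess import aggregate_climate, day_length
from savphen.types import AlignedSeries, SiteRecord, SynthConfig, TermSpec, STEP_DAYS

__all__ = [
    "simulate_rainfall",
    "generate_soil_moisture",
    "composite_sample",
    "generate_site",
    "generate_ensemble",
    "generate_aligned_ensemble",
]

SM_FLOOR = 0.1  # volumetric %; keeps log transforms finite
SPINUP_DAYS = 365  # discarded bucket-model warm-up
HISTORY_DAYS = 80  # daily history kept ahead of the first NDVI sample
SIM_START = pd.Timestamp("2000-01-01")


def _wet_season_mask(dates: pd.DatetimeIndex, window: tuple[int, int], southern: bool) -> np.ndarray:
    """True on days inside the wet-season day-of-year window.

    The window may wrap the year end; for southern-hemisphere sites it is
    shifted by half a year so the wet season tracks local summer.
    """
    doy = dates.dayofyear.to_numpy()
    if southern:
        doy = ((doy - 1 + 182) % 365) + 1
    lo, hi = window
    if lo <= hi:
        return (doy >= lo) & (doy <= hi)
    return (doy >= lo) | (doy <= hi)


def simulate_rainfall(
    config: SynthConfig,
    dates: pd.DatetimeIndex,
    rng: np.random.Generator,
    southern: bool = False,
    rain_rate: float | None = None,
) -> np.ndarray:
    """Daily rain depths (mm): Poisson event counts x exponential depths."""
    rate = config.rain_rate if rain_rate is None else rain_rate
    wet = _wet_season_mask(dates, config.wet_season_doy, southern)
    counts = np.where(wet, rng.poisson(rate, size=len(dates)), 0)
    rain = np.zeros(len(dates))
    nz = counts > 0
    # sum of k iid Exp(mean) depths == Gamma(k, mean)
    rain[nz] = rng.gamma(counts[nz], config.event_depth_mean)
    return rain


def generate_soil_moisture(
    config: SynthConfig,
    site_latitude: float,
    n_days: int,
    rng: np.random.Generator,
    rain_rate: float | None = None,
    start_date: pd.Timestamp = SIM_START,
) -> np.ndarray:
    """Bucket-model daily volumetric soil moisture in (SM_FLOOR, field capacity].

    A 100 mm surface layer is assumed, so 1 mm of stored water equals
    1 volumetric %.  Storage loses ``sm_decay`` per day, rain events add
    depth, and the store is clamped to the floor/field-capacity bounds.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    dates = pd.date_range(start_date, periods=n_days, freq="D")
    rain = simulate_rainfall(config, dates, rng, site_latitude < 0, rain_rate)
    sm = np.empty(n_days)
    store = SM_FLOOR
    keep = 1.0 - config.sm_decay
    cap = config.sm_field_capacity
    for t in range(n_days):
        store = min(store * keep + rain[t], cap)
        store = max(store, SM_FLOOR)
        sm[t] = store
    return sm


def composite_sample(
    daily_ndvi: pd.Series,
    composite_period: int,
    jitter: int,
    gap_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Composite-style sampling of a daily series.

    One observation per ``composite_period``-day window, acquired at the
    window start plus a uniform integer offset of at most ``jitter`` days;
    a fraction ``gap_fraction`` of observations is then removed at random.
    """
    if len(daily_ndvi) == 0:
        raise ValueError("empty daily NDVI series")
    if composite_period < 1:
        raise ValueError("composite_period must be >= 1")
    if not 0 <= jitter < composite_period:
        raise ValueError("jitter must satisfy 0 <= jitter < composite_period")
    n_windows = len(daily_ndvi) // composite_period
    if n_windows == 0:
        raise ValueError("series shorter than one composite window")
    starts = np.arange(n_windows) * composite_period
    offsets = rng.integers(0, jitter + 1, size=n_windows) if jitter > 0 else np.zeros(n_windows, dtype=int)
    pos = starts + offsets
    keep = rng.random(n_windows) >= gap_fraction
    pos = pos[keep]
    return pd.DataFrame(
        {
            "acq_date": daily_ndvi.index[pos],
            "ndvi": daily_ndvi.to_numpy(dtype=float)[pos],
        }
    )


def _transform_daily(term: TermSpec, sm: np.ndarray, dayl: np.ndarray, map_m_per_yr: float) -> np.ndarray:
    if term.variable == "sm":
        if term.transform == "log":
            return np.log(sm)
        return np.log(sm * map_m_per_yr)
    return dayl


def _window_aggregate(daily: np.ndarray, how: str, width: int = STEP_DAYS) -> np.ndarray:
    """Trailing-window climate summary per day: value for day d summarises
    days [d, d + width).  Output is ``width - 1`` days shorter than input.

    Matches the 8-day grid aggregation convention (median soil moisture,
    maximum day length), so a lag planted in these aggregates is exactly
    representable by the downstream regression grid.
    """
    win = np.lib.stride_tricks.sliding_window_view(daily, width)
    return np.median(win, axis=1) if how == "median" else np.max(win, axis=1)


def _site_rng(config: SynthConfig, site_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, site_index]))


def _site_basics(config: SynthConfig, site_index: int, rng: np.random.Generator):
    """Metadata plus the full daily climate record (spin-up discarded).

    The rain-event rate is scaled so the expected annual total matches the
    site's MAP draw, tying soil-moisture dynamics to the recorded MAP.
    """
    lat = float(rng.uniform(*config.latitude_range))
    map_m = float(rng.uniform(*config.map_range))
    lo, hi = config.map_range
    rel = (map_m - lo) / (hi - lo)
    tree_cover = float(np.clip(80.0 * rel + 10.0 * rng.normal(), 0.0, 100.0))
    aridity = float(np.clip(0.03 + 0.62 * rel + 0.05 * rng.normal(), 0.03, 0.65))

    probe = pd.date_range(SIM_START, periods=365, freq="D")
    season_days = int(_wet_season_mask(probe, config.wet_season_doy, lat < 0).sum())
    rate = (map_m * 1000.0) / (config.event_depth_mean * max(season_days, 1))

    n_days = SPINUP_DAYS + HISTORY_DAYS + config.n_years * 365
    sm = generate_soil_moisture(config, lat, n_days, rng, rain_rate=rate)
    dates = pd.date_range(SIM_START, periods=n_days, freq="D")
    # discard bucket warm-up
    dates, sm = dates[SPINUP_DAYS:], sm[SPINUP_DAYS:]
    dayl = day_length(lat, dates)
    tair = 18.0 + 10.0 * (dayl - np.mean(dayl)) / max(np.ptp(dayl), 1e-9) + rng.normal(0, 1.5, len(dates))
    climate = pd.DataFrame(
        {"date": dates, "sm_volpct": sm, "tair_c": np.round(tair, 3)}
    )
    return lat, map_m, tree_cover, aridity, climate


def generate_site(config: SynthConfig, site_index: int) -> SiteRecord:
    """One synthetic site: daily latent NDVI composited into a SiteRecord.

    Daily latent NDVI = intercept + sum of coefficient x transform(8-day
    trailing climate summary lagged by 8 x lag days) + Gaussian noise,
    clipped to [0, 1], then composite-sampled.  The climate enters through
    the same trailing-window summaries (median soil moisture, maximum day
    length) the analysis grid uses, so the planted lag is exactly
    representable downstream.  Identical config + seed give identical
    output.
    """
    rng = _site_rng(config, site_index)
    lat, map_m, tree_cover, aridity, climate = _site_basics(config, site_index, rng)
    dates = pd.DatetimeIndex(climate["date"])
    sm = climate["sm_volpct"].to_numpy()
    dayl = day_length(lat, dates)
    sm_agg = _window_aggregate(sm, "median")
    dayl_agg = _window_aggregate(dayl, "max")

    terms = config.term_specs()
    max_lag_days = max((t.lag for t, _ in terms), default=0) * STEP_DAYS
    if max_lag_days > HISTORY_DAYS:
        raise ValueError("lag exceeds available daily history")
    n_total = len(sm_agg)  # last STEP_DAYS-1 days lack a complete window
    n_obs_days = n_total - HISTORY_DAYS
    if n_obs_days < 1:
        raise ValueError("lag longer than the simulated series")
    latent = np.full(n_obs_days, config.intercept)
    for term, coef in terms:
        full = _transform_daily(term, sm_agg, dayl_agg, map_m)
        lag = term.lag * STEP_DAYS
        latent = latent + coef * full[HISTORY_DAYS - lag : n_total - lag]
    if config.noise_sd > 0:
        latent = latent + rng.normal(0.0, config.noise_sd, n_obs_days)
    latent = np.clip(latent, 0.0, 1.0)

    daily = pd.Series(latent, index=dates[HISTORY_DAYS : HISTORY_DAYS + n_obs_days])
    ndvi = composite_sample(
        daily, config.composite_period, config.jitter, config.gap_fraction, rng
    )
    return SiteRecord(
        site_id=f"site{site_index:02d}",
        latitude=lat,
        map_m_per_yr=map_m,
        tree_cover=tree_cover,
        aridity_index=aridity,
        climate=climate,
        ndvi=ndvi,
    )


def generate_ensemble(config: SynthConfig) -> list[SiteRecord]:
    """All sites of the configured ensemble (deterministic in the seed)."""
    return [generate_site(config, i) for i in range(config.n_sites)]


def generate_aligned_ensemble(
    config: SynthConfig,
    site_intercept_sd: float = 0.0,
) -> tuple[list[AlignedSeries], dict[str, float], pd.DataFrame]:
    """Aligned 8-day series whose NDVI is an exact lagged function of the
    aggregated climate (plus optional noise and per-site intercept shifts).

    NDVI(t) = intercept + sum coef x transform(grid variable at t - lag) so
    with ``noise_sd = 0`` the planted model is exactly recoverable by the
    selection pipeline.  ``site_intercept_sd`` adds a per-site N(0, sd)
    intercept perturbation to create ensemble heterogeneity.

    Returns (aligned series, MAP by site id, metadata table).
    """
    aligned: list[AlignedSeries] = []
    map_by_site: dict[str, float] = {}
    meta_rows = []
    terms = config.term_specs()
    max_lag = max((t.lag for t, _ in terms), default=0)
    for i in range(config.n_sites):
        rng = _site_rng(config, i)
        lat, map_m, tree_cover, aridity, climate = _site_basics(config, i, rng)
        dates = pd.DatetimeIndex(climate["date"])
        # grid covers the lag history plus the observation period
        n_steps_obs = (config.n_years * 365) // STEP_DAYS
        grid = dates[0] + pd.to_timedelta(
            np.arange(max_lag + n_steps_obs) * STEP_DAYS, unit="D"
        )
        sm_grid, dayl_grid = aggregate_climate(climate, lat, grid)
        ndvi = np.full(n_steps_obs, config.intercept)
        for term, coef in terms:
            full = _transform_daily(term, sm_grid, dayl_grid, map_m)
            ndvi = ndvi + coef * full[max_lag - term.lag : len(grid) - term.lag]
        if site_intercept_sd > 0:
            ndvi = ndvi + site_intercept_sd * rng.normal()
        if config.noise_sd > 0:
            ndvi = ndvi + rng.normal(0.0, config.noise_sd, n_steps_obs)
        ndvi = np.clip(ndvi, 0.0, 1.0)
        sid = f"site{i:02d}"
        aligned.append(
            AlignedSeries(sid, grid[max_lag:], ndvi, sm_grid[max_lag:], dayl_grid[max_lag:])
        )
        map_by_site[sid] = map_m
        meta_rows.append(
            {
                "site_id": sid,
                "latitude": lat,
                "map_m_per_yr": map_m,
                "tree_cover_pct": tree_cover,
                "aridity_index": aridity,
            }
        )
    return aligned, map_by_site, pd.DataFrame(meta_rows)
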