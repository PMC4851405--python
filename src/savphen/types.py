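"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: variables the regression search knows about
VARIABLES = ("sm", "dayl")

#: transforms admissible per variable
SM_TRANSFORMS = ("log", "log_map")
DAYL_TRANSFORMS = ("identity",)

MAX_LAG_DEFAULT = 10
STEP_DAYS = 8


@dataclass(frozen=True)
class TermSpec:
    """One regression term: a variable, its transform, and a lag in 8-day steps.

    Soil moisture (``sm``) enters through a log-family transform — plain
    ``log`` or ``log_map`` (log of soil moisture times mean annual
    precipitation).  Day length (``dayl``) enters untransformed.
    """

    variable: str
    transform: str
    lag: int

    def __post_init__(self) -> None:
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        allowed = SM_TRANSFORMS if self.variable == "sm" else DAYL_TRANSFORMS
        if self.transform not in allowed:
            raise ValueError(
                f"transform {self.transform!r} not allowed for {self.variable}"
            )
        if not (0 <= int(self.lag) <= MAX_LAG_DEFAULT):
            raise ValueError(f"lag must be in [0, {MAX_LAG_DEFAULT}], got {self.lag}")

    def label(self) -> str:
        if self.transform == "log":
            return f"log(sm_{self.lag})"
        if self.transform == "log_map":
            return f"log(sm_{self.lag}*MAP)"
        return f"dayL_{self.lag}"


@dataclass
class CandidateModel:
    """A fitted candidate regression: term set, coefficients, and fit scores."""

    terms: tuple[TermSpec, ...]
    coefficients: np.ndarray
    intercept: float
    rss: float
    r2: float
    bic: float
    n_obs: int

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.terms),):
            raise ValueError("one coefficient per term required")

    @property
    def n_params(self) -> int:
        """Slope coefficients plus intercept."""
        return len(self.terms) + 1

    @property
    def max_lag(self) -> int:
        return max(t.lag for t in self.terms)

    def equation(self) -> str:
        parts = [
            f"{c:+.4f}*{t.label()}" for c, t in zip(self.coefficients, self.terms)
        ]
        return "NDVI = " + " ".join(parts) + f" {self.intercept:+.4f}"


@dataclass
class SynthConfig:
    """Configuration of the synthetic site-ensemble generator."""

    n_sites: int = 15
    n_years: int = 3
    latitude_range: tuple[float, float] = (-25.0, 40.0)
    map_range: tuple[float, float] = (0.3, 1.2)  # m/year
    wet_season_doy: tuple[int, int] = (305, 90)  # window may wrap the year end
    rain_rate: float = 0.5  # expected events/day inside the wet season
    event_depth_mean: float = 8.0  # mm
    sm_decay: float = 0.015  # fractional loss per day
    sm_field_capacity: float = 40.0  # volumetric %
    true_terms: tuple[tuple[str, str, int, float], ...] = (
        ("sm", "log_map", 2, 0.12),
        ("dayl", "identity", 2, 0.01),
    )
    intercept: float = 0.22
    noise_sd: float = 0.02
    composite_period: int = 16
    jitter: int = 8
    gap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        lo, hi = self.latitude_range
        if not (-90 <= lo < hi <= 90):
            raise ValueError("latitude_range must be non-degenerate within [-90, 90]")
        mlo, mhi = self.map_range
        if not (0 < mlo < mhi):
            raise ValueError("map_range must be non-degenerate and positive")
        if self.rain_rate < 0:
            raise ValueError("rain_rate must be >= 0")
        if self.event_depth_mean <= 0:
            raise ValueError("event_depth_mean must be > 0")
        if not (0 < self.sm_decay < 1):
            raise ValueError("sm_decay must be in (0, 1)")
        if not (0 < self.sm_field_capacity <= 100):
            raise ValueError("sm_field_capacity must be in (0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.composite_period < 1:
            raise ValueError("composite_period must be >= 1")
        if not (0 <= self.jitter < self.composite_period):
            raise ValueError("jitter must satisfy 0 <= jitter < composite_period")
        if not (0 <= self.gap_fraction < 1):
            raise ValueError("gap_fraction must be in [0, 1)")
        for var, transform, lag, _coef in self.true_terms:
            TermSpec(var, transform, int(lag))  # validates variable/transform/lag

    def term_specs(self) -> list[tuple[TermSpec, float]]:
        return [
            (TermSpec(v, tr, int(lag)), float(coef))
            for v, tr, lag, coef in self.true_terms
        ]


@dataclass
class SiteRecord:
    """One site: metadata plus raw daily climate and composite NDVI series.

    ``climate`` columns: date (daily, strictly increasing), sm_volpct,
    optionally tair_c.  ``ndvi`` columns: acq_date (strictly increasing),
    ndvi in [-1, 1].
    """

    site_id: str
    latitude: float
    map_m_per_yr: float
    tree_cover: float
    aridity_index: float
    climate: pd.DataFrame
    ndvi: pd.DataFrame

    def __post_init__(self) -> None:
        if not (-90 <= self.latitude <= 90):
            raise ValueError(f"{self.site_id}: latitude out of range")
        if not (0 < self.map_m_per_yr < 10):
            raise ValueError(
                f"{self.site_id}: MAP {self.map_m_per_yr} not plausible in m/year "
                "(did you pass mm/year?)"
            )
        if not (0 <= self.tree_cover <= 100):
            raise ValueError(f"{self.site_id}: tree_cover out of [0, 100]")
        cd = pd.to_datetime(self.climate["date"])
        deltas = cd.diff().dropna().dt.days
        if len(cd) == 0:
            raise ValueError(f"{self.site_id}: empty climate series")
        if not (deltas == 1).all():
            raise ValueError(f"{self.site_id}: climate dates must be daily")
        sm = self.climate["sm_volpct"].to_numpy(dtype=float)
        if not ((sm > 0) & (sm <= 100)).all():
            raise ValueError(f"{self.site_id}: sm_volpct must lie in (0, 100]")
        nd = pd.to_datetime(self.ndvi["acq_date"])
        if len(nd) == 0:
            raise ValueError(f"{self.site_id}: empty NDVI series")
        if not nd.is_monotonic_increasing or nd.duplicated().any():
            raise ValueError(f"{self.site_id}: NDVI dates must strictly increase")
        vals = self.ndvi["ndvi"].to_numpy(dtype=float)
        if not ((vals >= -1) & (vals <= 1)).all():
            raise ValueError(f"{self.site_id}: NDVI outside [-1, 1]")


@dataclass
class AlignedSeries:
    """A site's co-registered 8-day grid of smoothed NDVI, soil moisture
    (8-day median, volumetric %) and day length (8-day maximum, hours)."""

    site_id: str
    step_dates: pd.DatetimeIndex
    ndvi: np.ndarray
    sm: np.ndarray
    dayl: np.ndarray

    def __post_init__(self) -> None:
        self.step_dates = pd.DatetimeIndex(self.step_dates)
        self.ndvi = np.asarray(self.ndvi, dtype=float)
        self.sm = np.asarray(self.sm, dtype=float)
        self.dayl = np.asarray(self.dayl, dtype=float)
        n = len(self.step_dates)
        if not (len(self.ndvi) == len(self.sm) == len(self.dayl) == n):
            raise ValueError(f"{self.site_id}: aligned series lengths differ")
        if n >= 2:
            steps = np.diff(self.step_dates.to_numpy()).astype("timedelta64[D]")
            if not (steps == np.timedelta64(STEP_DAYS, "D")).all():
                raise ValueError(f"{self.site_id}: grid spacing must be 8 days")
        for name, arr in (("ndvi", self.ndvi), ("sm", self.sm), ("dayl", self.dayl)):
            if np.isnan(arr).any():
                raise ValueError(f"{self.site_id}: NaN in aligned {name}")

    def __len__(self) -> int:
        return len(self.step_dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_date": self.step_dates,
                "ndvi_smooth": self.ndvi,
                "sm_med": self.sm,
                "dayl_max": self.dayl,
            }
        )


@dataclass
class PhenoMetrics:
    """Per-cycle start-of-season indices and whole-series NDVI amplitude."""

    site_id: str
    sos_steps: list[int]
    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class EvalSummary:
    """Distributions of holdout RMSE, r² and VIF over repetitions."""

    rmse_mean: float
    rmse_sd: float
    r2_mean: float
    r2_sd: float
    vif_mean: float
    vif_sd: float
    n_reps: int
    reps: pd.DataFrame = field(repr=False)
    per_site_rmse: Optional[pd.Series] = None
    sos_error_steps: Optional[pd.Series] = None
    amplitude_error: Optional[pd.Series] = None
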