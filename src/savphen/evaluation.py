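"""Model evaluation: resampled holdout, VIF, site-count sensitivity,
start-of-season / amplitude phenometrics, and importance correlations."""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from savphen.lagged_model import build_design, fit_ols
from savphen.preprocess import adaptive_savgol
from savphen.types import AlignedSeries, EvalSummary, PhenoMetrics, TermSpec

__all__ = [
    "vif",
    "site_sensitivity",
    "holdout_cv",
    "start_of_season",
    "phenometrics",
    "compare_phenometrics",
    "importance_correlates",
]

logger = logging.getLogger(__name__)


def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j).

    R2_j regresses regressor j on all others (with intercept).  Perfect
    collinearity yields an infinity sentinel with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 regressors")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than regressors")
    out = np.empty(p)
    for j in range(p):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, _, _, _ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ beta
        tss = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        r2_j = 0.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
        if r2_j >= 1.0 - 1e-12:
            warnings.warn(f"regressor {j} perfectly collinear; VIF = inf")
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2_j)
    return out


def _refit(sites, map_by_site, terms):
    y, X = build_design(sites, map_by_site, terms)
    coef, intercept, rss, _ = fit_ols(X, y)
    return coef, intercept, rss, len(y)


def site_sensitivity(
    sites: Sequence[AlignedSeries],
    map_by_site: Mapping[str, float],
    terms: Sequence[TermSpec],
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean in-sample RMSE vs number of sites used to refit the model.

    For each k in 1..n_sites, ``reps`` random k-subsets are drawn, the
    fixed term set's coefficients are refitted on the pooled subset, and
    the in-sample RMSE recorded.  Returns a (k, mean_rmse) table.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, len(sites) + 1):
        rmses = []
        for _ in range(reps):
            pick = rng.choice(len(sites), size=k, replace=False)
            chosen = [sites[i] for i in pick]
            try:
                _, _, rss, n = _refit(chosen, map_by_site, terms)
            except ValueError as exc:  # e.g. rank deficiency at tiny k
                logger.warning("site_sensitivity k=%d rep skipped: %s", k, exc)
                continue
            rmses.append(np.sqrt(rss / n))
        rows.append({"k": k, "mean_rmse": float(np.mean(rmses)), "n_reps": len(rmses)})
    return pd.DataFrame(rows)


def holdout_cv(
    sites: Sequence[AlignedSeries],
    map_by_site: Mapping[str, float],
    terms: Sequence[TermSpec],
    n_test: int = 3,
    reps: int = 1000,
    seed: int = 0,
    r2_mode: str = "pearson",
) -> EvalSummary:
    """Site-holdout cross-validation of a fixed term set.

    Each repetition refits the coefficients on a random train split and
    evaluates on the pooled held-out sites: RMSE, r2 (squared Pearson
    correlation of predicted vs observed by default; ``r2_mode='ssr'``
    gives 1 - SSE/SST), and the VIF of the evaluation design's regressors
    (NaN for single-regressor models).
    """
    n_sites = len(sites)
    if not (0 < n_test < n_sites):
        raise ValueError("need n_sites > n_test >= 1")
    if r2_mode not in ("pearson", "ssr"):
        raise ValueError("r2_mode must be 'pearson' or 'ssr'")
    rng = np.random.default_rng(seed)
    terms = list(terms)
    rows = []
    for rep in range(reps):
        order = rng.permutation(n_sites)
        train = [sites[i] for i in order[n_test:]]
        test = [sites[i] for i in order[:n_test]]
        coef, intercept, _, _ = _refit(train, map_by_site, terms)
        y_te, X_te = build_design(test, map_by_site, terms)
        if len(y_te) <= X_te.shape[1]:
            logger.warning("holdout rep %d discarded: evaluation design too short", rep)
            continue
        pred = intercept + X_te @ coef
        rmse = float(np.sqrt(np.mean((pred - y_te) ** 2)))
        if r2_mode == "pearson":
            r2 = float(np.corrcoef(pred, y_te)[0, 1] ** 2)
        else:
            sse = float(np.sum((pred - y_te) ** 2))
            sst = float(np.sum((y_te - y_te.mean()) ** 2))
            r2 = 1.0 - sse / sst
        v = float(np.mean(vif(X_te))) if X_te.shape[1] >= 2 else np.nan
        rows.append({"rep": rep, "rmse": rmse, "r2": r2, "vif": v})
    reps_df = pd.DataFrame(rows)
    if reps_df.empty:
        raise ValueError("all holdout repetitions were discarded")
    return EvalSummary(
        rmse_mean=float(reps_df["rmse"].mean()),
        rmse_sd=float(reps_df["rmse"].std(ddof=1)),
        r2_mean=float(reps_df["r2"].mean()),
        r2_sd=float(reps_df["r2"].std(ddof=1)),
        vif_mean=float(reps_df["vif"].mean()),
        vif_sd=float(reps_df["vif"].std(ddof=1)),
        n_reps=len(reps_df),
        reps=reps_df,
    )


def _cycles(x: np.ndarray, min_prominence_frac: float) -> list[tuple[int, int, int]]:
    """Growing cycles as (preceding-minimum, peak, SOS) index triples.

    Peaks qualify when their prominence reaches ``min_prominence_frac`` of
    the series amplitude; the preceding minimum is the lowest point since
    the previous qualifying peak (or the series start); SOS is the rising-
    limb index whose value is nearest the min/peak midpoint, earliest on
    ties.
    """
    x = np.asarray(x, dtype=float)
    amp = float(np.max(x) - np.min(x)) if len(x) else 0.0
    if amp == 0:
        return []
    peaks, _ = find_peaks(x, prominence=min_prominence_frac * amp)
    cycles = []
    prev_peak = 0
    for p in peaks:
        seg_start = prev_peak
        min_idx = seg_start + int(np.argmin(x[seg_start : p + 1]))
        midpoint = 0.5 * (x[p] + x[min_idx])
        limb = x[min_idx : p + 1]
        sos = min_idx + int(np.argmin(np.abs(limb - midpoint)))
        cycles.append((min_idx, int(p), sos))
        prev_peak = int(p)
    return cycles


def start_of_season(
    series, min_prominence_frac: float = 0.35
) -> list[int]:
    """Per-cycle start-of-season indices on the series' own grid.

    SOS is the step whose value is closest to the midpoint between a
    cycle's peak and its preceding minimum.  A series with no qualifying
    cycle returns an empty list.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 5:
        raise ValueError("series too short for cycle detection")
    return [sos for _, _, sos in _cycles(x, min_prominence_frac)]


def phenometrics(
    site_id: str, series, min_prominence_frac: float = 0.35
) -> PhenoMetrics:
    """SOS steps plus whole-series amplitude (max - min NDVI)."""
    x = np.asarray(series, dtype=float)
    return PhenoMetrics(
        site_id=site_id,
        sos_steps=start_of_season(x, min_prominence_frac),
        amplitude=float(np.max(x) - np.min(x)),
    )


def compare_phenometrics(
    model_series,
    observed_series,
    min_prominence_frac: float = 0.35,
    refilter_model: bool = False,
    **savgol_kwargs,
) -> tuple[list[int], float]:
    """Per-site phenometric errors of a modelled series vs observations.

    Cycles are matched by nearest peak; for each matched pair the SOS error
    is model SOS - observed SOS (in grid steps).  The amplitude error is
    model amplitude - observed amplitude.  ``refilter_model`` applies the
    adaptive Savitzky-Golay filter to the modelled series first, mirroring
    how the observations were smoothed.  Unmatched cycles are logged.
    """
    model = np.asarray(model_series, dtype=float)
    observed = np.asarray(observed_series, dtype=float)
    if len(model) != len(observed):
        raise ValueError("series must share one grid")
    if refilter_model:
        model = adaptive_savgol(model, **savgol_kwargs)
    mc = _cycles(model, min_prominence_frac)
    oc = _cycles(observed, min_prominence_frac)
    if len(mc) != len(oc):
        logger.warning(
            "cycle-count mismatch (model %d vs observed %d); matching overlap",
            len(mc),
            len(oc),
        )
    sos_errors: list[int] = []
    used: set[int] = set()
    for _, m_peak, m_sos in mc:
        best, best_d = None, None
        for j, (_, o_peak, _) in enumerate(oc):
            if j in used:
                continue
            d = abs(m_peak - o_peak)
            if best_d is None or d < best_d:
                best, best_d = j, d
        if best is None:
            break
        used.add(best)
        sos_errors.append(m_sos - oc[best][2])
    amp_error = float(
        (np.max(model) - np.min(model)) - (np.max(observed) - np.min(observed))
    )
    return sos_errors, amp_error


def importance_correlates(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p-value between per-site quantities."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = pearsonr(x, y)
    return float(r), float(p)
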