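"""Exhaustive lagged-regression search with BIC selection.

Candidate models combine at most one soil-moisture term (log or log x MAP
transform) and one day-length term, each lagged by 0-10 steps on the 8-day
grid.  All candidates are fitted by pooled ordinary least squares across
sites and ranked by the Bayesian Information Criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from savphen.types import AlignedSeries, CandidateModel, TermSpec

__all__ = [
    "enumerate_models",
    "build_design",
    "fit_ols",
    "bic",
    "select_model",
    "predict_site",
    "SelectionResult",
]

#: rss at or below n_obs * this is treated as a numerically perfect fit
PERFECT_FIT_RSS_PER_OBS = 1e-16


def enumerate_models(max_lag: int = 10) -> list[tuple[TermSpec, ...]]:
    """All candidate term sets: each variable at most once.

    Count = T(L+1) + (L+1) + T(L+1)^2 with T = 2 soil-moisture transforms
    and L = ``max_lag`` (275 for L = 10).
    """
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    lags = range(max_lag + 1)
    sm_terms = [TermSpec("sm", tr, l) for tr in ("log", "log_map") for l in lags]
    dayl_terms = [TermSpec("dayl", "identity", l) for l in lags]
    combos: list[tuple[TermSpec, ...]] = []
    combos += [(s,) for s in sm_terms]
    combos += [(d,) for d in dayl_terms]
    combos += [(s, d) for s in sm_terms for d in dayl_terms]
    return combos


def _term_column(
    term: TermSpec, site: AlignedSeries, map_m_per_yr: float, max_lag: int
) -> np.ndarray:
    n = len(site)
    lo, hi = max_lag - term.lag, n - term.lag
    if term.variable == "sm":
        sm = site.sm[lo:hi]
        if (sm <= 0).any():
            step = lo + int(np.argmax(sm <= 0))
            raise ValueError(
                f"non-positive soil moisture under log transform at "
                f"{site.site_id} step {step}"
            )
        if term.transform == "log":
            return np.log(sm)
        return np.log(sm * map_m_per_yr)
    return site.dayl[lo:hi]


def build_design(
    sites: Sequence[AlignedSeries],
    map_by_site: Mapping[str, float],
    terms: Sequence[TermSpec],
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled response vector and regressor matrix for one candidate.

    Per site, row t pairs NDVI(t) with each term's transformed variable at
    t - lag; the first max-lag steps are dropped so lags never cross site
    boundaries.  Sites are stacked in the given order.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("candidate must contain at least one term")
    max_lag = max(t.lag for t in terms)
    ys, xs = [], []
    for site in sites:
        if len(site) <= max_lag:
            raise ValueError(
                f"site {site.site_id} shorter than the maximum lag {max_lag}"
            )
        cols = [
            _term_column(t, site, map_by_site[site.site_id], max_lag) for t in terms
        ]
        xs.append(np.column_stack(cols))
        ys.append(site.ndvi[max_lag:])
    return np.concatenate(ys), np.vstack(xs)


def fit_ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Ordinary least squares with intercept.

    Returns (coefficients, intercept, rss, r2) with
    r2 = 1 - rss / sum((y - mean(y))^2).  A rank-deficient design is an
    error — distinct from near-collinearity, which fits fine and is
    reported through VIF downstream.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per response value")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} rows, got {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design contains missing values")
    A = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        raise ValueError("rank-deficient design (perfectly collinear regressors)")
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return beta[1:], float(beta[0]), rss, r2


def bic(rss: float, n_obs: int, n_params: int) -> float:
    """Gaussian concentrated-likelihood BIC: n ln(rss/n) + p ln(n).

    ``n_params`` counts slope coefficients plus the intercept.  A
    (numerically) perfect fit returns -inf so it wins all comparisons;
    remaining ties are broken elsewhere by parsimony.
    """
    if n_obs <= n_params:
        raise ValueError("n_obs must exceed n_params")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss <= n_obs * PERFECT_FIT_RSS_PER_OBS:
        return float("-inf")
    return n_obs * float(np.log(rss / n_obs)) + n_params * float(np.log(n_obs))


def _fit_candidate(
    sites: Sequence[AlignedSeries],
    map_by_site: Mapping[str, float],
    terms: Sequence[TermSpec],
) -> CandidateModel:
    y, X = build_design(sites, map_by_site, terms)
    coef, intercept, rss, r2 = fit_ols(X, y)
    score = bic(rss, len(y), len(terms) + 1)
    return CandidateModel(tuple(terms), coef, intercept, rss, r2, score, len(y))


@dataclass
class SelectionResult:
    """Lowest-BIC model plus the full candidate ranking."""

    best: CandidateModel
    ranking: list[CandidateModel]

    def ranking_frame(self) -> pd.DataFrame:
        rows = [
            {
                "terms": " + ".join(t.label() for t in m.terms),
                "n_terms": len(m.terms),
                "total_lag": sum(t.lag for t in m.terms),
                "bic": m.bic,
                "r2": m.r2,
                "rss": m.rss,
            }
            for m in self.ranking
        ]
        return pd.DataFrame(rows)


def select_model(
    sites: Sequence[AlignedSeries],
    map_by_site: Mapping[str, float],
    max_lag: int = 10,
) -> SelectionResult:
    """Fit every enumerated candidate on the pooled design; lowest BIC wins.

    Ties are broken by fewer parameters, then by smaller total lag.
    """
    if not sites:
        raise ValueError("need at least one site")
    candidates = enumerate_models(max_lag)
    fitted = [_fit_candidate(sites, map_by_site, terms) for terms in candidates]
    fitted.sort(key=lambda m: (m.bic, m.n_params, sum(t.lag for t in m.terms)))
    return SelectionResult(best=fitted[0], ranking=fitted)


def predict_site(
    model: CandidateModel, site: AlignedSeries, map_m_per_yr: float
) -> pd.Series:
    """Predicted NDVI on the site's grid (first max-lag steps dropped)."""
    max_lag = model.max_lag
    if len(site) <= max_lag:
        raise ValueError(f"site {site.site_id} shorter than model lag {max_lag}")
    cols = [_term_column(t, site, map_m_per_yr, max_lag) for t in model.terms]
    yhat = model.intercept + np.column_stack(cols) @ model.coefficients
    return pd.Series(yhat, index=site.step_dates[max_lag:], name="ndvi_pred")
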