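"""Plain-text I/O: CSV site ensembles, aligned series, and JSON models."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from savphen.types import AlignedSeries, CandidateModel, SiteRecord, TermSpec

__all__ = [
    "write_ensemble",
    "read_sites",
    "write_aligned",
    "read_aligned",
    "model_to_json",
    "model_from_json",
]

METADATA_COLUMNS = [
    "site_id",
    "latitude",
    "map_m_per_yr",
    "tree_cover_pct",
    "aridity_index",
]


def write_ensemble(sites: Sequence[SiteRecord], out_dir) -> Path:
    """Write one metadata table plus per-site climate and NDVI CSVs."""
    out = Path(out_dir)
    (out / "climate").mkdir(parents=True, exist_ok=True)
    (out / "ndvi").mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "latitude": s.latitude,
                "map_m_per_yr": s.map_m_per_yr,
                "tree_cover_pct": s.tree_cover,
                "aridity_index": s.aridity_index,
            }
            for s in sites
        ]
    )
    meta.to_csv(out / "metadata.csv", index=False)
    for s in sites:
        climate = s.climate.copy()
        climate["date"] = pd.to_datetime(climate["date"]).dt.strftime("%Y-%m-%d")
        climate.to_csv(out / "climate" / f"{s.site_id}.csv", index=False)
        ndvi = s.ndvi.copy()
        ndvi["acq_date"] = pd.to_datetime(ndvi["acq_date"]).dt.strftime("%Y-%m-%d")
        ndvi.to_csv(out / "ndvi" / f"{s.site_id}.csv", index=False)
    return out


def read_sites(metadata_csv, climate_dir, ndvi_dir) -> list[SiteRecord]:
    """Load and validate a site ensemble from its CSV layout.

    Unit sanity is enforced per site: MAP must be plausible in m/year
    (< 10) and soil moisture in volumetric % (<= 100); violations raise an
    error naming the offending site.
    """
    meta_path = Path(metadata_csv)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    records = []
    for row in meta.itertuples(index=False):
        sid = str(row.site_id)
        climate_path = Path(climate_dir) / f"{sid}.csv"
        ndvi_path = Path(ndvi_dir) / f"{sid}.csv"
        for path in (climate_path, ndvi_path):
            if not path.exists():
                raise FileNotFoundError(f"site {sid}: missing file {path}")
        try:
            climate = pd.read_csv(climate_path, parse_dates=["date"])
            ndvi = pd.read_csv(ndvi_path, parse_dates=["acq_date"])
        except ValueError as exc:
            raise ValueError(f"site {sid}: unparsable series file: {exc}") from exc
        if climate.empty:
            raise ValueError(f"site {sid}: empty climate file {climate_path}")
        if ndvi.empty:
            raise ValueError(f"site {sid}: empty NDVI file {ndvi_path}")
        records.append(
            SiteRecord(
                site_id=sid,
                latitude=float(row.latitude),
                map_m_per_yr=float(row.map_m_per_yr),
                tree_cover=float(row.tree_cover_pct),
                aridity_index=float(row.aridity_index),
                climate=climate,
                ndvi=ndvi,
            )
        )
    return records


def write_aligned(aligned: Sequence[AlignedSeries], out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for a in aligned:
        frame = a.to_frame()
        frame["step_date"] = frame["step_date"].dt.strftime("%Y-%m-%d")
        frame.to_csv(out / f"{a.site_id}.csv", index=False)
    return out


def read_aligned(in_dir) -> list[AlignedSeries]:
    paths = sorted(Path(in_dir).glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no aligned series CSVs in {in_dir}")
    out = []
    for path in paths:
        frame = pd.read_csv(path, parse_dates=["step_date"])
        out.append(
            AlignedSeries(
                site_id=path.stem,
                step_dates=pd.DatetimeIndex(frame["step_date"]),
                ndvi=frame["ndvi_smooth"].to_numpy(),
                sm=frame["sm_med"].to_numpy(),
                dayl=frame["dayl_max"].to_numpy(),
            )
        )
    return out


def model_to_json(model: CandidateModel, path, ranking: pd.DataFrame | None = None) -> None:
    payload = {
        "equation": model.equation(),
        "terms": [
            {
                "variable": t.variable,
                "transform": t.transform,
                "lag": t.lag,
                "coefficient": float(c),
            }
            for t, c in zip(model.terms, model.coefficients)
        ],
        "intercept": model.intercept,
        "rss": model.rss,
        "r2": model.r2,
        "bic": model.bic if np.isfinite(model.bic) else None,
        "n_obs": model.n_obs,
    }
    if ranking is not None:
        payload["ranking"] = json.loads(
            ranking.replace([np.inf, -np.inf], None).to_json(orient="records")
        )
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def model_from_json(path) -> CandidateModel:
    payload = json.loads(Path(path).read_text())
    terms = tuple(
        TermSpec(t["variable"], t["transform"], int(t["lag"]))
        for t in payload["terms"]
    )
    coefs = np.array([t["coefficient"] for t in payload["terms"]])
    bic = payload["bic"] if payload["bic"] is not None else float("-inf")
    return CandidateModel(
        terms=terms,
        coefficients=coefs,
        intercept=float(payload["intercept"]),
        rss=float(payload["rss"]),
        r2=float(payload["r2"]),
        bic=float(bic),
        n_obs=int(payload["n_obs"]),
    )
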