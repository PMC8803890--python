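"""Readers and writers for the package's plain-text and cube formats.

Single series travel as two-column CSV (time, value; blank or NaN
fields mark missing samples).  Cubes use the NetCDF layout with
dimensions (lat, lon, time) through xarray's scipy backend.  Decision
records serialize to JSON, curves and lag scans to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .embedding import TimeSeries

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_cube",
    "write_cube",
    "decision_to_json",
    "curve_to_csv",
]


def read_series_csv(path: str | Path, name: str = "") -> TimeSeries:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    steps = np.diff(t)
    step = float(np.median(steps)) if steps.size else 1.0
    if steps.size and not np.allclose(steps, step, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column is not regularly sampled")
    return TimeSeries(v, step=step or 1.0, name=name or str(df.columns[1]))


def write_series_csv(series: TimeSeries, path: str | Path) -> None:
    t = np.arange(len(series)) * series.step
    v = series.values.copy()
    v[~series.mask] = np.nan
    pd.DataFrame({"time": t, series.name or "value": v}).to_csv(path, index=False)


def write_cube(dataset: xr.Dataset, path: str | Path) -> None:
    """NetCDF3 via the scipy backend (no external NetCDF library)."""
    dataset.to_netcdf(path, engine="scipy")


def read_cube(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def decision_to_json(record, path: str | Path | None = None) -> str:
    """Serialize any object exposing ``to_dict`` (or a dict) to JSON."""
    payload = record.to_dict() if hasattr(record, "to_dict") else record
    text = json.dumps(payload, indent=2, default=_np_default)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def curve_to_csv(result, path: str | Path) -> None:
    """One row per library size (CrossMapResult) or per lag (LagScanResult)."""
    if hasattr(result, "library_sizes") and hasattr(result, "skills"):
        df = pd.DataFrame(
            {"library_size": result.library_sizes, "skill": result.skills}
        )
    elif hasattr(result, "lags"):
        df = pd.DataFrame({"lag": result.lags, "skill": result.skill_at_lag})
    else:
        raise TypeError(f"cannot serialize {type(result).__name__} as a curve")
    df.to_csv(path, index=False)


def _np_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
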