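"""Pixel-wise orchestration of RCCM x IGCI over gridded datacubes, and
the derived map products: robust-skill maps, skill-difference maps,
dominance maps, embedding-dimension maps and stratified summaries.

Pixels are embarrassingly independent: each derives its own random
seed from the master seed and its coordinates, so any execution order
(or running one pixel alone) reproduces identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .config import RCCMConfig
from .embedding import TimeSeries
from .errors import ConfigError, InsufficientDataError, DegenerateDistributionError, AlignmentError
from .igci import MaskedDecision, igci_score, mask_rccm
from .robust import plan_windows, rccm_decide, select_dimension_shared
from .synthetic import SyntheticCube

__all__ = [
    "PixelResult",
    "PairRunResult",
    "DominanceMap",
    "run_pair",
    "analyze_pair",
    "dominance_map",
    "skill_difference_map",
    "stratified_summary",
    "regime_labels",
]

#: integer codes for the per-direction final state in map products
FINAL_CODES = {"no_link": 0, "kept": 1, "masked": 2, "rejected_by_lag": 3}
SKIP_CODE = -1


@dataclass
class PixelResult:
    """Per-pixel record: both directions of one ordered variable pair."""

    row: int
    col: int
    forward: MaskedDecision | None  # A -> B
    backward: MaskedDecision | None  # B -> A
    selected_dimension: int | None
    skipped: bool = False
    reason: str = ""


def analyze_pair(
    series_a: TimeSeries,
    series_b: TimeSeries,
    config: RCCMConfig | None = None,
    seed: int = 0,
) -> tuple[MaskedDecision, MaskedDecision, int]:
    """Both causal directions of one series pair: RCCM decisions under
    a (by default) shared embedding dimension, one IGCI score, and the
    entropy mask applied to each direction.  Returns (A->B, B->A,
    selected dimension)."""
    config = config or RCCMConfig()
    plan = plan_windows(
        len(series_a), config.year_length, config.n_runs, config.min_valid_run
    )
    if config.share_dimension:
        dim, _ = select_dimension_shared(
            series_a, series_b, plan, config.dim_range, config, seed
        )
    else:
        dim = None
    fwd = rccm_decide(series_a, series_b, config, seed=seed, plan=plan, dimension=dim)
    bwd = rccm_decide(
        series_b, series_a, config, seed=seed + 1, plan=plan, dimension=dim
    )
    keep = series_a.mask & series_b.mask
    names = (series_a.name or "A", series_b.name or "B")
    ig = igci_score(
        series_a.values[keep], series_b.values[keep], config.epsilon, names
    )
    return mask_rccm(fwd, ig), mask_rccm(bwd, ig), fwd.selected_dimension


@dataclass
class PairRunResult:
    """Gridded outputs of :func:`run_pair` plus the per-pixel records."""

    maps: xr.Dataset
    pixels: list[PixelResult] = field(repr=False, default_factory=list)

    @property
    def n_skipped(self) -> int:
        return sum(p.skipped for p in self.pixels)


def _pixel_series(cube: xr.Dataset, var: str, i: int, j: int) -> TimeSeries:
    vals = np.asarray(cube[var].isel(lat=i, lon=j).values, dtype=float)
    return TimeSeries(vals, name=var)


def run_pair(
    cube: xr.Dataset | SyntheticCube,
    var_a: str,
    var_b: str,
    config: RCCMConfig | None = None,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> PairRunResult:
    """Run RCCM x IGCI for the ordered pair (var_a, var_b) on every
    unmasked pixel of a (lat, lon, time) cube.

    Pixels under ``mask`` (True = excluded) or with fewer valid samples
    than the configured minimum are skipped with a reason, never
    errored.  Every input pixel is accounted for in the output grids.
    """
    if isinstance(cube, SyntheticCube):
        cube = cube.dataset
    config = config or RCCMConfig()
    for var in (var_a, var_b):
        if var not in cube:
            raise ConfigError(f"variable {var!r} not present in the cube")
    if cube[var_a].dims != cube[var_b].dims:
        raise ConfigError("paired variables must share the (lat, lon, time) grid")
    ny = cube.sizes["lat"]
    nx = cube.sizes["lon"]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ny, nx):
            raise ConfigError(f"pixel mask shape {mask.shape} != grid {(ny, nx)}")

    shape = (ny, nx)
    skill_ab = np.full(shape, np.nan)
    skill_ba = np.full(shape, np.nan)
    lag_ab = np.full(shape, np.nan)
    lag_ba = np.full(shape, np.nan)
    dim_map = np.full(shape, np.nan)
    final_ab = np.full(shape, SKIP_CODE, dtype=int)
    final_ba = np.full(shape, SKIP_CODE, dtype=int)
    pixels: list[PixelResult] = []

    for i in range(ny):
        for j in range(nx):
            if mask is not None and mask[i, j]:
                pixels.append(PixelResult(i, j, None, None, None, True, "masked"))
                continue
            sa = _pixel_series(cube, var_a, i, j)
            sb = _pixel_series(cube, var_b, i, j)
            if min(sa.n_valid, sb.n_valid) < config.min_valid_run:
                pixels.append(
                    PixelResult(i, j, None, None, None, True, "insufficient_data")
                )
                continue
            pseed = int(
                np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % (2**31)
            )
            try:
                fwd, bwd, dim = analyze_pair(sa, sb, config, pseed)
            except (InsufficientDataError, AlignmentError, DegenerateDistributionError) as exc:
                pixels.append(
                    PixelResult(i, j, None, None, None, True, f"failed: {exc}")
                )
                continue
            pixels.append(PixelResult(i, j, fwd, bwd, dim))
            skill_ab[i, j] = fwd.rccm.robust_skill
            skill_ba[i, j] = bwd.rccm.robust_skill
            lag_ab[i, j] = fwd.rccm.optimal_lag
            lag_ba[i, j] = bwd.rccm.optimal_lag
            dim_map[i, j] = dim
            final_ab[i, j] = FINAL_CODES[fwd.final]
            final_ba[i, j] = FINAL_CODES[bwd.final]

    coords = {"lat": cube["lat"].values, "lon": cube["lon"].values}
    maps = xr.Dataset(
        {
            "skill_ab": (("lat", "lon"), skill_ab),
            "skill_ba": (("lat", "lon"), skill_ba),
            "lag_ab": (("lat", "lon"), lag_ab),
            "lag_ba": (("lat", "lon"), lag_ba),
            "dimension": (("lat", "lon"), dim_map),
            "final_ab": (("lat", "lon"), final_ab),
            "final_ba": (("lat", "lon"), final_ba),
        },
        coords=coords,
        attrs={
            "pair": f"{var_a},{var_b}",
            "final_codes": str(FINAL_CODES),
            "skip_code": SKIP_CODE,
            "seed": seed,
        },
    )
    return PairRunResult(maps, pixels)


def regime_labels(result: PairRunResult) -> np.ndarray:
    """Classify each pixel from its two final states: 0 independent,
    1 A drives B, 2 B drives A, 3 bidirectional, -1 skipped."""
    ab = result.maps["final_ab"].values
    ba = result.maps["final_ba"].values
    out = np.full(ab.shape, SKIP_CODE, dtype=int)
    ok = (ab != SKIP_CODE) & (ba != SKIP_CODE)
    kept_ab = ab == FINAL_CODES["kept"]
    kept_ba = ba == FINAL_CODES["kept"]
    out[ok] = 0
    out[ok & kept_ab & ~kept_ba] = 1
    out[ok & ~kept_ab & kept_ba] = 2
    out[ok & kept_ab & kept_ba] = 3
    return out


@dataclass
class DominanceMap:
    """Which of two drivers forces a target, pixel by pixel."""

    labels: np.ndarray  # codes of LABELS
    high: float
    low: float

    LABELS = {"none": 0, "driver1": 1, "driver2": 2, "joint": 3, "masked": -1}


def dominance_map(
    skill_driver1: np.ndarray | xr.DataArray,
    skill_driver2: np.ndarray | xr.DataArray,
    high: float = 0.9,
    low: float = 0.4,
) -> DominanceMap:
    """Threshold two robust-skill maps into a dominance classification.

    driver1 dominates where its skill exceeds ``high`` while driver2
    stays below ``low`` (and symmetrically); both above ``high`` is
    joint forcing; anything else is unclassified.  Pixels lacking
    either skill propagate as masked.
    """
    if high <= low:
        raise ConfigError(f"high threshold {high} must exceed low threshold {low}")
    s1 = np.asarray(skill_driver1, dtype=float)
    s2 = np.asarray(skill_driver2, dtype=float)
    if s1.shape != s2.shape:
        raise ConfigError(f"skill grids misaligned: {s1.shape} vs {s2.shape}")
    labels = np.zeros(s1.shape, dtype=int)
    valid = np.isfinite(s1) & np.isfinite(s2)
    labels[~valid] = DominanceMap.LABELS["masked"]
    labels[valid & (s1 > high) & (s2 < low)] = DominanceMap.LABELS["driver1"]
    labels[valid & (s2 > high) & (s1 < low)] = DominanceMap.LABELS["driver2"]
    labels[valid & (s1 > high) & (s2 > high)] = DominanceMap.LABELS["joint"]
    return DominanceMap(labels, high, low)


def skill_difference_map(
    skill_ab: np.ndarray | xr.DataArray, skill_ba: np.ndarray | xr.DataArray
) -> np.ndarray:
    """Signed per-pixel difference rho(A->B) - rho(B->A); positive
    values mean A's forcing of B dominates.  NaNs propagate."""
    a = np.asarray(skill_ab, dtype=float)
    b = np.asarray(skill_ba, dtype=float)
    if a.shape != b.shape:
        raise ConfigError(f"skill grids misaligned: {a.shape} vs {b.shape}")
    return a - b


def stratified_summary(
    values: np.ndarray | xr.DataArray,
    strata: np.ndarray,
    bins: int = 10,
) -> tuple[pd.DataFrame, dict[int, tuple[np.ndarray, np.ndarray]]]:
    """Per-stratum distribution summary of a per-pixel scalar.

    Returns a frame indexed by stratum code with count, median and
    quartiles, plus a per-stratum (counts, bin_edges) histogram dict.
    Empty strata are reported with count 0.  NaN pixels are excluded
    from the statistics but not from stratum membership counts.
    """
    v = np.asarray(values, dtype=float).ravel()
    s = np.asarray(strata).ravel()
    if v.size != s.size:
        raise ConfigError(f"values ({v.size}) and strata ({s.size}) misaligned")
    rows = []
    hists: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for code in np.unique(s):
        sel = v[(s == code) & np.isfinite(v)]
        if sel.size:
            q1, med, q3 = np.percentile(sel, [25, 50, 75])
            counts, edges = np.histogram(sel, bins=bins)
        else:
            q1 = med = q3 = np.nan
            counts, edges = np.zeros(bins, dtype=int), np.linspace(0, 1, bins + 1)
        rows.append(
            {"stratum": code, "count": sel.size, "median": med, "q1": q1, "q3": q3}
        )
        hists[code] = (counts, edges)
    return pd.DataFrame(rows).set_index("stratum"), hists
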