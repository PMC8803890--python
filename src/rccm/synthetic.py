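"""Synthetic benchmark systems: coupled logistic maps, planted-lag
pairs, and small gridded datacubes with known per-pixel causal regimes.

The coupled logistic map

    x_{t+1} = x_t (r_x (1 - x_t) - b_xy y_t)
    y_{t+1} = y_t (r_y (1 - y_t) - b_yx x_t)

is the standard cross-mapping benchmark: with r_x = 3.8 the driver is
chaotic, with r_y = 3.5 the response sits on a period-4 attractor that
becomes increasingly chaotic as the coupling b_yx grows.  Observation
noise is added to the emitted copies only, so the latent attractor is
untouched (a noise-free cause can drive a noisily observed effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .embedding import TimeSeries
from .errors import ConfigError, DivergenceError

__all__ = [
    "LogisticMapParams",
    "coupled_logistic_map",
    "planted_lag_system",
    "SyntheticCube",
    "synthetic_datacube",
    "REGIME_CODES",
    "REGIME_NAMES",
]


@dataclass(frozen=True)
class LogisticMapParams:
    """Parameters of the coupled logistic map benchmark.

    ``beta_yx`` is the forcing of X on Y (the coupling under study);
    ``beta_xy`` the back-coupling of Y on X.  ``sigma_x``/``sigma_y``
    are observation-noise standard deviations on the emitted copies.
    """

    r_x: float = 3.8
    r_y: float = 3.5
    beta_xy: float = 0.0
    beta_yx: float = 0.1
    sigma_x: float = 0.0
    sigma_y: float = 0.0
    n_samples: int = 1000
    burn_in: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.r_x, self.r_y):
            if not 0 < r <= 4:
                raise ConfigError(f"growth rate must lie in (0, 4], got {r}")
        if self.beta_xy < 0 or self.beta_yx < 0:
            raise ConfigError("couplings must be non-negative")
        if self.n_samples < 1 or self.burn_in < 0:
            raise ConfigError("n_samples >= 1 and burn_in >= 0 required")


def coupled_logistic_map(
    params: LogisticMapParams,
    x0: float | None = None,
    y0: float | None = None,
) -> tuple[TimeSeries, TimeSeries]:
    """Iterate the coupled map and emit noisy copies as two series.

    Initial conditions default to independent draws from U(0.2, 0.8).
    Raises :class:`DivergenceError` (naming the step) if the latent
    trajectory leaves [0, 1].
    """
    rng = np.random.default_rng(params.seed)
    if x0 is None:
        x0 = float(rng.uniform(0.2, 0.8))
    if y0 is None:
        y0 = float(rng.uniform(0.2, 0.8))
    if not (0 <= x0 <= 1 and 0 <= y0 <= 1):
        raise ConfigError(f"initial conditions must lie in [0,1], got {x0}, {y0}")

    total = params.burn_in + params.n_samples
    x = np.empty(total + 1)
    y = np.empty(total + 1)
    x[0], y[0] = x0, y0
    for t in range(total):
        x[t + 1] = x[t] * (params.r_x * (1.0 - x[t]) - params.beta_xy * y[t])
        y[t + 1] = y[t] * (params.r_y * (1.0 - y[t]) - params.beta_yx * x[t])
        if not (0.0 <= x[t + 1] <= 1.0 and 0.0 <= y[t + 1] <= 1.0):
            raise DivergenceError(
                f"trajectory left [0,1] at step {t + 1}: "
                f"x={x[t + 1]:.4g}, y={y[t + 1]:.4g}"
            )
    xs = x[params.burn_in : params.burn_in + params.n_samples]
    ys = y[params.burn_in : params.burn_in + params.n_samples]
    if params.sigma_x > 0:
        xs = xs + rng.normal(0.0, params.sigma_x, xs.size)
    if params.sigma_y > 0:
        ys = ys + rng.normal(0.0, params.sigma_y, ys.size)
    return TimeSeries(xs, name="X"), TimeSeries(ys, name="Y")


def _default_monotone(x: np.ndarray) -> np.ndarray:
    return x**2


def planted_lag_system(
    lag: int,
    noise: float = 0.0,
    n: int = 1000,
    seed: int = 0,
    r: float = 3.8,
    g=_default_monotone,
    burn_in: int = 300,
) -> tuple[TimeSeries, TimeSeries]:
    """Pair with a planted delay: Y(t) = g(X(t - lag)) + noise.

    X is a chaotic logistic map; ``g`` a fixed smooth strictly monotone
    map (default x -> x^2 on [0,1]).  The ground-truth optimal
    cross-map lag for the claim X -> Y is ``-lag`` under the convention
    that negative lags mean the cause precedes the effect.
    """
    if lag < 0:
        raise ConfigError(f"planted lag must be >= 0, got {lag}")
    if lag >= n:
        raise ConfigError(f"planted lag {lag} must be smaller than n={n}")
    params = LogisticMapParams(
        r_x=r, beta_xy=0.0, beta_yx=0.0, n_samples=n + lag, burn_in=burn_in, seed=seed
    )
    x_full, _ = coupled_logistic_map(params)
    xv = x_full.values
    yv = g(xv[: n]) if lag == 0 else g(xv[: -lag])
    yv = np.asarray(yv, dtype=float)[:n]
    xv = xv[lag : lag + n]
    if noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        yv = yv + rng.normal(0.0, noise, yv.size)
    return TimeSeries(xv, name="X"), TimeSeries(yv, name="Y")


# planted causal regimes of the datacube
REGIME_CODES = {"independent": 0, "a_drives_b": 1, "b_drives_a": 2, "bidirectional": 3}
REGIME_NAMES = {v: k for k, v in REGIME_CODES.items()}

# per-regime map parameters, chosen so the regimes are dynamically
# distinct: unidirectional forcing strong enough to imprint the driver
# on the response, symmetric moderate coupling for the bidirectional
# regime, detuned growth rates for independence
_REGIME_PARAMS = {
    "independent": dict(r_x=3.8, r_y=3.7, beta_xy=0.0, beta_yx=0.0),
    "a_drives_b": dict(r_x=3.8, r_y=3.5, beta_xy=0.0, beta_yx=0.3),
    "b_drives_a": dict(r_x=3.5, r_y=3.8, beta_xy=0.3, beta_yx=0.0),
    "bidirectional": dict(r_x=3.78, r_y=3.72, beta_xy=0.2, beta_yx=0.2),
}


@dataclass
class SyntheticCube:
    """Thin wrapper pairing the generated dataset with its truth map."""

    dataset: xr.Dataset

    @property
    def regime_map(self) -> np.ndarray:
        return self.dataset["regime_map"].values

    def __getitem__(self, name: str) -> xr.DataArray:
        return self.dataset[name]


def _quadrant_layout(ny: int, nx: int) -> np.ndarray:
    reg = np.zeros((ny, nx), dtype=int)
    reg[: ny // 2, nx // 2 :] = 1
    reg[ny // 2 :, : nx // 2] = 2
    reg[ny // 2 :, nx // 2 :] = 3
    return reg


def synthetic_datacube(
    shape: tuple[int, int] = (8, 8),
    n_years: int = 11,
    samples_per_year: int = 46,
    regime_layout: str | np.ndarray = "quadrants",
    seed: int = 0,
    seasonal_amplitude: float = 0.05,
    observation_noise: float = 0.01,
    missing_stripes: int = 0,
    var_names: tuple[str, str] = ("A", "B"),
) -> SyntheticCube:
    """Gridded two-variable datacube with planted per-pixel regimes.

    Each pixel holds an independent coupled-logistic simulation whose
    coupling structure is set by the regime map (``"quadrants"``, an
    integer array of regime codes, or a single regime name).  A shared
    sinusoidal seasonal cycle with period ``samples_per_year`` mimics
    the strong periodicity of land-surface fluxes; optional missing
    stripes blank out whole sampling intervals cube-wide.  Row 0 is the
    northernmost latitude; the time axis is a regular sample index.
    """
    ny, nx = shape
    if ny > 32 or nx > 32:
        raise ConfigError("datacube generator is desk-scale: grid at most 32 x 32")
    nt = n_years * samples_per_year
    if isinstance(regime_layout, str):
        if regime_layout == "quadrants":
            regimes = _quadrant_layout(ny, nx)
        elif regime_layout in REGIME_CODES:
            regimes = np.full((ny, nx), REGIME_CODES[regime_layout], dtype=int)
        else:
            raise ConfigError(f"unknown regime layout {regime_layout!r}")
    else:
        regimes = np.asarray(regime_layout, dtype=int)
        if regimes.shape != (ny, nx):
            raise ConfigError(f"regime map shape {regimes.shape} != grid {shape}")
        if not np.isin(regimes, list(REGIME_NAMES)).all():
            raise ConfigError(f"unknown regime codes in layout: {np.unique(regimes)}")

    season = seasonal_amplitude * np.sin(
        2.0 * np.pi * np.arange(nt) / samples_per_year
    )
    a = np.empty((ny, nx, nt))
    b = np.empty((ny, nx, nt))
    for i in range(ny):
        for j in range(nx):
            pseed = int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % (2**31))
            kw = _REGIME_PARAMS[REGIME_NAMES[int(regimes[i, j])]]
            params = LogisticMapParams(
                n_samples=nt,
                burn_in=300,
                seed=pseed,
                sigma_x=observation_noise,
                sigma_y=observation_noise,
                **kw,
            )
            xa, xb = coupled_logistic_map(params)
            a[i, j] = xa.values + season
            b[i, j] = xb.values + season

    if missing_stripes:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
        for t in rng.choice(nt, size=missing_stripes, replace=False):
            a[:, :, t] = np.nan
            b[:, :, t] = np.nan

    coords = {
        "lat": np.arange(ny)[::-1].astype(float),  # row 0 = northernmost
        "lon": np.arange(nx, dtype=float),
        "time": np.arange(nt),
    }
    ds = xr.Dataset(
        {
            var_names[0]: (("lat", "lon", "time"), a),
            var_names[1]: (("lat", "lon", "time"), b),
            "regime_map": (("lat", "lon"), regimes),
        },
        coords=coords,
        attrs={
            "samples_per_year": samples_per_year,
            "n_years": n_years,
            "regime_codes": str(REGIME_CODES),
            "fill_value": "nan",
            "seed": seed,
        },
    )
    for name in var_names:
        ds[name].attrs["_FillValue_decl"] = np.nan
    return SyntheticCube(ds)
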