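"""Pipeline configuration: one flat record of every tunable default."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["RCCMConfig", "load_config"]


@dataclass
class RCCMConfig:
    """Defaults of the robust cross-mapping pipeline.

    Attributes
    ----------
    dim_min, dim_max
        Inclusive search range for the embedding dimension p.
    delay
        Spacing tau between lagged coordinates, in samples.
    lag_min, lag_max
        Inclusive grid of cross-map alignment lags t_p, in samples
        (31 lags by default; negative = cause precedes effect).
    n_runs
        Bootstrap windows through time (N).
    year_length
        Samples per year of the input grid (46 for 8-day sampling).
    min_valid_run
        Minimum valid samples a window must contain; also sets the
        whole-year window length.
    n_library_sizes
        Points on the logarithmic library-size grid.
    n_resamples
        Library resamples per size within each window.
    skill_threshold
        Robust skill rho-tilde a link must reach to count as convergent
        (map products use 0.8).
    epsilon
        IGCI decision threshold on the entropy difference, in nats.
    min_overlap
        Minimum aligned pairs for a lag to be feasible.
    share_dimension
        Select one embedding dimension per pixel shared by both
        directions (pixel-wise dimension maps), or per direction.
    """

    dim_min: int = 1
    dim_max: int = 10
    delay: int = 1
    lag_min: int = -15
    lag_max: int = 15
    n_runs: int = 10
    year_length: int = 46
    min_valid_run: int = 400
    n_library_sizes: int = 8
    n_resamples: int = 5
    skill_threshold: float = 0.8
    epsilon: float = 0.2
    min_overlap: int = 50
    share_dimension: bool = True

    def __post_init__(self) -> None:
        if self.dim_min < 1 or self.dim_max < self.dim_min:
            raise ConfigError(f"bad dimension range {self.dim_min}..{self.dim_max}")
        if self.lag_max < self.lag_min:
            raise ConfigError(f"bad lag range {self.lag_min}..{self.lag_max}")
        if self.n_runs < 1 or self.year_length < 1 or self.min_valid_run < 3:
            raise ConfigError("n_runs, year_length, min_valid_run must be positive")

    @property
    def dim_range(self) -> range:
        return range(self.dim_min, self.dim_max + 1)

    @property
    def lags(self) -> range:
        return range(self.lag_min, self.lag_max + 1)

    def replace(self, **kw) -> "RCCMConfig":
        return replace(self, **kw)


def load_config(path: str | Path) -> RCCMConfig:
    """Read a flat key: value YAML/JSON file; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a flat mapping")
    known = {f.name for f in fields(RCCMConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RCCMConfig(**raw)
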