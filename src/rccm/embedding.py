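"""State-space reconstruction and simplex cross-map prediction.

A scalar series sampled on a regular grid is turned into a *shadow
manifold* of delay-coordinate vectors (Takens reconstruction).  Points
on one variable's manifold are then used to predict the other variable
with the simplex estimator: an exponentially weighted average over the
E+1 nearest library neighbours.  The Pearson correlation between the
cross-mapped estimate and the observed values is the cross-map skill
rho, the basic quantity of convergent cross-mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import AlignmentError, InsufficientDataError

__all__ = [
    "TimeSeries",
    "EmbeddingConfig",
    "ShadowManifold",
    "SimplexResult",
    "delay_embed",
    "simplex_cross_map",
    "cross_map_skill",
]


@dataclass
class TimeSeries:
    """A regularly sampled scalar series with a per-sample validity mask.

    Parameters
    ----------
    values
        Sample values.  Non-finite entries are treated as missing.
    step
        Sampling interval in arbitrary time units (must be positive).
    mask
        Optional boolean validity flags, ``True`` = valid.  Combined
        with the finiteness of ``values``.
    name
        Variable name used in direction labels and serialized records.
    """

    values: np.ndarray
    step: float = 1.0
    mask: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("TimeSeries requires a 1-D sequence of length >= 1")
        if not self.step > 0:
            raise ValueError(f"sampling step must be positive, got {self.step}")
        finite = np.isfinite(self.values)
        if self.mask is None:
            self.mask = finite
        else:
            self.mask = np.asarray(self.mask, dtype=bool).ravel()
            if self.mask.size != self.values.size:
                raise ValueError(
                    f"mask length {self.mask.size} != values length {self.values.size}"
                )
            self.mask = self.mask & finite

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def slice(self, start: int, stop: int) -> "TimeSeries":
        """Sub-series over sample indices [start, stop)."""
        return TimeSeries(
            self.values[start:stop], self.step, self.mask[start:stop], self.name
        )

    def zscore(self) -> "TimeSeries":
        """Standardize using valid samples; constant series pass through."""
        v = self.values[self.mask]
        mu = float(v.mean()) if v.size else 0.0
        sd = float(v.std()) if v.size else 0.0
        out = self.values.copy()
        if sd > 0:
            out = (out - mu) / sd
        else:
            out = out - mu
        return TimeSeries(out, self.step, self.mask.copy(), self.name)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding hyperparameters.

    ``dimension`` is the embedding dimension p (the toy benchmark calls
    it m), ``delay`` the spacing tau in samples between lagged
    coordinates, and ``cross_map_lag`` the alignment t_p applied when
    cross-mapping (negative = cause precedes effect).
    """

    dimension: int = 2
    delay: int = 1
    cross_map_lag: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError(f"dimension must be >= 1, got {self.dimension}")
        if self.delay < 1:
            raise ValueError(f"delay must be >= 1, got {self.delay}")


@dataclass
class ShadowManifold:
    """Delay-coordinate reconstruction of a series.

    ``points[i]`` is the vector ``(x_t, x_{t-tau}, ..., x_{t-(E-1)tau})``
    for ``t = point_times[i]`` (0-based index of the most recent
    coordinate).  Vectors touching any invalid sample are dropped.
    """

    points: np.ndarray
    point_times: np.ndarray
    source_length: int
    config: EmbeddingConfig = field(default_factory=EmbeddingConfig)

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def dimension(self) -> int:
        return int(self.points.shape[1])


def delay_embed(series: TimeSeries, config: EmbeddingConfig) -> ShadowManifold:
    """Build the shadow manifold of ``series`` under ``config``.

    Raises
    ------
    InsufficientDataError
        If no complete lagged vector can be formed; the message names
        the minimum span of consecutive valid samples required.
    """
    e, tau = config.dimension, config.delay
    span = (e - 1) * tau + 1
    n = len(series)
    if n < span:
        raise InsufficientDataError(
            f"series of length {n} too short for dimension {e}, delay {tau}: "
            f"needs at least {span} consecutive valid samples"
        )
    t = np.arange((e - 1) * tau, n)
    idx = t[:, None] - np.arange(e)[None, :] * tau
    complete = series.mask[idx].all(axis=1)
    if not complete.any():
        raise InsufficientDataError(
            f"no run of {span} consecutive valid samples: cannot embed with "
            f"dimension {e}, delay {tau}"
        )
    t = t[complete]
    return ShadowManifold(series.values[idx[complete]], t, n, config)


@dataclass
class SimplexResult:
    """Aligned cross-map predictions for a set of query points."""

    predicted: np.ndarray
    observed: np.ndarray
    times: np.ndarray  # manifold time of each query point


def _valid_target_times(target: TimeSeries, times: np.ndarray, lag: int) -> np.ndarray:
    shifted = times + lag
    ok = (shifted >= 0) & (shifted < len(target))
    ok[ok] &= target.mask[shifted[ok]]
    return ok


def _neighbor_weights(
    manifold: ShadowManifold,
    lib: np.ndarray,
    qry: np.ndarray,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-library-neighbour times and simplex weights per query.

    Returns ``(times, weights)``, each of shape (n_queries, k): the
    manifold times of the k nearest library neighbours (self excluded)
    and their normalized exponential weights.
    """
    tree = cKDTree(manifold.points[lib])
    kq = min(k + 1, lib.size)
    dist, nn = tree.query(manifold.points[qry], k=kq)
    dist = np.atleast_2d(dist)
    nn = np.atleast_2d(nn)
    nn_global = lib[nn]

    d = dist.copy()
    d[nn_global == qry[:, None]] = np.inf  # exclude the query point itself
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    dsel = np.take_along_axis(d, order, axis=1)
    if not np.isfinite(dsel).all():
        bad = int(np.isfinite(dsel).all(axis=1).argmin())
        raise InsufficientDataError(
            f"fewer than {k} usable neighbours for query {qry[bad]}"
        )
    nsel = np.take_along_axis(nn_global, order, axis=1)

    d1 = dsel[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d1 > 0.0, np.exp(-dsel / np.where(d1 > 0, d1, 1.0)), dsel == 0.0)
    w = w / w.sum(axis=1, keepdims=True)
    return manifold.point_times[nsel], w


def simplex_cross_map(
    target: TimeSeries,
    manifold: ShadowManifold,
    lag: int = 0,
    library_indices: np.ndarray | None = None,
    query_indices: np.ndarray | None = None,
    n_neighbors: int | None = None,
) -> SimplexResult:
    """Predict ``target`` from ``manifold`` with the simplex estimator.

    For each query point at manifold time t the E+1 nearest library
    neighbours (self excluded) are found; the prediction of
    ``target[t + lag]`` is the weighted mean of ``target[s_i + lag]``
    over neighbour times s_i with weights ``u_i / sum u_j``,
    ``u_i = exp(-d_i / d_1)`` and d_1 the nearest-neighbour distance.
    Exact ties at distance zero share equal weight.
    """
    k = int(n_neighbors) if n_neighbors is not None else manifold.dimension + 1
    all_idx = np.arange(len(manifold))
    lib = all_idx if library_indices is None else np.asarray(library_indices, dtype=int)
    qry = all_idx if query_indices is None else np.asarray(query_indices, dtype=int)

    # library points must map to a valid target value under the lag
    lib = lib[_valid_target_times(target, manifold.point_times[lib], lag)]
    qry = qry[_valid_target_times(target, manifold.point_times[qry], lag)]
    if qry.size == 0:
        raise AlignmentError(
            f"no query points align with the target under lag {lag}"
        )
    lib_set = set(lib.tolist())
    self_overlap = any(int(q) in lib_set for q in qry)
    needed = k + 1 if self_overlap else k
    if lib.size < needed:
        raise InsufficientDataError(
            f"library of {lib.size} points is smaller than the {needed} required "
            f"for {k}-neighbour simplex prediction"
        )

    times, w = _neighbor_weights(manifold, lib, qry, k)
    pred = (target.values[times + lag] * w).sum(axis=1)
    obs = target.values[manifold.point_times[qry] + lag]
    return SimplexResult(pred, obs, manifold.point_times[qry])


def cross_map_skill(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation between prediction and observation.

    Defined as 0.0 when either side has zero variance.  Requires at
    least 3 aligned pairs.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if p.size != o.size:
        raise ValueError(f"length mismatch: {p.size} vs {o.size}")
    if p.size < 3:
        raise InsufficientDataError(
            f"cross-map skill needs >= 3 aligned pairs, got {p.size}"
        )
    if p.std() == 0.0 or o.std() == 0.0:
        return 0.0
    return float(np.corrcoef(p, o)[0, 1])
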