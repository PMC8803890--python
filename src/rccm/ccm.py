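"""Standard and extended (lagged) convergent cross-mapping.

Direction X -> Y ("X causes Y") is tested by cross-mapping X from Y's
shadow manifold: if X forces Y, the history of Y encodes X, and the
skill of the cross-mapped estimate converges upward as the library of
manifold points grows.  The extended variant scans a grid of alignment
lags t_p; a best lag t_p > 0 (effect preceding cause) rejects the
causal claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .embedding import (
    EmbeddingConfig,
    TimeSeries,
    cross_map_skill,
    delay_embed,
    simplex_cross_map,
    _neighbor_weights,
    _valid_target_times,
)
from .errors import AlignmentError, InsufficientDataError

__all__ = [
    "CrossMapResult",
    "LagScanResult",
    "LagAcceptance",
    "default_library_sizes",
    "ccm_curve",
    "lag_scan",
    "accept_by_lag",
]

#: lag grid of the extended scan: -15 .. +15 samples, 31 lags
DEFAULT_LAGS = tuple(range(-15, 16))


@dataclass
class CrossMapResult:
    """Cross-map skill as a function of library size for one direction."""

    direction: tuple[str, str]  # (cause, effect): cause mapped from effect's manifold
    library_sizes: np.ndarray
    skills: np.ndarray
    lag: int = 0

    @property
    def terminal_skill(self) -> float:
        return float(self.skills[-1])


@dataclass
class LagScanResult:
    """Skill at the maximal library for each alignment lag."""

    direction: tuple[str, str]
    lags: np.ndarray
    skill_at_lag: np.ndarray  # NaN where the lag was infeasible
    optimal_lag: int

    @property
    def optimal_skill(self) -> float:
        return float(np.nanmax(self.skill_at_lag))


@dataclass
class LagAcceptance:
    """Outcome of the positive-lag rejection rule."""

    accepted: bool
    optimal_lag: int
    instantaneous: bool = False
    reason: str = ""


def default_library_sizes(max_size: int, dimension: int, n_sizes: int = 8) -> np.ndarray:
    """Logarithmically spaced library sizes from 10*p to ``max_size``."""
    lo = 10 * dimension
    if lo >= max_size:
        return np.array([max_size], dtype=int)
    sizes = np.unique(np.round(np.geomspace(lo, max_size, n_sizes)).astype(int))
    return sizes


def _split_pools(
    manifold, train_length: int | None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Library/query manifold-index pools for a train/test split at
    ``train_length`` samples (library from the training part, queries
    from the rest); both ``None`` -> full in-sample pools."""
    if train_length is None:
        return np.arange(len(manifold)), None
    in_train = manifold.point_times < train_length
    return np.flatnonzero(in_train), np.flatnonzero(~in_train)


def ccm_curve(
    cause: TimeSeries,
    effect: TimeSeries,
    config: EmbeddingConfig,
    library_sizes: np.ndarray | str | None = None,
    rng: np.random.Generator | int | None = None,
    n_resamples: int = 20,
    policy: str = "contiguous",
    train_length: int | None = None,
    strict: bool = False,
) -> CrossMapResult:
    """Convergence curve: skill of cross-mapping ``cause`` from
    ``effect``'s shadow manifold at each library size.

    Libraries are random contiguous blocks (or random subsets with
    ``policy="subset"``) of the library pool, resampled ``n_resamples``
    times per size with the mean skill reported.  With ``train_length``
    set, the library pool is restricted to manifold points from the
    first ``train_length`` samples and skill is evaluated on the
    remaining (test) points; otherwise prediction is in-sample over the
    full manifold.  Both series are z-scored internally so the
    Euclidean neighbour search is unit-free.
    """
    rng = np.random.default_rng(rng)
    cz, ez = cause.zscore(), effect.zscore()
    manifold = delay_embed(ez, config)
    lag = config.cross_map_lag
    pool, queries = _split_pools(manifold, train_length)
    if pool.size == 0:
        raise InsufficientDataError("empty library pool after train/test split")

    if library_sizes is None:
        library_sizes = default_library_sizes(pool.size, config.dimension)
    elif isinstance(library_sizes, str):
        if library_sizes != "full":
            raise ValueError(f"unknown library_sizes option {library_sizes!r}")
        library_sizes = np.array([pool.size], dtype=int)
    sizes = np.asarray(library_sizes, dtype=int)
    if (sizes <= 0).any() or (np.diff(sizes) <= 0).any():
        raise ValueError("library_sizes must be strictly increasing and positive")
    if sizes[-1] > pool.size:
        if strict:
            raise InsufficientDataError(
                f"library size {sizes[-1]} exceeds the {pool.size} available points"
            )
        warnings.warn(
            f"clipping library sizes to the {pool.size} available points",
            stacklevel=2,
        )
        sizes = np.unique(np.minimum(sizes, pool.size))

    skills = np.empty(sizes.size)
    for si, size in enumerate(sizes):
        n_rep = 1 if size == pool.size and policy == "contiguous" else n_resamples
        vals = np.empty(n_rep)
        for r in range(n_rep):
            if policy == "contiguous":
                start = int(rng.integers(0, pool.size - size + 1))
                lib = pool[start : start + size]
            elif policy == "subset":
                lib = rng.choice(pool, size=size, replace=False)
            else:
                raise ValueError(f"unknown library policy {policy!r}")
            res = simplex_cross_map(
                cz, manifold, lag=lag, library_indices=lib, query_indices=queries
            )
            vals[r] = cross_map_skill(res.predicted, res.observed)
        skills[si] = vals.mean()
    return CrossMapResult((cause.name or "X", effect.name or "Y"), sizes, skills, lag)


def _best_lag(lags: np.ndarray, skills: np.ndarray) -> int:
    """Argmax skill; ties broken toward smallest |lag|, then negative."""
    finite = np.isfinite(skills)
    if not finite.any():
        raise AlignmentError("all lags infeasible in lag scan")
    best = np.nanmax(skills)
    cands = lags[finite & (skills >= best - 1e-12)]
    order = sorted(cands.tolist(), key=lambda lag: (abs(lag), lag))
    return int(order[0])


def lag_scan(
    cause: TimeSeries,
    effect: TimeSeries,
    config: EmbeddingConfig,
    lags: np.ndarray | None = None,
    min_overlap: int = 50,
    train_length: int | None = None,
) -> LagScanResult:
    """Cross-map skill at the maximal library for each alignment lag.

    The lag shifts which cause sample a manifold point predicts:
    manifold point of the effect at time t predicts ``cause[t + lag]``,
    so negative lags test "cause precedes effect".  Lags leaving fewer
    than ``min_overlap`` aligned pairs are marked infeasible (NaN).
    """
    if lags is None:
        lags = np.array(DEFAULT_LAGS, dtype=int)
    lags = np.asarray(lags, dtype=int)
    cz, ez = cause.zscore(), effect.zscore()
    manifold = delay_embed(ez, config)
    pool, queries = _split_pools(manifold, train_length)
    if queries is None:
        queries = pool

    skills = _all_lag_skills(cz, manifold, pool, queries, lags, min_overlap)
    optimal = _best_lag(lags, skills)
    return LagScanResult((cause.name or "X", effect.name or "Y"), lags, skills, optimal)


def _all_lag_skills(
    target: TimeSeries,
    manifold,
    pool: np.ndarray,
    queries: np.ndarray,
    lags: np.ndarray,
    min_overlap: int,
) -> np.ndarray:
    """Skill per lag.  All lags are compared on the common library and
    query sets of points whose target time is valid under *every*
    scanned lag, so differences between lags reflect alignment, not
    changing sample composition; the neighbour search is then shared
    across lags.  If that common set is too small (heavy masking or
    extreme lags), each lag falls back to its own maximal set.
    """
    lo, hi = int(lags.min()), int(lags.max())
    ok_all = _valid_target_times(target, manifold.point_times, lo)
    ok_all &= _valid_target_times(target, manifold.point_times, hi)
    if not target.mask.all():
        for lag in lags:  # interior masked samples matter too
            ok_all &= _valid_target_times(target, manifold.point_times, int(lag))
    lib = pool[ok_all[pool]]
    qry = queries[ok_all[queries]]
    k = manifold.dimension + 1

    skills = np.full(lags.size, np.nan)
    if qry.size >= min_overlap and lib.size >= k + 1:
        times, w = _neighbor_weights(manifold, lib, qry, k)
        qt = manifold.point_times[qry]
        for i, lag in enumerate(lags):
            pred = (target.values[times + int(lag)] * w).sum(axis=1)
            skills[i] = cross_map_skill(pred, target.values[qt + int(lag)])
        return skills

    for i, lag in enumerate(lags):  # slow path: per-lag maximal sets
        try:
            res = simplex_cross_map(
                target, manifold, lag=int(lag), library_indices=pool,
                query_indices=queries,
            )
            if res.predicted.size < min_overlap:
                continue
            skills[i] = cross_map_skill(res.predicted, res.observed)
        except (AlignmentError, InsufficientDataError):
            continue
    return skills


def accept_by_lag(scan: LagScanResult) -> LagAcceptance:
    """Positive-lag rejection: the causal claim is rejected iff the
    best-mapping lag t_p is positive; t_p = 0 is accepted but flagged
    instantaneous (to be arbitrated by the entropy mask)."""
    tp = scan.optimal_lag
    if tp > 0:
        return LagAcceptance(False, tp, False, "optimal lag positive (anti-causal)")
    if tp == 0:
        return LagAcceptance(True, tp, True, "instantaneous -- requires IGCI mask")
    return LagAcceptance(True, tp, False, "cause precedes effect")
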