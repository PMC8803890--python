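"""Entropy-based information-geometric causal inference (IGCI) and the
mask it applies to robust cross-mapping results.

For a (near-)deterministic invertible mechanism Y = f(X), IGCI exploits
the asymmetry that the mechanism leaves the cause's distribution
"simpler": with both variables rescaled to [0, 1], the cause has the
larger differential entropy.  The score C_{X->Y} = H(P_Y) - H(P_X)
therefore points from cause to effect when it is negative.  Entropies
are estimated with a k-d partitioning (kDP) scheme: recursive
median splits of the sample, stopped when a cell looks uniform or too
small, with the plug-in entropy of the resulting adaptive histogram.

Cross-mapping fails under strong or instantaneous coupling (both
directions look convergent); the entropy score arbitrates those cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DegenerateDistributionError, InsufficientDataError
from .robust import RCCMDecision

__all__ = ["IGCIResult", "MaskedDecision", "kdp_entropy", "igci_score", "mask_rccm"]

#: decision threshold on |C| in nats, for [0,1]-rescaled data
DEFAULT_EPSILON = 0.2


def kdp_entropy(
    sample: np.ndarray,
    min_cell: int = 8,
    alpha: float = 0.05,
    min_depth: int = 3,
) -> float:
    """Differential entropy (nats) via k-d partitioning.

    The sample's support is split recursively at the cell median while
    a median-deviation uniformity test rejects at level ``alpha`` and
    the cell holds at least ``2 * min_cell`` points; the first
    ``min_depth`` levels always split (a symmetric density centres its
    median and would otherwise defeat the test at the root).  The
    estimate is the plug-in entropy of the final partition,

        H = sum_cells (n_c / n) * log(n * width_c / n_c).

    Raises on samples smaller than 8 or (numerically) constant.
    """
    x = np.sort(np.asarray(sample, dtype=float).ravel())
    n = x.size
    if n < 8:
        raise InsufficientDataError(f"kDP entropy needs >= 8 samples, got {n}")
    if x[0] == x[-1]:
        raise DegenerateDistributionError("constant sample has no differential entropy")
    z_crit = float(norm.ppf(1.0 - alpha / 2.0))
    total = 0.0
    # cells are (i, j, lo, hi, depth) over the sorted sample x[i:j]
    stack = [(0, n, float(x[0]), float(x[-1]), 0)]
    while stack:
        i, j, lo, hi, depth = stack.pop()
        m = j - i
        width = hi - lo
        if width <= 0.0:
            # ties collapsed the cell; a point mass contributes the
            # narrowest resolvable width to keep the sum finite
            width = np.spacing(abs(hi) + 1.0)
            total += (m / n) * np.log(n * width / m)
            continue
        med = float(x[i + m // 2])
        can_split = m >= 2 * min_cell and lo < med < hi
        if can_split:
            z = (med - 0.5 * (lo + hi)) / (width / (2.0 * np.sqrt(m)))
            if depth < min_depth or abs(z) > z_crit:
                half = m // 2
                stack.append((i, i + half, lo, med, depth + 1))
                stack.append((i + half, j, med, hi, depth + 1))
                continue
        total += (m / n) * np.log(n * width / m)
    return float(total)


@dataclass
class IGCIResult:
    """Entropy-based causal score for one variable pair."""

    pair: tuple[str, str]  # (name_x, name_y)
    entropy_x: float
    entropy_y: float
    score: float  # H(P_Y) - H(P_X)
    inferred_direction: tuple[str, str] | None  # None = undecided
    epsilon: float

    @property
    def decided(self) -> bool:
        return self.inferred_direction is not None

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "entropy_x": self.entropy_x,
            "entropy_y": self.entropy_y,
            "score": self.score,
            "inferred_direction": (
                list(self.inferred_direction) if self.inferred_direction else None
            ),
            "epsilon": self.epsilon,
        }


def _rescale_unit(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise DegenerateDistributionError("constant sample cannot be rescaled to [0,1]")
    return (v - lo) / (hi - lo)


def igci_score(
    x: np.ndarray,
    y: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    names: tuple[str, str] = ("X", "Y"),
) -> IGCIResult:
    """Score the pair: C_{X->Y} = H(P_Y) - H(P_X) on [0,1]-rescaled data.

    Direction X->Y is inferred when the score is below ``-epsilon``
    (the cause has the larger entropy), Y->X above ``+epsilon``,
    undecided otherwise.  Antisymmetric by construction:
    score(x, y) == -score(y, x).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"paired samples must match: {x.size} vs {y.size}")
    keep = np.isfinite(x) & np.isfinite(y)
    hx = kdp_entropy(_rescale_unit(x[keep]))
    hy = kdp_entropy(_rescale_unit(y[keep]))
    score = hy - hx
    if score < -epsilon:
        direction: tuple[str, str] | None = (names[0], names[1])
    elif score > epsilon:
        direction = (names[1], names[0])
    else:
        direction = None
    return IGCIResult(names, hx, hy, score, direction, epsilon)


@dataclass
class MaskedDecision:
    """Cross-mapping verdict after the entropy mask.

    ``final`` is one of:

    - ``"kept"``          the RCCM link stands;
    - ``"masked"``        a convergent link contradicted by a decisive
                          entropy score (the strong/instantaneous-
                          coupling correction);
    - ``"rejected_by_lag"`` the best alignment lag was positive;
    - ``"no_link"``       RCCM itself found no convergent link.
    """

    rccm: RCCMDecision
    igci: IGCIResult
    final: str
    reason: str

    @property
    def link_present(self) -> bool:
        return self.final == "kept"

    def to_dict(self) -> dict:
        return {
            "rccm": self.rccm.to_dict(),
            "igci": self.igci.to_dict(),
            "final": self.final,
            "reason": self.reason,
        }


def mask_rccm(rccm: RCCMDecision, igci: IGCIResult) -> MaskedDecision:
    """Apply the entropy mask to one RCCM direction.

    A positive optimal lag rejects the claim outright.  Otherwise, when
    the entropy difference is decisive (|score| > epsilon) the link is
    kept only if the IGCI direction agrees with the cross-mapping
    direction and masked if it points the other way; an indecisive
    score leaves the RCCM verdict untouched.
    """
    if set(rccm.direction) != set(igci.pair):
        raise ValueError(
            f"pair mismatch: RCCM {rccm.direction} vs IGCI {igci.pair}"
        )
    if rccm.optimal_lag > 0:
        return MaskedDecision(
            rccm, igci, "rejected_by_lag", f"optimal lag {rccm.optimal_lag} > 0"
        )
    if not rccm.convergent:
        return MaskedDecision(
            rccm, igci, "no_link", "cross-map skill not convergent"
        )
    if igci.decided:
        if igci.inferred_direction == rccm.direction:
            return MaskedDecision(rccm, igci, "kept", "entropy score agrees")
        return MaskedDecision(
            rccm,
            igci,
            "masked",
            f"entropy score {igci.score:+.3f} contradicts the cross-map direction",
        )
    return MaskedDecision(rccm, igci, "kept", "entropy score indecisive; RCCM stands")
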