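import numpy as np
import pytest

from rccm import LogisticMapParams, coupled_logistic_map


def exhaustive_simplex(target, manifold, lag, lib, qry, k):
    """Independent simplex oracle: per-query exhaustive distance scan
    (no spatial index), explicit weight formula."""
    preds, obs, times = [], [], []
    for q in qry:
        t = manifold.point_times[q] + lag
        if t < 0 or t >= len(target) or not target.mask[t]:
            continue
        shifted = manifold.point_times[lib] + lag
        ok = (shifted >= 0) & (shifted < len(target)) & (lib != q)
        ok[ok] &= target.mask[shifted[ok]]
        cand = lib[ok]
        d = np.sqrt(((manifold.points[cand] - manifold.points[q]) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:k]
        dk = d[order]
        vk = target.values[manifold.point_times[cand[order]] + lag]
        if dk[0] == 0.0:
            w = (dk == 0.0).astype(float)
        else:
            w = np.exp(-dk / dk[0])
        preds.append(float(np.dot(w, vk) / w.sum()))
        obs.append(target.values[t])
        times.append(manifold.point_times[q])
    return np.array(preds), np.array(obs), np.array(times)


@pytest.fixture(scope="session")
def logistic_pair():
    """Unidirectionally coupled logistic pair (chaotic driver, forced
    period-4 response), 1000 samples, noise-free."""
    params = LogisticMapParams(beta_yx=0.1, n_samples=1000, seed=42)
    return coupled_logistic_map(params)


@pytest.fixture(scope="session")
def independent_pair():
    """Two uncoupled chaotic logistic maps on different seeds."""
    x, _ = coupled_logistic_map(
        LogisticMapParams(beta_yx=0.0, r_y=3.7, n_samples=1000, seed=1)
    )
    _, y = coupled_logistic_map(
        LogisticMapParams(beta_yx=0.0, r_y=3.7, n_samples=1000, seed=2)
    )
    return x, y
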