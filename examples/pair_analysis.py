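"""Causal direction between one pair of coupled nonlinear series.

Simulates a chaotic driver X forcing a response Y through the coupled
logistic map, then runs the full robust cross-mapping pipeline in both
directions and applies the entropy mask.
"""

import numpy as np

from rccm import (
    LogisticMapParams,
    RCCMConfig,
    analyze_pair,
    coupled_logistic_map,
)

# X chaotic (r=3.8) forcing Y (r=3.5) with coupling 0.3; 11 "years"
# of 46 samples, light observation noise on both emitted series
params = LogisticMapParams(
    beta_yx=0.3, r_y=3.5, sigma_x=0.01, sigma_y=0.01, n_samples=506, seed=3
)
x, y = coupled_logistic_map(params)
x.name, y.name = "X", "Y"

config = RCCMConfig(dim_min=1, dim_max=6)
forward, backward, dimension = analyze_pair(x, y, config, seed=0)

for label, dec in [("X -> Y", forward), ("Y -> X", backward)]:
    r = dec.rccm
    print(
        f"{label}: robust skill {r.robust_skill:+.3f}, optimal lag {r.optimal_lag:+d}, "
        f"convergent={r.convergent}, final='{dec.final}' ({dec.reason})"
    )
print(f"selected embedding dimension p = {dimension}")
print(f"entropy score C = {forward.igci.score:+.3f} (|C| <= 0.2 is indecisive)")
print()
print(
    "A kept X->Y link with a negative/zero lag and a rejected or much\n"
    "weaker Y->X link recovers the planted unidirectional forcing; the\n"
    "skill is the Pearson correlation between Y-manifold cross-map\n"
    "estimates of X and the observed X, median-aggregated over 10\n"
    "bootstrap windows."
)
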