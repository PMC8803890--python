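"""Coupling x noise benchmark on the coupled logistic map.

Reproduces the classic robustness experiment at desk scale: how
cross-map skill for recovering the cause degrades with observation
noise on the effect, and how the entropy mask protects direction
identification.  Increase --runs for smoother numbers.
"""

from rccm import benchmark_logistic

res = benchmark_logistic(
    betas=(0.05, 0.10, 0.15),
    sigmas=(0.0, 0.025, 0.05),
    n_runs=25,
    n_samples=1000,
    seed=0,
)
print(res.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print(
    "median_skill_true is the terminal cross-map skill for estimating\n"
    "the cause X from the effect's shadow manifold: it grows with the\n"
    "coupling beta_yx and collapses as effect noise sigma_y swamps the\n"
    "imprint of X on Y.  masked_rate (CCM+IGCI) never identifies the\n"
    "true direction less often than plain CCM (plain_rate)."
)
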