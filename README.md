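# rccm — robust convergent cross-mapping with entropy masking

`rccm` infers directed causal links between pairs of nonlinear
dynamical time series — the kind of problem posed by land–atmosphere
flux records (GPP, latent heat, soil moisture, precipitation, air
temperature, radiation) sampled on a regular grid — and applies the
inference pixel-wise over gridded (lat × lon × time) datacubes. It is
aimed at researchers in ecosystem science, Earth-system analysis and
nonlinear dynamics who need causal hypotheses from observational
series where Granger-style linear methods break down.

## Method

**Convergent cross-mapping (CCM).** If X forces Y, Takens' theorem
guarantees that Y's delay-coordinate reconstruction (the *shadow
manifold* M_Y, vectors `(y_t, y_{t−τ}, …, y_{t−(p−1)τ})`) encodes X.
The claim X → Y is tested by predicting X from nearest neighbours in
M_Y with the simplex estimator (p+1 neighbours, weights
`w_i ∝ exp(−d_i/d_1)`); the Pearson correlation ρ between estimate and
observation is the *cross-map skill*. A causal link shows skill that
*converges* upward as the neighbour library grows. The extended
variant scans alignment lags t_p ∈ {−15, …, 15}; a best lag t_p > 0
(effect preceding cause) rejects the claim.

**Robust CCM (RCCM).** A single convergence curve is noisy and the
embedding dimension p is unknown. The series is therefore cut into
N = 10 overlapping whole-year windows with staggered starts; each
window trains on its first third (library) and tests on the rest.
p is selected automatically (the value maximizing the median terminal
skill across windows), convergence is judged on the median across
windows of the one-step skill-difference curve, and the reported
robust skill ρ̃ is the median terminal skill at the optimal lag.

**IGCI masking.** Under strong or instantaneous coupling CCM reports
*both* directions as convergent. Entropy-based information-geometric
causal inference arbitrates: with both variables rescaled to [0, 1],
a (near-)deterministic invertible mechanism leaves the cause with the
larger differential entropy, so the score
`Ĉ_{X→Y} = Ĥ(P_Y) − Ĥ(P_X)` (kDP estimator: recursive median-split
partitioning) points from cause to effect when negative. A convergent
link whose direction a decisive score (|Ĉ| > ε = 0.2) contradicts is
masked.

## Worked example

```python
from rccm import LogisticMapParams, RCCMConfig, analyze_pair, coupled_logistic_map

params = LogisticMapParams(beta_yx=0.3, r_y=3.5, sigma_x=0.01, sigma_y=0.01,
                           n_samples=506, seed=3)
x, y = coupled_logistic_map(params)          # chaotic X forcing Y
forward, backward, p = analyze_pair(x, y, RCCMConfig(dim_min=1, dim_max=6), seed=0)
```

This prints (see `examples/pair_analysis.py`):

```
X -> Y: robust skill +0.950, optimal lag -3, convergent=True, final='kept'
Y -> X: robust skill +0.778, optimal lag +2, convergent=False, final='rejected_by_lag'
selected embedding dimension p = 5
entropy score C = +0.019 (|C| <= 0.2 is indecisive)
```

The planted unidirectional forcing is recovered: the X → Y claim
cross-maps with ρ̃ = 0.95 at a causal (negative) lag and is kept,
while the reverse claim peaks at an anti-causal (+2) lag and is
rejected. The other scripts in `examples/` demonstrate the
coupling × noise benchmark, the entropy oracles, and the pixel-wise
datacube pipeline with its dominance, skill-difference and stratified
map products; each prints a short interpretation of its numbers.

A thin CLI mirrors the pipeline entry points:

```bash
rccm make-cube --shape 8,8 --out cube.nc
rccm run-pair --cube cube.nc --pair A,B --seed 1 --out out/
rccm benchmark-logistic --runs 100
```

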