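# Methods

## State-space reconstruction and the simplex cross-map

A regularly sampled scalar series is embedded into delay-coordinate
vectors `(x_t, x_{t−τ}, …, x_{t−(p−1)τ})`, indexed by the time of the
most recent coordinate. Vectors touching any invalid sample are
dropped rather than imputed, so gaps shorten the manifold but never
contaminate it. The cross-map estimate of a target value at manifold
time t uses the p+1 nearest library neighbours of the query point
(Euclidean distance, the query itself excluded), weighted
`w_i = u_i / Σu_j` with `u_i = exp(−d_i/d_1)`; exact zero-distance
ties share equal weight, which also removes the division by zero.
Both series of a pair are z-scored before neighbour search so units
cancel; Pearson correlation is unaffected. The defaults τ = 1 and
p+1 neighbours follow standard simplex-projection practice at coarse
(8-day-scale) temporal resolution. Skill is defined as 0 when either
side of the correlation is constant.

The implementation is verified, to 1e−10, against an exhaustive
per-query distance scan with the explicit weight formula on random
instances up to 500 points (the tree-based search and the oracle
share no code path).

## Convergence curves and the lag scan

For the claim X → Y, X is cross-mapped from M_Y with libraries that
are random contiguous blocks of the training manifold, resampled
(default 20 times; 5 inside the windowed pipeline, where the windows
themselves already form an ensemble) at each of 8 logarithmically
spaced sizes from 10·p to the training maximum; the mean per size is
reported. Contiguous blocks respect serial dependence better than
random subsets; a `subset` policy is available.

The alignment lag t_p shifts which cause sample a manifold point
predicts: negative lags test "cause precedes effect". All lags are
compared on the common library/query subset valid under every scanned
lag, so differences reflect alignment rather than changing sample
composition (this also lets the neighbour search be shared across the
scan). Ties at the maximal skill resolve to the smallest |lag|, and
between ±k to −k, favouring the causal reading. The claim is rejected
outright when t_p > 0; t_p = 0 is accepted but flagged instantaneous,
to be arbitrated by the entropy mask.

**Known degeneracy.** For a noise-free pure-copy system
Y(t) = g(X(t−d)) embedded at p ≥ 2, the lags −d and −d−1 are both
exact coordinate lookups and every lag ≥ −d is a deterministic
forward iterate, so the skill-versus-lag curve is flat near 1 and the
argmax is decided by interpolation noise. Such a system is
one-dimensional, and the scan run at p = 1 recovers −d essentially
always; the lag-recovery checks therefore use p = 1. Real (noisy,
self-dynamical) systems do not show this plateau.

## The robust decision

Windows: the window length is the smallest whole-year span holding at
least `min_valid_run` samples (default 400, i.e. 9 years at 46
samples/year), and the N = 10 windows take evenly spaced start
offsets across the remaining slack, overlapping as needed. Each
window trains on its first third. A window whose valid-sample count
falls below the minimum is dropped; a decision requires at least half
the planned windows.

The embedding dimension is selected per pair (optionally per
direction) as the p in 1…10 maximizing the median terminal skill
across windows, ties to the smallest p. Selection uses the terminal
library only; the full convergence curve is then computed at the
selected p. Convergence requires a positive mean of the first half of
the median one-step skill-difference curve *or* an already-saturated
curve (median initial skill at or above the threshold — strong
near-synchronous coupling converges before the smallest library, and
demanding a further rise would misread saturation as absence), and in
either case ρ̃ at or above the skill threshold (0.8 for map
products). ρ̃ is the median across windows of the terminal skill at
the optimal lag, so it always lies between the per-window extremes.

Seeding: one master seed; per-window and per-pixel seeds derive from
it through `numpy` seed sequences, so results are independent of
execution order and a pixel run alone equals the same pixel inside a
grid run.

## Entropy estimation and the mask

The kDP estimator sorts the sample, then recursively splits cells at
their median while a uniformity test rejects: under uniformity the
cell median is asymptotically normal around the cell centre with
s.d. `width/(2√m)`, and the cell splits when the standardized
deviation exceeds the two-sided 5% point, provided at least 16 points
remain. Because a symmetric density centres its median, the first
three levels always split (8 cells minimum); without this a Gaussian
sample would terminate at the root. The estimate is the plug-in
entropy `Σ (n_c/n) log(n·width_c/n_c)` of the resulting adaptive
partition. Against closed forms at n = 10⁴ the median error is below
0.01 nats for U(0,1), N(0,1) and Exp(1), and the affine law
H(aX) = H(X) + ln a holds to machine precision.

The IGCI score rescales both variables to [0, 1] (uniform reference
measure) before estimation; ε = 0.2 nats on that scale. The mask
removes a convergent, lag-admissible link only when the score is
decisive *and* points the other way; agreement or indecision leaves
the cross-map verdict untouched, so genuinely bidirectional couplings
(whose symmetric mechanisms give near-zero scores) survive.

Entropy asymmetry needs a sufficiently nonlinear mechanism relative
to the cause's support: for a chaotic-logistic cause on ≈[0.18,0.95]
the map x² is nearly affine (true score ≈ +0.02, indecisive), while
x⁶ is decisively negative (≈ −0.9). The instantaneous-coupling checks
use x⁶ for this reason.

## Synthetic systems

The coupled logistic map `x_{t+1} = x_t(r_x(1−x_t) − β_xy y_t)`,
`y_{t+1} = y_t(r_y(1−y_t) − β_yx x_t)` with r_x = 3.8, r_y = 3.5
gives a chaotic driver and a period-4 response that chaoticizes as
the coupling grows; benchmark couplings are β_yx ∈ {0.05, 0.10, 0.15}
with β_xy = 0. Observation noise is added to the emitted copies only
(σ_x = 0, σ_y ∈ {0, 0.025, 0.05}), leaving the latent attractor
intact — a noise-free cause driving a noisily observed effect.
Burn-in is 300 steps; initial conditions draw from U(0.2, 0.8); a
trajectory leaving [0, 1] raises an error naming the step. The
benchmark fixes p = 2, τ = 1 and a one-step alignment (lag −1,
matching the map's x_t → y_{t+1} forcing), trains on the first third
of 1000 samples, and replicates each grid cell over 100 seeded runs.
"Plain CCM identifies the true direction" means X → Y is detected
(terminal skill ≥ 0.5 with a non-falling curve) and Y → X is not; the
combined method first removes detections contradicted by a decisive
entropy score. The 0.5 detection level is a benchmark-reporting
choice only; map products use 0.8.

The datacube generator plants one regime per pixel — independent
(β = 0, detuned rates), A→B and B→A (unidirectional β = 0.3, strong
enough to imprint the driver without fully synchronizing the pair),
and bidirectional (symmetric β = 0.2, r = 3.78/3.72) — plus a shared
sinusoidal seasonal cycle (amplitude 0.05, period one year) and
σ = 0.01 observation noise. The couplings were fixed once from pilot
simulations so the four regimes are dynamically distinct at the 0.9 /
0.8 / 0.4 thresholds. The cube emulates the length scale of an 8-day,
11-year gridded product (506 steps) but none of the distributional
properties of real flux products: no trends, no spatially correlated
noise, no regime mixtures within a pixel. Passing the cube recovery
check shows the pipeline's plumbing and decision logic are sound
under strong seasonal autocorrelation, not that real-data inferences
are correct.

## Problem sizes and runtime

Desk-scale defaults keep every check on one CPU in minutes: 100 runs
per benchmark cell (the full experiment design scales to thousands),
an 8 × 8 × 506 cube (64 pixels, both directions, dimension search
1…6), 100 seeds for the masking and lag-recovery ensembles, and 200
random instances for the simplex oracle.

## Limitations

- Bivariate only: no conditioning on third variables; confounders are
  an assumption, not a test.
- The convergence rule (first-half delta mean, saturation clause) is
  a calibrated heuristic; there is no significance test on ρ̃ beyond
  the bootstrap ensemble.
- IGCI assumes a (near-)deterministic invertible mechanism and an
  independence of cause distribution and mechanism; heavy noise or
  nearly affine mechanisms leave it indecisive, and the mask then
  defaults to the cross-map verdict.
- Embedding delay τ is fixed (default 1), not tuned by mutual
  information; mixed-variable embeddings and locally weighted (S-map)
  prediction are out of scope.
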