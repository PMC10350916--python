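# Methods

This note records the model definitions, algorithmic choices, default
parameters and known limitations of `slmassembly`, in the order the
pipeline runs.

## Lattice model

**State.** N labeled particles on an L x L torus, at most one per cell,
each with an internal state s_i in {1..M_T}.  Energies are in k_B T.

**Targets.** A target m is a placement of all N particles on distinct
cells; its adjacency matrix I^m marks particle pairs occupying
nearest-neighbor cells in that layout.  Targets are finite absolute
shapes (no periodic wrap inside a layout); recognition on the periodic
board compares adjacency matrices, which is automatically translation
invariant.  Default target set: a compact ceil(sqrt(N))-wide rectangular
block; target 1 orders particles row-major, target 2 boustrophedon
(same bond count, different adjacency), targets 3+ use fixed seeded
permutations.  For N=25 each target carries 40 bonds, so the assembled
energy is 40 * J_s = -160 with the default couplings.

**Pair energy.** For a board-adjacent pair that is a neighboring pair of
target m: J_s if both states equal m, J_half if exactly one does, J_w if
neither; J_w for pairs that are neighbors in no target.  J_half defaults
to (J_s + J_w)/2 = -2.5 and is an explicit, configurable parameter.  If a
bond is shared by several targets the most attractive per-target energy
applies, which avoids double counting and keeps the assembled targets
degenerate global minima.

**Distance to target.** d_m = sum_{i<j} |B_ij - I^m_ij|, the Hamming
distance between board adjacency and target adjacency; d_m = 0 defines
assembly together with the equivalent energy criterion E <= min_m J_s *
bonds(m).  Internal-state mismatches are not penalized by d_m; the
energy criterion already distinguishes them.

## Monte Carlo dynamics

One MC step = one translation attempt (uniform particle, uniform
direction; an occupied destination rejects before any energy evaluation,
and time still advances) followed by one switch attempt (independently
uniform particle, uniform new state != current; skipped when M_T = 1).
Acceptance: p = min(1, e^(-dE)) for translations and
q = min(1, e^(-dE + sign*delta_mu)) for switches, where sign = [>=2
neighbors in the proposed state] - [>=2 neighbors in the current state].

**Entropy production.** Each accepted move adds log(p_fwd/p_rev).  For a
translation the reverse is the inverse displacement, giving exactly -dE;
for a switch the reverse proposes the old state in the post-move
neighborhood, whose drive sign is exactly the negative of the forward
one, giving -dE + sign*delta_mu.  The kernel uses these closed forms; the
generic log-ratio implementation in `entropy_increment` is tested against
them.

**Exactness of bookkeeping.** With half-integer couplings every energy is
exactly representable in binary floating point, so the incrementally
updated energy equals a full recomputation bit-for-bit (asserted over
10^5 audited steps in the tests).

**Randomness.** Each trajectory carries its own PCG32 stream seeded from
the trajectory seed; initial placement uses an independent numpy PCG64
generator with the same seed.  Trajectories are bit-reproducible and safe
to run in parallel with seeds base_seed + index.

**Recording.** Observables (E, cumulative dS, all d_m) are recorded every
`record_every` steps, default T_cap // 50,000 so a full-length run yields
~5x10^4 samples; assembly is detected at recorded steps only, and by
default the run halts at first assembly (continuing is a flag).

## First-assembly-time statistics

Realizations that do not assemble within T_cap are right-censored at the
cap: they enter order statistics at T_cap (the median becomes an explicit
lower bound when more than half are censored) and are excluded from
density fits.  sigma is the log-scale half-distance between the 16th and
84th percentiles; the log-normal fit is percentile-based (mu = log Md).
The hybrid histogram uses 10 log-equal bins below the median
(configurable; nothing quantitative depends on it), Scott-width linear
bins above, and one terminal bin at T_cap for the censored mass.  The
drive dependence of Md and sigma is summarized by a least-squares fit of
A e^(-b*delta_mu) + C, with a degenerate-data flag when b is
unidentifiable.

## Segmentation

The energy series is block-mean down-sampled (decimation would discard
within-block information that the segment means use) and modeled as
piecewise-linear trend plus independent Gaussian noise with per-segment
variance; no seasonal component.  Segments must span at least
floor(0.01 * n) samples (one percent of the series).

Two backends:

* **bayes** (default). Reversible-jump MCMC over change-point
  configurations.  Per-segment regression parameters are integrated out
  under a conjugate normal-inverse-gamma prior: the design is (intercept,
  slope scaled by the segment half-width), the coefficient prior is unit
  variance on the globally standardized signal, and the noise variance
  prior is InvGamma(2, s2) with s2 a robust noise estimate (median squared
  first difference debiased by the chi-square-1 median).  The number of
  change points is uniform on 0..max_cp with uniform admissible positions
  given the count.  Moves: birth, death, local shift, and an exact
  merge/split pair exchanging two adjacent change points for one —
  without it the chain cannot tunnel between a true jump and the
  two-point "ramp" configuration that models it under the minimum-duration
  constraint.  Chains (4 by default; 5,000 burn-in and 20,000 kept samples
  each) start at the penalized-least-squares optimum.  The reported count
  is the posterior median, placed at the peaks of the per-sample
  change-point probability; a between-chain spread diagnostic on the
  count is attached and warned about when large.
* **pls**. Deterministic optimal partitioning by dynamic programming with
  per-segment Gaussian profile likelihood and a BIC-style penalty
  2 log n per change point (escalated if the max_cp cap is ever hit).
  Exact and reproducible; used where determinism matters.

Both backends standardize the signal internally, making the detected
change points invariant under affine rescaling.  Segment statistics are
the mean, standard deviation (ddof = 1) and OLS slope per sample.

## Stochastic landscape

Pre-assembly segments of assembling trajectories are labeled
Y = ln(T_FAS - end_step); segments ending at or after T_FAS, and all
segments of censored trajectories, are discarded.  The label anchor is
the segment end: a forecast is issued once a segment has been observed in
full, and t_r is then positive for every kept segment.

The three coordinates are z-scored jointly over the whole labeled pool
and projected on the first two principal components, following the
flowchart ordering (PCA before the random split; a strict no-leak variant
would fit the normalization on the training part only — the difference
is the coordinate statistics, not the labels, and test labels never
enter any fitted quantity, which a label-poisoning test enforces).

The landscape is the Delaunay triangulation of the training-point scores
with node values given by Gaussian-kernel (Nadaraya-Watson) smoothing of
the training labels; the bandwidth default is Scott's rule on the 2-D
scores.  Prediction is barycentric interpolation inside the convex hull
and the nearest node's value outside it (total, finite everywhere).

**Bias correction.** Segments split 60:20:20 into train/CV/test by
segment (not by trajectory).  K = 10 re-splits of the train+CV pool;
per repeat, the landscape trained on the training part predicts the CV
part and the bias mean(Y_hat - Y) is accumulated in bins of the predicted
value (width 0.5 in natural-log units, bins aligned to multiples of the
width; an empty bin contributes zero).  The per-bin biases averaged over
repeats form the bias table; the final landscape is rebuilt on the whole
train+CV pool and its test predictions are corrected by the bias linearly
interpolated between bin centers.  Natural log is used throughout; only
the bin width depends on the base.

A usability gate refuses to train when fewer than 60% of the supplied
trajectories contain an assembly event (configurable).

## Evaluation

The naive competitor Y_hat_M is the mean label of the train+CV pool.
Test points are binned by the bias-corrected prediction (width 0.5);
per bin, Gaussian-KDE densities of the error distributions
(Delta Y_hat_BC = Y_hat_BC - Y_test, Delta Y_hat_M = Y_hat_M - Y_test)
and of the data spread (Delta Y_test = <Y_test> - Y_test) are compared by
Kullback-Leibler divergence, and the per-bin values are averaged with the
bin weights.  Bins holding less than 1% of the test mass or fewer than 5
points are excluded and the weights renormalized.  The default direction
is KLD(error-density || data-density); KLD is not symmetric and the
direction is a configuration flag.  The divergence integral uses
Simpson's rule on a dense shared grid with a 1e-12 density floor before
the logarithm; it is flagged infinite only when most of the first
density's mass lies where the second vanishes even after flooring.
Against closed-form Gaussian cases the quadrature is accurate to better
than 1e-4.

## Synthetic fixtures

* **Piecewise signals**: concatenated linear-trend segments with declared
  means, slopes and common noise sigma; exact change-point indices
  returned.
* **Landscape datasets**: stochastic coordinates driven by two latent
  Gaussian factors plus small isotropic jitter — the near-planar,
  correlated cloud that real segment coordinates form, and the regime in
  which a two-component projection can recover a declared response
  surface (with isotropic coordinates the z-scored PC plane would be
  arbitrary).  Labels are a declared smooth function of the coordinates
  (through the pseudo-inverse of the latent mixing) plus noise.
* **Assembly-time samples**: log-normal draws right-censored at a cap.

Fixtures use numpy PCG64 streams, deliberately a different generator
family from the simulator kernel's PCG32.  What passing fixture tests do
not show: fixtures realize the statistical structures the stages assume
(piecewise-linear trends, planar coordinate clouds, log-normal times);
they do not emulate kinetic-trap physics, heavy-tailed censoring
interactions, or segment-to-segment correlation within a trajectory.

## Scaled-down experiment sizes

The full reference campaign (1,000 realizations x 5x10^7 steps x 12 drive
values) is cluster-scale.  The packaged end-to-end experiment uses drive
2.4, 100 realizations and a 5x10^6-step cap (seeds 100..199, deterministic
pls backend), chosen as the smallest configuration at which the assembly
fraction clears the 60% usability gate and the test set holds several
hundred segments; it reproduces the direction of the headline comparison
(positive test correlation with p < 0.05 and KLD_BC < KLD_M).  The
detailed-balance check runs on an exactly enumerable 2-particle,
3x3-lattice system; its coupling is set to J_s = -2 because at the
reference J_s = -4 the bond is metastable and the visit-frequency
estimator at 10^6 samples is variance- (not bias-) limited, while the
property under test is coupling-independent (the aggregate bond occupancy
is additionally checked at J_s = -4).

## Known limitations

* Single-particle moves only: cluster diffusion is suppressed, so
  absolute time scales are not those of collective-move dynamics.
* The Bayesian sampler's posterior is exact only up to MCMC error;
  pathological signals may need more kept samples (the mixing diagnostic
  warns).
* Percentile-based log-normal fitting ignores censoring beyond the order
  statistics; no survival-likelihood estimation is attempted.
* The landscape extrapolates outside the training hull by nearest-node
  value — forecasts far from observed stochastic coordinates are
  anchored, not modeled.
* Bias is modeled as a function of the predicted value only (binned,
  piecewise-linear), not of position on the landscape.
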