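# slmassembly

Driven lattice Monte Carlo simulation of multicomponent self-assembly and
stochastic-landscape forecasting of the remaining time to the first
assembly event.

## The problem

Self-assembling systems with many distinguishable components have rugged
energy landscapes: long-lived kinetic traps delay the first completion of
a target structure, and the first-assembly time T_FAS of a single
realization is broadly (approximately log-normally) distributed.  This
package is for researchers studying nonequilibrium self-assembly who want
(a) a fast, reproducible simulator of a canonical toy model and (b) a
data-driven forecast of how much longer a running realization will take
to assemble, using only a scalar observable of the trajectory.

## The model

N distinguishable particles live on an L x L square lattice with periodic
boundaries; each carries an internal state s_i in {1..M_T} selecting one
of M_T stored target structures.  A pair of lattice-adjacent particles
interacts with

* J_s (strong) if the pair is nearest-neighbor in target m and
  s_i = s_j = m,
* J_half = (J_s + J_w)/2 if exactly one of the two states equals m,
* J_w (weak) otherwise.

The total energy is E = sum over adjacent pairs of J(s_i, s_j); each fully
assembled target is a global minimum (for the reference system N=25, L=15,
M_T=2, J_s=-4, J_w=-1 that minimum is E = -160 k_B T).  Dynamics are
single-particle Metropolis: a translation attempt with acceptance
p = min(1, e^(-dE)) followed by an internal-state switch attempt with

    q = min(1, exp(-dE + sign * delta_mu)),

where the self-healing drive delta_mu >= 0 biases a particle toward the
state shared by two or more of its lattice neighbors (sign = +1 toward,
-1 away, 0 otherwise).  The drive breaks detailed balance; the trajectory
entropy production dS accumulates log(p_forward/p_reverse) over accepted
moves.

## The stochastic landscape method (SLM)

Energy trajectories are down-sampled, segmented into statistically
homogeneous pieces by Bayesian trend change-point detection (piecewise
linear + Gaussian noise, minimum segment duration 1% of the series), and
each pre-assembly segment is summarized by its stochastic coordinates
(mean, standard deviation, trend) and labeled with Y = log(t_r), the log
remaining time to first assembly at the segment end.  The coordinates are
z-scored, projected on their first two principal components, and a
Delaunay-triangulated, kernel-smoothed surface over the PC plane predicts
Y for new segments.  K = 10 cross-validation re-splits estimate the
prediction bias as a function of the predicted value; the bias-corrected
predictor is evaluated on a held-out test set against the naive mean
predictor via Pearson correlation and weighted Kullback-Leibler
divergences of the binned error distributions.

## Worked example

```python
import numpy as np
from slmassembly import (ModelParams, compact_targets, run_trajectory,
                         total_energy, SLMConfig, run_slm, evaluate)

params = ModelParams(delta_mu=2.4, T_cap=5_000_000)   # drive 2.4 k_B T
targets = compact_targets(params.N, params.M_T)
print("ground state:", targets.ground_state_energy(params))

trajs = [run_trajectory(params, targets, seed=100 + i) for i in range(100)]
print("assembled fraction:", np.mean([not t.censored for t in trajs]))

result, dataset = run_slm(trajs, SLMConfig(backend="pls", seed=11))
report = evaluate(result)
print(f"{dataset.n} segments, R={report.R:.3f}, "
      f"KLD_M={report.KLD_M:.3f}, KLD_BC={report.KLD_BC:.3f}")
```

Output (a few minutes on one CPU):

```
ground state: -160.0
assembled fraction: 0.69
3172 segments, R=0.589, KLD_M=0.476, KLD_BC=0.010
```

Reading the numbers: 69 of 100 realizations assembled within the
5x10^6-step cap; the landscape's bias-corrected forecast of log(t_r)
correlates with the truth at R = 0.59 on held-out segments, and its
weighted error-distribution divergence (KLD_BC = 0.01) is far below that
of the naive mean predictor (KLD_M = 0.48) — knowing where a trajectory
sits on the stochastic landscape genuinely sharpens the forecast of the
remaining assembly time.

A command-line interface mirrors the library:

```
slmassembly simulate --config params.yaml --n-realizations 100 --out runs/
slmassembly stats --trajectories runs/ --out stats.json
slmassembly segment --trajectories runs/ --backend bayes --out segments.csv
slmassembly campaign --n-realizations 100 --out campaign/
```

## Layout

- `lattice_model` — targets, states, interaction energies, distances
- `mc_dynamics` — Metropolis kernel, drive, entropy production, trajectories
- `assembly_stats` — censoring-aware T_FAS statistics, hybrid histograms, fits
- `segmentation` — Bayesian (RJ-MCMC) and penalized-least-squares change points
- `slm` — labeling, PCA projection, landscape, cross-validated bias correction
- `evaluation` — Pearson R, prediction binning, weighted KLDs
- `fixtures` — synthetic generators with known ground truth
- `workbench` / `cli` — per-drive campaigns and the command-line interface

See `docs/methods.md` for the modeling choices, priors, tolerances and
known limitations.
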