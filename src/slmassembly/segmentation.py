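"""Trend change-point segmentation of energy trajectories.

The signal is modeled as piecewise-linear trend plus independent Gaussian
noise, with its own noise level in every segment; trend changes only (no
seasonal component).  Two backends produce the change points:

* ``bayes`` (default) — a reversible-jump Markov chain over change-point
  configurations.  Per-segment regression parameters (intercept, slope,
  noise variance) are integrated out under a conjugate
  normal-inverse-gamma prior, the number of change points has a uniform
  prior on 0..max_cp with uniform admissible positions given the count,
  and the selected count is the posterior median, placed at the peaks of
  the per-sample change-point probability.
* ``pls`` — deterministic penalized least squares: optimal partitioning by
  dynamic programming with a BIC-style penalty per change point.

Both enforce a minimum segment duration (default one percent of the signal
length) and both are invariant under affine rescaling of the signal, which
is standardized internally before any inference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SignalWindow", "ChangePointPosterior", "Segment",
    "downsample", "detect_changepoints", "extract_segments",
    "segment_statistics",
]


@dataclass
class SignalWindow:
    """A down-sampled observable series.

    ``t`` are the sample indices, ``x`` the observable values, ``steps``
    the MC step at the start of each aggregation block, and ``step_span``
    the number of raw MC steps covered by one sample.
    """

    t: np.ndarray
    x: np.ndarray
    downsample_factor: int = 1
    steps: np.ndarray | None = None
    step_span: int = 1
    trajectory_id: str = "0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        if len(self.t) != len(self.x):
            raise ValueError("t and x must have equal length")
        if self.downsample_factor < 1:
            raise ValueError("downsample factor must be >= 1")
        if self.steps is None:
            self.steps = self.t.copy()
        else:
            self.steps = np.asarray(self.steps, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.x)


def downsample(trajectory, factor: int, observable: str = "E") -> SignalWindow:
    """Block-mean aggregation of a trajectory observable.

    Consecutive windows of ``factor`` recorded samples are averaged;
    ``floor(n / factor)`` output samples are produced and the MC-step
    bookkeeping is preserved so segment boundaries map back to steps.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.asarray(getattr(trajectory, observable), dtype=float)
    steps = np.asarray(trajectory.steps, dtype=np.int64)
    n = len(x) // factor
    if n == 0:
        raise ValueError(f"factor {factor} exceeds series length {len(x)}")
    xb = x[: n * factor].reshape(n, factor).mean(axis=1)
    sb = steps[: n * factor : factor]
    record_every = int(steps[1] - steps[0]) if len(steps) > 1 else 1
    return SignalWindow(
        t=np.arange(n), x=xb, downsample_factor=factor, steps=sb,
        step_span=record_every * factor,
        trajectory_id=str(getattr(trajectory, "seed", "0")),
    )


@dataclass
class ChangePointPosterior:
    """Posterior summary of the trend change-point analysis."""

    cp_probability: np.ndarray
    n_cp_distribution: np.ndarray
    chosen_cp: np.ndarray
    min_duration: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class Segment:
    """One change-point-delimited interval [start, end) of a window.

    The stochastic coordinates are the segment mean, standard deviation
    (ddof=1) and trend (OLS slope per sample); ``Y`` is the log remaining
    time label attached later by the landscape pipeline.
    """

    trajectory_id: str
    start: int
    end: int
    start_step: int
    end_step: int
    mean: float
    std: float
    trend: float
    Y: float | None = None


# ---------------------------------------------------------------------------
# numba cost kernels (shared prefix sums; y standardized by the caller)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _prefixes(y):
    n = len(y)
    Sy = np.zeros(n + 1)
    Sy2 = np.zeros(n + 1)
    Sxy = np.zeros(n + 1)
    Sx = np.zeros(n + 1)
    Sx2 = np.zeros(n + 1)
    for i in range(n):
        Sy[i + 1] = Sy[i] + y[i]
        Sy2[i + 1] = Sy2[i] + y[i] * y[i]
        Sxy[i + 1] = Sxy[i] + i * y[i]
        Sx[i + 1] = Sx[i] + i
        Sx2[i + 1] = Sx2[i] + float(i) * i
    return Sy, Sy2, Sxy, Sx, Sx2


@njit(cache=True)
def _seg_moments(a, b, Sy, Sy2, Sxy, Sx, Sx2):
    """Centered moments of segment [a, b): (m, sy, syy_c, sxx_c, sxy_c)."""
    m = b - a
    sy = Sy[b] - Sy[a]
    sx = Sx[b] - Sx[a]
    xbar = sx / m
    ybar = sy / m
    sxx_c = (Sx2[b] - Sx2[a]) - m * xbar * xbar
    sxy_c = (Sxy[b] - Sxy[a]) - xbar * sy
    syy_c = (Sy2[b] - Sy2[a]) - m * ybar * ybar
    return m, sy, syy_c, sxx_c, sxy_c


@njit(cache=True)
def _rss_cost(a, b, Sy, Sy2, Sxy, Sx, Sx2):
    """Gaussian -log-likelihood (profile, per-segment variance) of a line fit."""
    m, _sy, syy_c, sxx_c, sxy_c = _seg_moments(a, b, Sy, Sy2, Sxy, Sx, Sx2)
    rss = syy_c
    if sxx_c > 0.0:
        rss = syy_c - sxy_c * sxy_c / sxx_c
    eps = 1e-12 * m  # y is standardized: floor keeps noiseless input finite
    if rss < eps:
        rss = eps
    return 0.5 * m * (math.log(rss / m) + 1.0)


@njit(cache=True)
def _log_marginal(a, b, s2, Sy, Sy2, Sxy, Sx, Sx2):
    """Log marginal likelihood of segment [a, b) under the NIG prior.

    Design is (intercept, centered slope scaled by the segment half-width).
    ``s2`` is a robust estimate of the within-segment noise variance (from
    the median squared first difference of the standardized signal); the
    noise variance has an InvGamma(2, s2) prior (mean s2) and the
    coefficients have prior covariance (sigma^2 / s2) * I, i.e. unit
    variance on the standardized scale regardless of the signal-to-noise
    ratio.
    """
    m, sy, syy_c, sxx_c, sxy_c = _seg_moments(a, b, Sy, Sy2, Sxy, Sx, Sx2)
    syy = syy_c + sy * sy / m
    hw = 0.5 * m
    sxpxp = sxx_c / (hw * hw)
    sxpy = sxy_c / hw
    a0 = 2.0
    b0 = s2
    an = a0 + 0.5 * m
    quad = sy * sy / (s2 + m) + sxpy * sxpy / (s2 + sxpxp)
    bn = b0 + 0.5 * (syy - quad)
    if bn < 1e-300:
        bn = 1e-300
    return (-0.5 * m * math.log(2.0 * math.pi)
            + 0.5 * (math.log(s2) - math.log(s2 + m))
            + 0.5 * (math.log(s2) - math.log(s2 + sxpxp))
            + a0 * math.log(b0) - an * math.log(bn)
            + math.lgamma(an) - math.lgamma(a0))


@njit(cache=True)
def _log_n_configs(n, k, d):
    """Log count of k change points in (0, n) with all segments >= d."""
    slack = n - (k + 1) * d
    if slack < 0:
        return -np.inf
    # C(slack + k, k)
    return (math.lgamma(slack + k + 1.0) - math.lgamma(k + 1.0)
            - math.lgamma(slack + 1.0))


@njit(cache=True)
def _dp_partition(y, d, beta, Sy, Sy2, Sxy, Sx, Sx2):
    """Optimal penalized partition; returns back-pointer array."""
    n = len(y)
    INF = np.inf
    dp = np.full(n + 1, INF)
    back = np.full(n + 1, -1, dtype=np.int64)
    dp[0] = 0.0
    for j in range(d, n + 1):
        best = INF
        arg = -1
        i = 0
        while i <= j - d:
            if dp[i] < INF:
                c = dp[i] + _rss_cost(i, j, Sy, Sy2, Sxy, Sx, Sx2)
                if i > 0:
                    c += beta
                if c < best:
                    best = c
                    arg = i
            i = d if i == 0 else i + 1
        dp[j] = best
        back[j] = arg
    return back


@njit(cache=True)
def _rng_u(state_box):
    """xorshift64* uniform in [0, 1)."""
    s = state_box[0]
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    state_box[0] = s
    return np.float64(s * np.uint64(2685821657736338717) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True)
def _bayes_chain(y, d, max_cp, n_burn, n_keep, rng_state, s2, cps_init,
                 Sy, Sy2, Sxy, Sx, Sx2, cp_counts, k_samples):
    """One reversible-jump chain over change-point configurations.

    Moves: birth/death of one change point, local shift, and a merge/split
    pair that exchanges two adjacent change points for one (and back) --
    the tunnel between a true jump and the two-point ramp that models it,
    which single-site moves cannot cross under the minimum-duration
    constraint.  The chain starts at the penalized-least-squares optimum.
    """
    n = len(y)
    bounds = np.zeros(max_cp + 3, dtype=np.int64)
    k = len(cps_init)
    for i in range(k):
        bounds[i + 1] = cps_init[i]
    bounds[k + 1] = n
    seg_lp = np.zeros(max_cp + 2)
    for g in range(k + 1):
        seg_lp[g] = _log_marginal(bounds[g], bounds[g + 1], s2,
                                  Sy, Sy2, Sxy, Sx, Sx2)

    box = np.empty(1, dtype=np.uint64)
    box[0] = rng_state
    total = n_burn + n_keep
    for it in range(total):
        u1 = _rng_u(box)
        u2 = _rng_u(box)
        u3 = _rng_u(box)

        if u1 < 0.25:  # birth
            if k < max_cp:
                A = 0
                for g in range(k + 1):
                    glen = bounds[g + 1] - bounds[g]
                    if glen >= 2 * d:
                        A += glen - 2 * d + 1
                if A > 0:
                    pick = int(u2 * A)
                    if pick >= A:
                        pick = A - 1
                    gsel = -1
                    p = -1
                    acc = 0
                    for g in range(k + 1):
                        glen = bounds[g + 1] - bounds[g]
                        room = glen - 2 * d + 1
                        if room > 0:
                            if pick < acc + room:
                                gsel = g
                                p = bounds[g] + d + (pick - acc)
                                break
                            acc += room
                    lo = bounds[gsel]
                    hi = bounds[gsel + 1]
                    old_lp = seg_lp[gsel]
                    lp1 = _log_marginal(lo, p, s2, Sy, Sy2, Sxy, Sx, Sx2)
                    lp2 = _log_marginal(p, hi, s2, Sy, Sy2, Sxy, Sx, Sx2)
                    dlog = (lp1 + lp2 - old_lp
                            + _log_n_configs(n, k, d)
                            - _log_n_configs(n, k + 1, d)
                            + math.log(A) - math.log(k + 1.0))
                    if dlog >= 0.0 or u3 < math.exp(dlog):
                        for idx in range(k + 1, gsel, -1):
                            bounds[idx + 1] = bounds[idx]
                            seg_lp[idx] = seg_lp[idx - 1]
                        bounds[gsel + 1] = p
                        seg_lp[gsel] = lp1
                        seg_lp[gsel + 1] = lp2
                        k += 1
        elif u1 < 0.50:  # death
            if k > 0:
                j = int(u2 * k)
                if j >= k:
                    j = k - 1
                lo = bounds[j]
                hi = bounds[j + 2]
                lp_merge = _log_marginal(lo, hi, s2, Sy, Sy2, Sxy, Sx, Sx2)
                # admissible birth positions in the post-death state
                A = 0
                for g in range(k):
                    if g == j:
                        glen = hi - lo
                    elif g < j:
                        glen = bounds[g + 1] - bounds[g]
                    else:
                        glen = bounds[g + 2] - bounds[g + 1]
                    if glen >= 2 * d:
                        A += glen - 2 * d + 1
                dlog = (lp_merge - seg_lp[j] - seg_lp[j + 1]
                        + _log_n_configs(n, k, d)
                        - _log_n_configs(n, k - 1, d)
                        + math.log(float(k)) - math.log(float(A)))
                if dlog >= 0.0 or u3 < math.exp(dlog):
                    for idx in range(j + 1, k + 1):
                        bounds[idx] = bounds[idx + 1]
                    for idx in range(j + 1, k):
                        seg_lp[idx] = seg_lp[idx + 1]
                    seg_lp[j] = lp_merge
                    k -= 1
        elif u1 < 0.80:  # shift
            if k > 0:
                j = int(u2 * k)
                if j >= k:
                    j = k - 1
                lo = bounds[j]
                hi = bounds[j + 2]
                span = hi - lo - 2 * d + 1
                if span > 0:
                    u4 = _rng_u(box)
                    p = lo + d + int(u4 * span)
                    if p >= hi - d + 1:
                        p = hi - d
                    if p != bounds[j + 1]:
                        lp1 = _log_marginal(lo, p, s2, Sy, Sy2, Sxy, Sx, Sx2)
                        lp2 = _log_marginal(p, hi, s2, Sy, Sy2, Sxy, Sx, Sx2)
                        dlog = lp1 + lp2 - seg_lp[j] - seg_lp[j + 1]
                        if dlog >= 0.0 or u3 < math.exp(dlog):
                            bounds[j + 1] = p
                            seg_lp[j] = lp1
                            seg_lp[j + 1] = lp2
        elif u1 < 0.90:  # merge two adjacent change points into one
            if k >= 2:
                j = int(u2 * (k - 1))
                if j >= k - 1:
                    j = k - 2
                lo = bounds[j]
                hi = bounds[j + 3]
                W = hi - lo
                A_m = W - 2 * d + 1
                S = W - 3 * d
                T = 0.5 * (S + 1.0) * (S + 2.0)  # valid (q1, q2) split pairs
                u4 = _rng_u(box)
                p = lo + d + int(u4 * A_m)
                if p >= hi - d + 1:
                    p = hi - d
                lp1 = _log_marginal(lo, p, s2, Sy, Sy2, Sxy, Sx, Sx2)
                lp2 = _log_marginal(p, hi, s2, Sy, Sy2, Sxy, Sx, Sx2)
                dlog = (lp1 + lp2 - seg_lp[j] - seg_lp[j + 1] - seg_lp[j + 2]
                        + _log_n_configs(n, k, d)
                        - _log_n_configs(n, k - 1, d)
                        + math.log(A_m) - math.log(T))
                if dlog >= 0.0 or u3 < math.exp(dlog):
                    for idx in range(j + 1, k):
                        bounds[idx + 1] = bounds[idx + 2]
                    for idx in range(j + 2, k):
                        seg_lp[idx] = seg_lp[idx + 1]
                    bounds[j + 1] = p
                    seg_lp[j] = lp1
                    seg_lp[j + 1] = lp2
                    k -= 1
        else:  # split one change point into two
            if 1 <= k < max_cp:
                j = int(u2 * k)
                if j >= k:
                    j = k - 1
                lo = bounds[j]
                hi = bounds[j + 2]
                W = hi - lo
                S = W - 3 * d
                if S >= 0:
                    A_m = W - 2 * d + 1
                    T = 0.5 * (S + 1.0) * (S + 2.0)
                    # (u_a, u_b) uniform over the triangle u_a + u_b <= S
                    ua = 0
                    ub = 0
                    while True:
                        ua = int(_rng_u(box) * (S + 1))
                        ub = int(_rng_u(box) * (S + 1))
                        if ua + ub <= S:
                            break
                    q1 = lo + d + ua
                    q2 = q1 + d + ub
                    lp1 = _log_marginal(lo, q1, s2, Sy, Sy2, Sxy, Sx, Sx2)
                    lp2 = _log_marginal(q1, q2, s2, Sy, Sy2, Sxy, Sx, Sx2)
                    lp3 = _log_marginal(q2, hi, s2, Sy, Sy2, Sxy, Sx, Sx2)
                    dlog = (lp1 + lp2 + lp3 - seg_lp[j] - seg_lp[j + 1]
                            + _log_n_configs(n, k, d)
                            - _log_n_configs(n, k + 1, d)
                            + math.log(T) - math.log(A_m))
                    if dlog >= 0.0 or u3 < math.exp(dlog):
                        for idx in range(k + 1, j + 1, -1):
                            bounds[idx + 1] = bounds[idx]
                        for idx in range(k, j + 1, -1):
                            seg_lp[idx + 1] = seg_lp[idx]
                        bounds[j + 1] = q1
                        bounds[j + 2] = q2
                        seg_lp[j] = lp1
                        seg_lp[j + 1] = lp2
                        seg_lp[j + 2] = lp3
                        k += 1

        if it >= n_burn:
            k_samples[it - n_burn] = k
            for j in range(k):
                cp_counts[bounds[j + 1]] += 1
    return box[0]


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sd = x.std()
    return (x - mu) / sd if sd > 0 else x - mu


def _min_duration(n: int, min_seg_frac: float) -> int:
    return max(2, int(min_seg_frac * n))


def detect_changepoints(window: SignalWindow, min_seg_frac: float = 0.01,
                        max_cp: int = 99, backend: str = "bayes",
                        n_chains: int = 4, n_burn: int = 5_000,
                        n_keep: int = 20_000,
                        seed: int = 0) -> ChangePointPosterior:
    """Posterior over trend change points of a signal window.

    Segments must last at least ``floor(min_seg_frac * n)`` samples (one
    percent of the series by default).  The ``bayes`` backend samples the
    posterior with ``n_chains`` reversible-jump chains; ``pls`` solves the
    penalized piecewise-linear least-squares problem exactly, returning a
    degenerate posterior concentrated on its solution.
    """
    n = window.n
    d = _min_duration(n, min_seg_frac)
    if n < 2 * d:
        raise ValueError(
            f"window length {n} too short for minimum duration {d}")
    y = _standardize(window.x)
    Sy, Sy2, Sxy, Sx, Sx2 = _prefixes(y)

    if backend == "pls":
        beta = 2.0 * math.log(n)
        while True:
            back = _dp_partition(y, d, beta, Sy, Sy2, Sxy, Sx, Sx2)
            cps = []
            j = n
            while back[j] > 0:
                cps.append(int(back[j]))
                j = back[j]
            cps = np.array(sorted(cps), dtype=np.int64)
            if len(cps) <= max_cp:
                break
            beta *= 2.0  # escalate the penalty until the cap is respected
        cp_prob = np.zeros(n)
        cp_prob[cps] = 1.0
        ncp = np.zeros(len(cps) + 1)
        ncp[len(cps)] = 1.0
        return ChangePointPosterior(
            cp_probability=cp_prob, n_cp_distribution=ncp, chosen_cp=cps,
            min_duration=d, diagnostics={"backend": "pls", "penalty": beta})
    if backend != "bayes":
        raise ValueError(f"unknown backend {backend!r}")

    max_cp_eff = min(max_cp, n // d - 1)
    dy = np.diff(y)
    # robust noise variance: median of squared first differences, debiased
    # by the chi^2_1 median (0.4549), halved for the difference of two values
    s2 = max(float(np.median(dy * dy)) / (2.0 * 0.4549), 1e-10)

    # start every chain at the penalized-least-squares optimum (MAP-like)
    back = _dp_partition(y, d, 2.0 * math.log(n), Sy, Sy2, Sxy, Sx, Sx2)
    init = []
    j = n
    while back[j] > 0:
        init.append(int(back[j]))
        j = back[j]
    cps_init = np.array(sorted(init), dtype=np.int64)
    if len(cps_init) > max_cp_eff:
        cps_init = cps_init[:0]

    cp_counts = np.zeros(n, dtype=np.int64)
    k_all = []
    chain_means = []
    for c in range(n_chains):
        k_samples = np.zeros(n_keep, dtype=np.int64)
        rng0 = np.uint64(0x9E3779B97F4A7C15) ^ (np.uint64(seed) * np.uint64(2654435761) + np.uint64(c + 1))
        if rng0 == 0:
            rng0 = np.uint64(1)
        _bayes_chain(y, d, max_cp_eff, n_burn, n_keep, rng0, s2, cps_init,
                     Sy, Sy2, Sxy, Sx, Sx2, cp_counts, k_samples)
        k_all.append(k_samples)
        chain_means.append(k_samples.mean())
    k_all = np.concatenate(k_all)
    cp_prob = cp_counts / (n_chains * n_keep)
    n_cp_dist = np.bincount(k_all, minlength=max_cp_eff + 1).astype(float)
    n_cp_dist /= n_cp_dist.sum()
    k_star = int(np.median(k_all))

    chosen: list[int] = []
    for p in np.argsort(cp_prob)[::-1]:
        if len(chosen) == k_star or cp_prob[p] == 0.0:
            break
        p = int(p)
        if p < d or p > n - d:
            continue
        if all(abs(p - q) >= d for q in chosen):
            chosen.append(p)
    if len(chosen) < k_star:
        warnings.warn(
            f"only {len(chosen)} admissible probability peaks for the "
            f"posterior-median count {k_star}", stacklevel=2)
    spread = float(np.std(chain_means))
    diagnostics = {"backend": "bayes", "chain_mean_k": chain_means,
                   "between_chain_std_k": spread,
                   "mixing_warning": spread > 1.0}
    if spread > 1.0:
        warnings.warn("between-chain spread of the change-point count "
                      f"is {spread:.2f}; chains may not have mixed",
                      stacklevel=2)
    return ChangePointPosterior(
        cp_probability=cp_prob, n_cp_distribution=n_cp_dist,
        chosen_cp=np.array(sorted(chosen), dtype=np.int64),
        min_duration=d, diagnostics=diagnostics)


def segment_statistics(x: np.ndarray) -> tuple[float, float, float]:
    """(mean, std with ddof=1, OLS slope per sample) of one segment."""
    x = np.asarray(x, dtype=float)
    m = len(x)
    mean = float(x.mean())
    std = float(x.std(ddof=1)) if m > 1 else 0.0
    if m > 1:
        t = np.arange(m, dtype=float)
        tc = t - t.mean()
        trend = float((tc * (x - mean)).sum() / (tc * tc).sum())
    else:
        trend = 0.0
    return mean, std, trend


def extract_segments(window: SignalWindow,
                     posterior: ChangePointPosterior) -> list[Segment]:
    """Tile the window into segments at the chosen change points."""
    n = window.n
    bounds = np.concatenate(([0], np.asarray(posterior.chosen_cp, dtype=np.int64), [n]))
    if np.any(np.diff(bounds) < posterior.min_duration):
        raise ValueError("chosen change points violate the minimum duration")
    segments = []
    span = window.step_span
    for a, b in zip(bounds[:-1], bounds[1:]):
        a, b = int(a), int(b)
        mean, std, trend = segment_statistics(window.x[a:b])
        segments.append(Segment(
            trajectory_id=window.trajectory_id,
            start=a, end=b,
            start_step=int(window.steps[a]),
            end_step=int(window.steps[b - 1]) + span,
            mean=mean, std=std, trend=trend,
        ))
    return segments
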