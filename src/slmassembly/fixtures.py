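"""Deterministic synthetic-input generators with known ground truth.

Every downstream stage can be exercised without any lattice simulation:
piecewise-trend signals with known change points for the segmentation
stage, segment datasets with a declared response surface for the landscape
stage, and log-normal first-assembly-time samples for the statistics
stage.  Fixture randomness uses numpy's PCG64 generator family, a stream
family distinct from the simulator's internal PCG32, so tests cannot
couple accidentally to simulator seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .assembly_stats import AssemblyTimeSample
from .segmentation import Segment, SignalWindow

__all__ = [
    "PiecewiseSpec", "LandscapeSpec", "AssemblyTimesSpec",
    "make_piecewise_signal", "make_landscape_dataset", "make_assembly_times",
]


@dataclass(frozen=True)
class PiecewiseSpec:
    """Concatenated linear-trend segments with iid Gaussian noise.

    ``durations`` are the per-segment sample counts; ``means`` the segment
    value at its midpoint; ``trends`` the slope per sample; ``sigma`` the
    common noise standard deviation.
    """

    durations: tuple[int, ...]
    means: tuple[float, ...]
    trends: tuple[float, ...]
    sigma: float = 1.0
    seed: int = 0
    min_duration: int = 2

    def __post_init__(self) -> None:
        if not (len(self.durations) == len(self.means) == len(self.trends)):
            raise ValueError("durations, means and trends must align")
        if any(d < self.min_duration for d in self.durations):
            raise ValueError("segment durations below the declared minimum")


def make_piecewise_signal(spec: PiecewiseSpec
                          ) -> tuple[SignalWindow, np.ndarray]:
    """Generate the signal; returns (window, true change-point indices)."""
    rng = np.random.default_rng(spec.seed)
    parts = []
    for dur, mean, trend in zip(spec.durations, spec.means, spec.trends):
        t = np.arange(dur) - (dur - 1) / 2.0
        parts.append(mean + trend * t + rng.normal(0.0, spec.sigma, dur))
    x = np.concatenate(parts)
    cps = np.cumsum(spec.durations)[:-1].astype(np.int64)
    window = SignalWindow(t=np.arange(len(x)), x=x, trajectory_id="fixture")
    return window, cps


_W = np.array([[1.0, 0.6, -0.5],    # latent axis 1 in coordinate space
               [0.2, -0.8, -0.6]])  # latent axis 2


@dataclass(frozen=True)
class LandscapeSpec:
    """Segments with correlated 3-D stochastic coordinates and Y = f(c)+noise.

    The coordinates are driven by two latent Gaussian factors (plus a small
    isotropic jitter ``coord_eps``), mirroring the strong correlation of
    mean/std/trend in real segment data: the cloud is close to a plane, so
    the first two principal components recover the informative subspace
    and the declared response is a well-defined smooth function of the
    coordinates (through the pseudo-inverse of the latent mixing).
    """

    n: int = 500
    coord_mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    coord_eps: float = 0.05
    noise: float = 0.0
    seed: int = 0
    g: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def response(self, coords: np.ndarray) -> np.ndarray:
        """Ground-truth label surface as a function of the coordinates."""
        latent = (np.atleast_2d(coords) - self.coord_mean) @ np.linalg.pinv(_W)
        a, b = latent[:, 0], latent[:, 1]
        if self.g is not None:
            return self.g(a, b)
        return 2.0 + 1.5 * a - 1.0 * b + 0.3 * a * b


def make_landscape_dataset(spec: LandscapeSpec
                           ) -> tuple[list[Segment], Callable]:
    """Segments with known response surface; returns (segments, truth f)."""
    if spec.n < 10:
        raise ValueError("need n >= 10 segments")
    rng = np.random.default_rng(spec.seed)
    latent = rng.normal(0.0, 1.0, size=(spec.n, 2))
    coords = (np.asarray(spec.coord_mean) + latent @ _W
              + rng.normal(0.0, spec.coord_eps, size=(spec.n, 3)))
    y = spec.response(coords) + rng.normal(0.0, spec.noise, spec.n)
    segments = [
        Segment(trajectory_id="fixture", start=i, end=i + 1,
                start_step=i, end_step=i + 1,
                mean=float(c[0]), std=float(c[1]), trend=float(c[2]),
                Y=float(val))
        for i, (c, val) in enumerate(zip(coords, y))
    ]
    return segments, spec.response


@dataclass(frozen=True)
class AssemblyTimesSpec:
    """Log-normal first-assembly times right-censored at a cap."""

    n: int = 1000
    mu: float = 10.0       # mean of log T_FAS
    sigma: float = 1.0     # std of log T_FAS
    cap: float = np.inf
    seed: int = 0


def make_assembly_times(spec: AssemblyTimesSpec) -> AssemblyTimeSample:
    rng = np.random.default_rng(spec.seed)
    raw = np.exp(rng.normal(spec.mu, spec.sigma, spec.n))
    censored = raw >= spec.cap
    values = np.where(censored, spec.cap, raw)
    cap = spec.cap if np.isfinite(spec.cap) else float(raw.max() * 2)
    return AssemblyTimeSample(values=values, censored=censored,
                              T_cap=int(np.ceil(cap)))
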