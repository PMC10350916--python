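"""First-assembly-time statistics.

Realizations that never assemble within the step cap are right-censored at
T_cap: they participate in order statistics at the cap (so the median is a
lower bound once more than half the sample is censored) but are excluded
from density fits.  The spread summary sigma is the log-scale half-distance
between the 16th and 84th percentiles, matching a log-normal standard
deviation when the sample is log-normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AssemblyTimeSample", "FirstAssemblyStats", "ExpFitResult",
    "summarize_first_assembly", "hybrid_histogram", "fit_density",
    "fit_exponential_trend",
]


class NoAssemblyError(ValueError):
    """Every realization in the sample is censored."""


class InsufficientDataError(ValueError):
    """Too few non-censored values for a density fit."""


@dataclass
class AssemblyTimeSample:
    """First-assembly times T_FAS with per-realization censoring flags."""

    values: np.ndarray
    censored: np.ndarray
    T_cap: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.values.shape != self.censored.shape:
            raise ValueError("values and censored must have equal length")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def censoring_fraction(self) -> float:
        return float(self.censored.mean()) if self.n else 0.0

    def effective_values(self) -> np.ndarray:
        """Values with censored realizations pinned at T_cap."""
        out = self.values.copy()
        out[self.censored] = self.T_cap
        return out

    def uncensored(self) -> np.ndarray:
        return self.values[~self.censored]


@dataclass
class FirstAssemblyStats:
    """Median/percentile summary and log-normal fit of a T_FAS sample."""

    Md: float
    sigma: float
    p16: float
    p84: float
    fit_mu: float
    fit_sigma: float
    censoring_fraction: float
    median_is_lower_bound: bool


def summarize_first_assembly(sample: AssemblyTimeSample) -> FirstAssemblyStats:
    """Median, 16th/84th percentiles, log-scale sigma, and log-normal fit.

    Order statistics include censored realizations at T_cap; the
    log-normal parameters (fit_mu, fit_sigma) are percentile-based:
    fit_mu = log Md and fit_sigma = (log p84 - log p16) / 2.
    """
    if sample.n == 0 or np.all(sample.censored):
        raise NoAssemblyError("no realization assembled within T_cap")
    vals = sample.effective_values()
    p16, Md, p84 = np.percentile(vals, [16, 50, 84])
    sigma = (np.log(p84) - np.log(p16)) / 2.0
    frac = sample.censoring_fraction
    lower_bound = frac > 0.5
    if lower_bound:
        warnings.warn(
            f"{frac:.0%} of realizations censored: median is a lower bound",
            stacklevel=2)
    return FirstAssemblyStats(
        Md=float(Md), sigma=float(sigma), p16=float(p16), p84=float(p84),
        fit_mu=float(np.log(Md)), fit_sigma=float(sigma),
        censoring_fraction=frac, median_is_lower_bound=lower_bound)


def scott_bin_width(x: np.ndarray) -> float:
    """Scott's rule bin width 3.49 * s * n^(-1/3)."""
    x = np.asarray(x, dtype=float)
    return 3.49 * x.std(ddof=1) * len(x) ** (-1.0 / 3.0)


def hybrid_histogram(sample: AssemblyTimeSample,
                     n_log_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with log-equal bins below the median and Scott bins above.

    Below the sample median the bin edges are equally spaced in log10;
    above it they are linear with the Scott width; a single terminal
    overflow bin at T_cap captures every censored realization.  Returns
    (counts, edges) with counts summing to the sample size.
    """
    if sample.n == 0:
        raise ValueError("empty sample")
    obs = sample.uncensored()
    n_cens = int(sample.censored.sum())
    cap = float(sample.T_cap)
    if len(obs) == 0:
        edges = np.array([cap, np.nextafter(cap, np.inf)])
        return np.array([n_cens]), edges
    vals = sample.effective_values()
    Md = float(np.median(vals))
    lo = float(obs.min())
    below = obs[obs < Md]
    above = obs[(obs >= Md) & (obs < cap)]
    edges: list[float] = []
    if len(below) and lo < Md:
        edges.extend(np.logspace(np.log10(max(lo, 1.0)),
                                 np.log10(Md), n_log_bins + 1)[:-1])
    edges.append(Md)
    if len(above):
        hi = float(above.max())
        w = scott_bin_width(above) if len(above) > 1 else max(hi - Md, 1.0)
        if w <= 0:
            w = max(hi - Md, 1.0)
        k = max(1, int(np.ceil((hi - Md) / w)))
        edges.extend(Md + w * np.arange(1, k + 1))
    if edges[-1] < cap:
        edges.append(cap)
    edges.append(np.nextafter(cap, np.inf))  # terminal censored bin [cap, cap]
    edges = np.unique(np.asarray(edges, dtype=float))
    edges[0] = min(edges[0], lo)  # guard the log/exp round-trip of logspace
    at_cap = vals >= cap
    counts, _ = np.histogram(vals[~at_cap], bins=edges)
    counts[-1] += int(at_cap.sum())
    assert counts.sum() == sample.n
    return counts, edges


def fit_density(sample: AssemblyTimeSample, method: str = "log-normal",
                min_values: int = 30):
    """Normalized density on (0, inf) fitted to the non-censored values.

    ``method='log-normal'`` fits by the moments of the log values;
    ``method='kde-positive'`` builds a Gaussian KDE of the log values and
    maps it back with the 1/x Jacobian.  Returns a vectorized callable
    that is zero at and below x = 0.
    """
    obs = sample.uncensored()
    if len(obs) < min_values:
        raise InsufficientDataError(
            f"need >= {min_values} non-censored values, got {len(obs)}")
    logs = np.log(obs)
    if method == "log-normal":
        mu, sig = logs.mean(), logs.std(ddof=1)
        def density(x):
            x = np.asarray(x, dtype=float)
            out = np.zeros_like(x)
            pos = x > 0
            out[pos] = stats.lognorm.pdf(x[pos], s=sig, scale=np.exp(mu))
            return out
    elif method == "kde-positive":
        kde = stats.gaussian_kde(logs)
        def density(x):
            x = np.asarray(x, dtype=float)
            out = np.zeros_like(x)
            pos = x > 0
            out[pos] = kde(np.log(x[pos])) / x[pos]
            return out
    else:
        raise ValueError(f"unknown density method {method!r}")
    return density


@dataclass
class ExpFitResult:
    """Parameters of the decay fit A * exp(-b * x) + C."""

    A: float
    b: float
    C: float
    covariance: np.ndarray
    residuals: np.ndarray
    degenerate: bool = False


def fit_exponential_trend(x: np.ndarray, y: np.ndarray) -> ExpFitResult:
    """Least-squares fit of A * exp(-b * x) + C to (x, y).

    Mirrors the exponential-decay summaries of the first-assembly median
    and sigma versus the drive.  Near-constant data are flagged degenerate
    (b unidentifiable) with A ~ 0 and C at the data mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for the exponential fit")
    spread = y.max() - y.min()
    scale = max(abs(y).max(), 1.0)
    if spread <= 1e-12 * scale:
        return ExpFitResult(A=0.0, b=0.0, C=float(y.mean()),
                            covariance=np.full((3, 3), np.nan),
                            residuals=y - y.mean(), degenerate=True)

    def model(xx, A, b, C):
        return A * np.exp(-b * xx) + C

    xr = x.max() - x.min() or 1.0
    p0 = (y[np.argmin(x)] - y.min(), 1.0 / xr, y.min())
    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20_000)
    except RuntimeError as err:
        raise RuntimeError(f"exponential fit failed to converge: {err}") from err
    res = y - model(x, *popt)
    return ExpFitResult(A=float(popt[0]), b=float(popt[1]), C=float(popt[2]),
                        covariance=pcov, residuals=res)
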