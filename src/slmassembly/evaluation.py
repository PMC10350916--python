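"""Performance evaluation of the landscape predictor.

The bias-corrected predictor is compared against the naive mean predictor
(the mean log remaining time of the pooled training+CV segments) through
the Pearson correlation with the true test labels and through weighted
Kullback-Leibler divergences of per-bin error distributions: the test data
are binned by the predicted value (width 0.5 on the log scale), the error
densities Delta_Y_hat = Y_hat - Y_test and the data spread
Delta_Y_test = <Y_test> - Y_test are KDE-estimated per bin, and the KLD of
the estimator-error density against the data density is averaged over bins
with the bin weights.  Smaller KLD means a better predictor; the headline
comparison is KLD_BC < KLD_M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport", "mean_predictor", "pearson_r", "bin_by_prediction",
    "kld", "evaluate",
]

_EPS = 1e-12  # density floor before the log


def mean_predictor(training_labels: np.ndarray) -> float:
    """Naive guess: the mean of Y over the pooled training + CV segments."""
    y = np.asarray(training_labels, dtype=float)
    if y.size == 0:
        raise ValueError("empty training label set")
    return float(y.mean())


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation and its two-sided t-distribution p-value."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 3:
        raise ValueError("need two equal-length arrays with >= 3 points")
    if y_true.std() == 0 or y_pred.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(y_true, y_pred)
    return float(r), float(p)


@dataclass
class PredictionBin:
    """One bin of test points grouped by predicted value."""

    center: float
    index: np.ndarray
    weight: float
    Y_test: np.ndarray
    Y_hat: np.ndarray


def bin_by_prediction(Y_test: np.ndarray, Y_hat: np.ndarray,
                      width: float = 0.5) -> list[PredictionBin]:
    """Group test points into bins of Y_hat aligned to multiples of width."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    Y_test = np.asarray(Y_test, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    n = len(Y_hat)
    keys = np.floor(Y_hat / width).astype(np.int64)
    bins = []
    for b in np.unique(keys):
        idx = np.flatnonzero(keys == b)
        bins.append(PredictionBin(
            center=(b + 0.5) * width, index=idx, weight=len(idx) / n,
            Y_test=Y_test[idx], Y_hat=Y_hat[idx]))
    return bins


def kld(f1, f2, grid: np.ndarray | None = None,
        support: tuple[float, float] | None = None,
        n_grid: int = 4001) -> float:
    """Kullback-Leibler divergence integral f1 log(f1/f2) dx.

    ``f1`` and ``f2`` are density callables (or arrays sampled on ``grid``).
    The quadrature uses Simpson's rule on a shared dense grid; densities
    are floored at a small epsilon before the log, and a divergence beyond
    the floor's reach is reported as inf.
    """
    if grid is None:
        if support is None:
            raise ValueError("provide either grid or support")
        grid = np.linspace(support[0], support[1], n_grid)
    g1 = f1(grid) if callable(f1) else np.asarray(f1, dtype=float)
    g2 = f2(grid) if callable(f2) else np.asarray(f2, dtype=float)
    g1 = np.clip(g1, 0.0, None)
    mass1 = integrate.simpson(g1, x=grid)
    if mass1 <= 0:
        raise ValueError("f1 has no mass on the integration grid")
    mismatched = integrate.simpson(np.where(g2 <= _EPS, g1, 0.0), x=grid)
    if mismatched > 0.5 * mass1:
        # most of f1's mass lies where f2 vanishes even after flooring
        logger.warning("support mismatch beyond regularization; KLD infinite")
        return float("inf")
    integrand = np.where(g1 > 0, g1 * np.log(np.maximum(g1, _EPS)
                                             / np.maximum(g2, _EPS)), 0.0)
    return float(integrate.simpson(integrand, x=grid))


def _kde_density(values: np.ndarray):
    sd = values.std(ddof=1)
    if sd == 0:  # degenerate point mass: narrow Gaussian at the value
        mu = float(values.mean())
        return lambda x: stats.norm.pdf(x, loc=mu, scale=1e-3)
    return stats.gaussian_kde(values)


@dataclass
class EvaluationReport:
    """Pearson R, weighted KLDs and per-bin error summaries."""

    R: float
    p_value: float
    KLD_M: float
    KLD_BC: float
    n_test: int
    bins: list[dict] = field(default_factory=list)
    direction: str = "estimator_vs_data"

    def to_dict(self) -> dict:
        return {"R": self.R, "p_value": self.p_value, "KLD_M": self.KLD_M,
                "KLD_BC": self.KLD_BC, "n_test": self.n_test,
                "direction": self.direction, "bins": self.bins}


def evaluate(result, bin_width: float = 0.5, min_weight: float = 0.01,
             min_members: int = 5,
             direction: str = "estimator_vs_data") -> EvaluationReport:
    """Evaluate a PredictionResult against its held-out test labels.

    Per bin of the bias-corrected prediction, KDE densities of the error
    distributions Delta_Y_hat_BC, Delta_Y_hat_M and of the data spread
    Delta_Y_test are compared by KLD; bins carrying less than ``min_weight``
    of the test mass or fewer than ``min_members`` points are excluded and
    the remaining weights renormalized.  ``direction`` selects the KLD
    argument order; the default follows KLD(error-density ‖ data-density).
    """
    y_test = np.asarray(result.Y_test, dtype=float)
    y_bc = np.asarray(result.Y_hat_BC, dtype=float)
    y_m = float(result.Y_hat_M)
    if y_bc.std() == 0:  # degenerate constant predictor: R undefined
        R, p = float("nan"), float("nan")
    else:
        R, p = pearson_r(y_test, y_bc)

    bins = bin_by_prediction(y_test, y_bc, bin_width)
    kept, skipped = [], 0
    for b in bins:
        if b.weight < min_weight or len(b.index) < min_members:
            skipped += 1
            continue
        kept.append(b)
    if skipped:
        logger.info("excluded %d low-occupancy bins from the KLD average",
                    skipped)
    if not kept:
        raise ValueError("no bin carries enough test points for evaluation")
    wsum = sum(b.weight for b in kept)

    kld_m = kld_bc = 0.0
    detail = []
    for b in kept:
        d_data = b.Y_test.mean() - b.Y_test
        d_bc = b.Y_hat - b.Y_test
        d_m = y_m - b.Y_test
        all_vals = np.concatenate([d_data, d_bc, d_m])
        span = max(all_vals.std(), 0.1)
        grid = np.linspace(all_vals.min() - 4 * span,
                           all_vals.max() + 4 * span, 2001)
        f_data = _kde_density(d_data)
        f_bc = _kde_density(d_bc)
        f_m = _kde_density(d_m)
        if direction == "estimator_vs_data":
            k_bc = kld(f_bc, f_data, grid=grid)
            k_m = kld(f_m, f_data, grid=grid)
        elif direction == "data_vs_estimator":
            k_bc = kld(f_data, f_bc, grid=grid)
            k_m = kld(f_data, f_m, grid=grid)
        else:
            raise ValueError(f"unknown KLD direction {direction!r}")
        w = b.weight / wsum
        kld_bc += w * k_bc
        kld_m += w * k_m
        detail.append({
            "center": b.center, "weight": w, "n": int(len(b.index)),
            "kld_M": k_m, "kld_BC": k_bc,
            "mean_abs_err_M": float(np.abs(d_m).mean()),
            "mean_abs_err_BC": float(np.abs(d_bc).mean()),
        })
    return EvaluationReport(R=R, p_value=p, KLD_M=float(kld_m),
                            KLD_BC=float(kld_bc), n_test=len(y_test),
                            bins=detail, direction=direction)
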