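"""The stochastic landscape method (SLM).

Pre-assembly trajectory segments are summarized by their stochastic
coordinates (mean, standard deviation, trend of the segmented observable)
and labeled with the natural log of the remaining time to the first
assembly, Y = log(t_r), t_r = T_FAS - t evaluated at the segment end.  The
coordinates are z-scored jointly over the whole labeled pool, projected on
their first two principal components, and a smoothed, triangulated surface
over the PC plane maps any query point to a predicted Y.  K repeated
train/cross-validation re-splits estimate the prediction bias as a function
of the predicted value; the final landscape built on the pooled
training+CV data, minus the interpolated bias, yields the bias-corrected
predictor evaluated on a held-out test set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError, cKDTree
from sklearn.decomposition import PCA

from .segmentation import (
    Segment,
    SignalWindow,
    detect_changepoints,
    downsample,
    extract_segments,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentDataset", "Landscape", "PredictionResult", "SLMConfig",
    "label_segments", "normalize_and_project", "build_landscape", "predict",
    "cv_bias_correction", "run_slm", "segments_to_frame", "frame_to_segments",
]

COORD_NAMES = ("mean", "std", "trend")


class UsabilityError(RuntimeError):
    """Too few trajectories contain an assembly event to train the SLM."""


def label_segments(segments: list[Segment], trajectory) -> list[Segment]:
    """Attach Y = log(T_FAS - end_step) to segments ending before assembly.

    Segments ending at or after T_FAS are discarded; a censored trajectory
    contributes nothing (its first-assembly time is unknown).
    """
    if getattr(trajectory, "censored", False):
        logger.info("trajectory %s censored; all segments excluded",
                    getattr(trajectory, "seed", "?"))
        return []
    t_fas = trajectory.T_FAS
    out = []
    for seg in segments:
        t_r = t_fas - seg.end_step
        if t_r > 0:
            seg.Y = float(np.log(t_r))
            out.append(seg)
    return out


@dataclass
class SegmentDataset:
    """Labeled pre-assembly segments with normalization, PCA and splits."""

    segments: list[Segment]
    partition: np.ndarray | None = None       # values in {"train","cv","test"}
    norm_mean: np.ndarray | None = None
    norm_std: np.ndarray | None = None
    loadings: np.ndarray | None = None        # (3, 2)
    explained_variance: np.ndarray | None = None
    scores: np.ndarray | None = None          # (n, 2)

    @property
    def n(self) -> int:
        return len(self.segments)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([[s.mean, s.std, s.trend] for s in self.segments])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.Y for s in self.segments], dtype=float)

    def mask(self, which: str) -> np.ndarray:
        return self.partition == which


def normalize_and_project(dataset: SegmentDataset) -> SegmentDataset:
    """Z-score the stochastic coordinates jointly and project on 2 PCs.

    The normalization statistics and PCA loadings are stored on the
    dataset so that new segments can be projected consistently.
    """
    X = dataset.coordinates
    if dataset.n < 3:
        raise ValueError("need at least 3 segments for PCA")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    for name, s in zip(COORD_NAMES, sd):
        if s == 0:
            raise ValueError(f"coordinate {name!r} has zero variance")
    Z = (X - mu) / sd
    pca = PCA(n_components=2)
    scores = pca.fit_transform(Z)
    dataset.norm_mean = mu
    dataset.norm_std = sd
    dataset.loadings = pca.components_.T  # (3, 2)
    dataset.explained_variance = pca.explained_variance_
    dataset.scores = scores
    return dataset


def scott_bandwidth_2d(scores: np.ndarray) -> float:
    """Scott's-rule bandwidth for the 2-D PC scores (mean of per-axis h)."""
    n = len(scores)
    return float(scores.std(axis=0, ddof=1).mean() * n ** (-1.0 / 6.0))


@dataclass
class Landscape:
    """Triangulated, kernel-smoothed surface Y(PC1, PC2)."""

    nodes: np.ndarray
    node_values: np.ndarray
    smoothing: float
    triangulation: Delaunay | None = None
    _interp: LinearNDInterpolator | None = field(default=None, repr=False)
    _tree: cKDTree | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.triangulation is None:
            try:
                self.triangulation = Delaunay(self.nodes)
            except QhullError as err:
                raise ValueError(
                    "training points are degenerate (collinear); cannot "
                    "triangulate the landscape") from err
        self._interp = LinearNDInterpolator(self.triangulation,
                                            self.node_values)
        self._tree = cKDTree(self.nodes)

    @property
    def hull(self):
        return self.triangulation.convex_hull


def build_landscape(scores: np.ndarray, labels: np.ndarray,
                    bandwidth: float | None = None) -> Landscape:
    """Delaunay triangulation of the training scores with smoothed values.

    Node values are Gaussian-kernel (Nadaraya-Watson) smoothed labels with
    bandwidth ``h`` (Scott's rule on the scores by default); the landscape
    function is piecewise-linear interpolation over the simplices.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(scores) < 3:
        raise ValueError("need at least 3 training points")
    # merge exactly duplicated nodes (qhull dislikes them)
    uniq, inv = np.unique(scores.round(12), axis=0, return_inverse=True)
    if len(uniq) < len(scores):
        vals = np.zeros(len(uniq))
        cnt = np.zeros(len(uniq))
        np.add.at(vals, inv, labels)
        np.add.at(cnt, inv, 1)
        scores, labels = uniq, vals / cnt
    h = scott_bandwidth_2d(scores) if bandwidth is None else float(bandwidth)
    if h > 0:
        d2 = ((scores[:, None, :] - scores[None, :, :]) ** 2).sum(axis=2)
        W = np.exp(-d2 / (2.0 * h * h))
        node_values = (W @ labels) / W.sum(axis=1)
    else:
        node_values = labels.copy()
    return Landscape(nodes=scores, node_values=node_values, smoothing=h)


def predict(landscape: Landscape, scores: np.ndarray) -> np.ndarray:
    """Barycentric interpolation; nearest node outside the convex hull."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = landscape._interp(scores)
    nan = ~np.isfinite(y)
    if np.any(nan):
        _, idx = landscape._tree.query(scores[nan])
        y[nan] = landscape.node_values[idx]
    return y


@dataclass
class PredictionResult:
    """Primary, bias-corrected and mean predictions on the test set."""

    Y_hat_p: np.ndarray
    Y_hat_BC: np.ndarray
    Y_hat_M: float
    Y_test: np.ndarray
    bias_bin_centers: np.ndarray
    bias_values: np.ndarray
    test_index: np.ndarray


def _bias_table(y_hat: np.ndarray, y_true: np.ndarray,
                bin_width: float) -> dict[int, list[float]]:
    table: dict[int, list[float]] = {}
    for yh, yt in zip(y_hat, y_true):
        b = int(np.floor(yh / bin_width))
        table.setdefault(b, []).append(yh - yt)
    return table


def _interp_bias(y_hat: np.ndarray, centers: np.ndarray,
                 values: np.ndarray) -> np.ndarray:
    if len(centers) == 0:
        return np.zeros_like(y_hat)
    if len(centers) == 1:
        return np.full_like(y_hat, values[0])
    return np.interp(y_hat, centers, values)


def cv_bias_correction(dataset: SegmentDataset, K: int = 10,
                       bin_width: float = 0.5,
                       bandwidth: float | None = None,
                       train_frac: float = 0.75,
                       seed: int = 0) -> PredictionResult:
    """K repeated train/CV re-splits -> binned bias -> corrected predictor.

    The test partition stays fixed; the pooled train+CV segments are
    re-split K times.  Per repeat, a landscape trained on the training
    part predicts the CV part, and mean(Y_hat - Y) is accumulated in bins
    of the predicted value (width 0.5 on the log scale).  The per-bin
    biases averaged over repeats form the bias table; the final landscape
    is rebuilt on all train+CV segments and its test predictions are
    corrected by the linearly interpolated bias.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(~dataset.mask("test"))
    test = np.flatnonzero(dataset.mask("test"))
    if len(pool) < 6 or len(test) == 0:
        raise ValueError("dataset too small for bias-corrected prediction")
    scores = dataset.scores
    Y = dataset.labels

    acc: dict[int, list[float]] = {}
    for _ in range(K):
        perm = rng.permutation(pool)
        n_tr = max(3, int(round(train_frac * len(pool))))
        n_tr = min(n_tr, len(pool) - 1)  # CV part never empty
        tr, cv = perm[:n_tr], perm[n_tr:]
        scape = build_landscape(scores[tr], Y[tr], bandwidth)
        y_hat_cv = predict(scape, scores[cv])
        for b, errs in _bias_table(y_hat_cv, Y[cv], bin_width).items():
            acc.setdefault(b, []).append(float(np.mean(errs)))

    bins = sorted(acc)
    centers = np.array([(b + 0.5) * bin_width for b in bins])
    values = np.array([float(np.mean(acc[b])) for b in bins])

    final = build_landscape(scores[pool], Y[pool], bandwidth)
    y_hat_p = predict(final, scores[test])
    y_hat_bc = y_hat_p - _interp_bias(y_hat_p, centers, values)
    return PredictionResult(
        Y_hat_p=y_hat_p, Y_hat_BC=y_hat_bc,
        Y_hat_M=float(Y[pool].mean()), Y_test=Y[test],
        bias_bin_centers=centers, bias_values=values, test_index=test)


@dataclass(frozen=True)
class SLMConfig:
    """End-to-end SLM pipeline configuration."""

    downsample_factor: int | None = None   # None: aim for <= target_samples
    target_samples: int = 2_000
    min_seg_frac: float = 0.01
    max_cp: int = 99
    backend: str = "bayes"
    K: int = 10
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    bin_width: float = 0.5
    bandwidth: float | None = None
    usability_threshold: float = 0.6
    enforce_usability: bool = True
    seed: int = 0


def split_segments(n: int, split: tuple[float, float, float],
                   rng: np.random.Generator) -> np.ndarray:
    """Random per-segment assignment to train/cv/test."""
    f_tr, f_cv, f_te = split
    total = f_tr + f_cv + f_te
    perm = rng.permutation(n)
    n_tr = int(round(n * f_tr / total))
    n_cv = int(round(n * f_cv / total))
    part = np.empty(n, dtype=object)
    part[perm[:n_tr]] = "train"
    part[perm[n_tr:n_tr + n_cv]] = "cv"
    part[perm[n_tr + n_cv:]] = "test"
    return part.astype("U5")


def collect_segments(trajectories, config: SLMConfig) -> list[Segment]:
    """Down-sample, segment and label every assembling trajectory."""
    labeled: list[Segment] = []
    for traj in trajectories:
        if traj.censored:
            logger.info("skipping censored trajectory %s", traj.seed)
            continue
        n_rec = len(traj.steps)
        factor = config.downsample_factor or max(
            1, int(np.ceil(n_rec / config.target_samples)))
        if n_rec // factor < 2 * max(2, int(config.min_seg_frac * (n_rec // factor))):
            logger.info("trajectory %s too short after down-sampling", traj.seed)
            continue
        window = downsample(traj, factor)
        post = detect_changepoints(
            window, min_seg_frac=config.min_seg_frac, max_cp=config.max_cp,
            backend=config.backend, seed=config.seed + traj.seed)
        segs = extract_segments(window, post)
        labeled.extend(label_segments(segs, traj))
    return labeled


def run_slm(trajectories, config: SLMConfig = SLMConfig()
            ) -> tuple[PredictionResult, SegmentDataset]:
    """Full pipeline: segment, label, project, bias-correct, predict.

    Refuses to run (usability error) when the fraction of trajectories
    containing an assembly event falls below the configured threshold.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories supplied")
    frac = np.mean([not t.censored for t in trajectories])
    if config.enforce_usability and frac < config.usability_threshold:
        raise UsabilityError(
            f"only {frac:.0%} of trajectories assembled; below the "
            f"{config.usability_threshold:.0%} usability threshold")
    labeled = collect_segments(trajectories, config)
    dataset = SegmentDataset(segments=labeled)
    return run_slm_on_segments(dataset, config), dataset


def run_slm_on_segments(dataset: SegmentDataset,
                        config: SLMConfig = SLMConfig()) -> PredictionResult:
    """SLM on an already-collected labeled segment dataset."""
    if dataset.n < 10:
        raise ValueError(f"too few labeled segments ({dataset.n})")
    rng = np.random.default_rng(config.seed)
    normalize_and_project(dataset)
    dataset.partition = split_segments(dataset.n, config.split, rng)
    f_tr, f_cv, _ = config.split
    result = cv_bias_correction(
        dataset, K=config.K, bin_width=config.bin_width,
        bandwidth=config.bandwidth,
        train_frac=f_tr / (f_tr + f_cv),
        seed=int(rng.integers(2**31)))
    return result


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trajectory_id": s.trajectory_id, "start": s.start, "end": s.end,
        "start_step": s.start_step, "end_step": s.end_step,
        "mean": s.mean, "std": s.std, "trend": s.trend, "Y": s.Y,
    } for s in segments])


def frame_to_segments(df: pd.DataFrame) -> list[Segment]:
    return [Segment(
        trajectory_id=str(r.trajectory_id), start=int(r.start), end=int(r.end),
        start_step=int(r.start_step), end_step=int(r.end_step),
        mean=float(r.mean), std=float(r.std), trend=float(r.trend),
        Y=None if pd.isna(r.Y) else float(r.Y),
    ) for r in df.itertuples()]


def save_model(path: str | Path, dataset: SegmentDataset,
               landscape: Landscape, result: PredictionResult) -> None:
    """Serialize normalization, loadings, nodes and bias table as JSON."""
    payload = {
        "norm_mean": dataset.norm_mean.tolist(),
        "norm_std": dataset.norm_std.tolist(),
        "loadings": dataset.loadings.tolist(),
        "nodes": landscape.nodes.tolist(),
        "node_values": landscape.node_values.tolist(),
        "smoothing": landscape.smoothing,
        "bias_bin_centers": result.bias_bin_centers.tolist(),
        "bias_values": result.bias_values.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Reload a serialized model; returns (project_fn, predict_fn)."""
    data = json.loads(Path(path).read_text())
    mu = np.array(data["norm_mean"])
    sd = np.array(data["norm_std"])
    load = np.array(data["loadings"])
    scape = Landscape(nodes=np.array(data["nodes"]),
                      node_values=np.array(data["node_values"]),
                      smoothing=data["smoothing"])
    centers = np.array(data["bias_bin_centers"])
    values = np.array(data["bias_values"])

    def project(coords: np.ndarray) -> np.ndarray:
        return ((np.atleast_2d(coords) - mu) / sd) @ load

    def predict_bc(coords: np.ndarray) -> np.ndarray:
        y = predict(scape, project(coords))
        return y - _interp_bias(y, centers, values)

    return project, predict_bc
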