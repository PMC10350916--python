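"""Stochastic landscape: labeling, projection, interpolation, bias removal."""

import numpy as np
import pytest

from slmassembly import (
    SegmentDataset,
    SLMConfig,
    build_landscape,
    cv_bias_correction,
    label_segments,
    normalize_and_project,
    predict,
    run_slm,
)
from slmassembly.fixtures import LandscapeSpec, make_landscape_dataset
from slmassembly.segmentation import Segment
from slmassembly import slm as slm_mod
from slmassembly.slm import (
    UsabilityError,
    load_model,
    run_slm_on_segments,
    save_model,
    split_segments,
)


def seg(end_step, mean=0.0, std=1.0, trend=0.0, Y=None):
    return Segment(trajectory_id="t", start=0, end=10, start_step=0,
                   end_step=end_step, mean=mean, std=std, trend=trend, Y=Y)


class FakeTraj:
    def __init__(self, T_FAS, censored=False):
        self.T_FAS = T_FAS
        self.censored = censored
        self.seed = 0


class TestLabeling:
    def test_label_is_log_remaining_time(self):
        out = label_segments([seg(end_step=900)], FakeTraj(1000))
        assert out[0].Y == pytest.approx(np.log(100), abs=1e-12)

    def test_segment_ending_at_assembly_excluded(self):
        assert label_segments([seg(end_step=1000)], FakeTraj(1000)) == []
        assert label_segments([seg(end_step=1100)], FakeTraj(1000)) == []

    def test_censored_trajectory_contributes_nothing(self):
        out = label_segments([seg(end_step=10)], FakeTraj(1000, censored=True))
        assert out == []

    def test_labels_match_subtraction_oracle(self):
        ends = [100, 350, 600, 850, 999]
        out = label_segments([seg(end_step=e) for e in ends], FakeTraj(1000))
        np.testing.assert_allclose(
            [s.Y for s in out], np.log(1000 - np.array(ends)))


class TestProjection:
    def test_normalized_columns(self):
        segs, _ = make_landscape_dataset(LandscapeSpec(n=200, seed=1))
        ds = normalize_and_project(SegmentDataset(segments=segs))
        Z = (ds.coordinates - ds.norm_mean) / ds.norm_std
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_planar_cloud_fully_explained(self):
        # coordinates lying exactly in a 2-D plane: two PCs carry everything
        rng = np.random.default_rng(2)
        ab = rng.normal(size=(100, 2))
        coords = ab @ np.array([[1.0, 0.5, -0.2], [0.3, -1.0, 0.8]])
        segs = [seg(0, *c, Y=0.0) for c in coords]
        ds = normalize_and_project(SegmentDataset(segments=segs))
        Z = (ds.coordinates - ds.norm_mean) / ds.norm_std
        total = (Z ** 2).sum()
        explained = (ds.scores ** 2).sum()
        assert explained == pytest.approx(total, rel=1e-10)

    def test_scores_match_eigendecomposition_oracle(self):
        segs, _ = make_landscape_dataset(LandscapeSpec(n=300, seed=3))
        ds = normalize_and_project(SegmentDataset(segments=segs))
        Z = (ds.coordinates - ds.norm_mean) / ds.norm_std
        cov = np.cov(Z, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        top2 = evecs[:, order[:2]]
        oracle = (Z - Z.mean(axis=0)) @ top2
        # eigenvectors defined up to sign per component
        for k in range(2):
            diff = min(np.abs(ds.scores[:, k] - oracle[:, k]).max(),
                       np.abs(ds.scores[:, k] + oracle[:, k]).max())
            assert diff < 1e-8
        assert ds.explained_variance[0] >= ds.explained_variance[1]

    def test_zero_variance_coordinate_named(self):
        segs = [seg(0, mean=float(i), std=2.0, trend=float(i) / 7, Y=0.0)
                for i in range(20)]
        with pytest.raises(ValueError, match="std"):
            normalize_and_project(SegmentDataset(segments=segs))


class TestLandscape:
    def test_three_points_interpolate_exactly_without_smoothing(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        labels = np.array([1.0, 2.0, 3.0])
        scape = build_landscape(pts, labels, bandwidth=0.0)
        np.testing.assert_allclose(predict(scape, pts), labels, atol=1e-12)

    def test_constant_labels_everywhere(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(50, 2))
        scape = build_landscape(pts, np.full(50, 2.5))
        queries = rng.normal(size=(20, 2))
        np.testing.assert_allclose(predict(scape, queries), 2.5, atol=1e-12)

    def test_smooth_surface_recovery_at_interior_points(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-2, 2, size=(2000, 2))
        noise = 0.05
        f = lambda p: np.sin(p[:, 0]) + 0.5 * p[:, 1]
        labels = f(pts) + rng.normal(0, noise, 2000)
        scape = build_landscape(pts, labels)
        held = rng.uniform(-1.5, 1.5, size=(200, 2))
        err = predict(scape, held) - f(held)
        assert np.abs(err).max() < 2 * noise + 0.05  # smoothing bias margin

    def test_centroid_is_barycentric_mean(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        labels = np.array([3.0, 6.0, 9.0])
        scape = build_landscape(pts, labels, bandwidth=0.0)
        centroid = pts.mean(axis=0, keepdims=True)
        assert predict(scape, centroid)[0] == pytest.approx(6.0, abs=1e-12)

    def test_outside_hull_nearest_node(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        labels = np.array([1.0, 2.0, 3.0])
        scape = build_landscape(pts, labels, bandwidth=0.0)
        assert predict(scape, np.array([[50.0, 0.0]]))[0] == 2.0
        assert np.isfinite(predict(scape, np.array([[-30.0, -30.0]]))[0])

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            build_landscape(pts, np.arange(10.0))


class TestBiasCorrection:
    @staticmethod
    def _dataset(n=1500, noise=0.1, seed=6):
        segs, _ = make_landscape_dataset(LandscapeSpec(n=n, noise=noise,
                                                       seed=seed))
        ds = normalize_and_project(SegmentDataset(segments=segs))
        ds.partition = split_segments(ds.n, (0.6, 0.2, 0.2),
                                      np.random.default_rng(seed))
        return ds

    def test_injected_constant_offset_recovered(self, monkeypatch):
        ds = self._dataset()
        delta = 0.7
        base = cv_bias_correction(ds, seed=7)

        real_predict = slm_mod.predict
        monkeypatch.setattr(slm_mod, "predict",
                            lambda scape, s: real_predict(scape, s) + delta)
        shifted = cv_bias_correction(ds, seed=7)
        # bias table absorbs the offset ...
        assert np.median(shifted.bias_values) == pytest.approx(
            np.median(base.bias_values) + delta, abs=0.15)
        # ... and the corrected predictions are offset-free
        assert np.median(np.abs(shifted.Y_hat_BC - base.Y_hat_BC)) < 0.2

    def test_unbiased_predictor_small_bias(self, monkeypatch):
        # replace the landscape by a predictor that is unbiased by
        # construction: labels are f(scores) + noise and the predictor
        # returns f(scores) exactly, so estimated biases are pure noise
        ds = self._dataset(n=3000, noise=0.0, seed=8)
        normalize_and_project(ds)
        sigma = 0.1
        rng = np.random.default_rng(88)
        f = lambda scores: 2.0 + scores @ np.array([1.0, -0.5])
        for s, scr in zip(ds.segments, ds.scores):
            s.Y = float(f(scr[None, :])[0] + rng.normal(0, sigma))
        monkeypatch.setattr(slm_mod, "predict",
                            lambda scape, scores: f(np.atleast_2d(scores)))
        res = cv_bias_correction(ds, seed=9)
        # per-bin standard error with ~150 CV points per bin over 10 repeats
        assert np.abs(np.median(res.bias_values)) < 3 * sigma / np.sqrt(30)
        assert np.abs(res.bias_values).max() < 5 * sigma

    def test_correction_is_pointwise_subtraction(self):
        ds = self._dataset()
        res = cv_bias_correction(ds, seed=10)
        interp = np.interp(res.Y_hat_p, res.bias_bin_centers,
                           res.bias_values)
        np.testing.assert_allclose(res.Y_hat_BC, res.Y_hat_p - interp,
                                   atol=1e-12)


class TestPipeline:
    def test_noiseless_recovery(self):
        segs, _ = make_landscape_dataset(LandscapeSpec(n=2000, noise=0.0,
                                                       seed=11))
        res = run_slm_on_segments(SegmentDataset(segments=segs),
                                  SLMConfig(seed=12))
        r = np.corrcoef(res.Y_test, res.Y_hat_BC)[0, 1]
        assert r >= 0.9

    def test_determinism(self):
        segs, _ = make_landscape_dataset(LandscapeSpec(n=800, noise=0.1,
                                                       seed=13))
        a = run_slm_on_segments(SegmentDataset(segments=list(segs)),
                                SLMConfig(seed=14))
        b = run_slm_on_segments(SegmentDataset(segments=list(segs)),
                                SLMConfig(seed=14))
        np.testing.assert_array_equal(a.Y_hat_BC, b.Y_hat_BC)

    def test_shift_equivariance(self):
        # adding c to every label adds c to every prediction (c aligned
        # with the bias-bin grid so binning is unchanged)
        c = 2.0
        segs, _ = make_landscape_dataset(LandscapeSpec(n=1000, noise=0.05,
                                                       seed=15))
        shifted = [Segment(**{**s.__dict__, "Y": s.Y + c}) for s in segs]
        a = run_slm_on_segments(SegmentDataset(segments=segs),
                                SLMConfig(seed=16))
        b = run_slm_on_segments(SegmentDataset(segments=shifted),
                                SLMConfig(seed=16))
        np.testing.assert_allclose(b.Y_hat_BC, a.Y_hat_BC + c, atol=1e-9)
        assert b.Y_hat_M == pytest.approx(a.Y_hat_M + c, abs=1e-12)

    def test_test_labels_never_leak(self):
        segs, _ = make_landscape_dataset(LandscapeSpec(n=1000, noise=0.05,
                                                       seed=17))
        a = run_slm_on_segments(SegmentDataset(segments=segs),
                                SLMConfig(seed=18))
        # poison the test labels and rerun: predictions must not move
        poisoned = []
        rng = np.random.default_rng(0)
        for s in segs:
            poisoned.append(Segment(**s.__dict__))
        ds = SegmentDataset(segments=poisoned)
        res_a = run_slm_on_segments(ds, SLMConfig(seed=18))
        for idx in res_a.test_index:
            poisoned[idx].Y += rng.normal(0, 5)
        ds2 = SegmentDataset(segments=poisoned)
        res_b = run_slm_on_segments(ds2, SLMConfig(seed=18))
        np.testing.assert_array_equal(res_a.Y_hat_BC, res_b.Y_hat_BC)

    def test_usability_gate(self):
        # fewer than 60% of trajectories assembled: the pipeline refuses
        class Fake:
            def __init__(self, censored):
                self.censored = censored
        fakes = [Fake(True)] * 5 + [Fake(False)] * 5
        with pytest.raises(UsabilityError):
            run_slm(fakes, SLMConfig())

    def test_model_roundtrip(self, tmp_path):
        segs, _ = make_landscape_dataset(LandscapeSpec(n=600, noise=0.05,
                                                       seed=19))
        ds = SegmentDataset(segments=segs)
        res = run_slm_on_segments(ds, SLMConfig(seed=20))
        pool = ~ds.mask("test")
        scape = build_landscape(ds.scores[pool], ds.labels[pool])
        path = tmp_path / "model.json"
        save_model(path, ds, scape, res)
        project, predict_bc = load_model(path)
        coords = ds.coordinates[res.test_index]
        np.testing.assert_allclose(project(coords),
                                   ds.scores[res.test_index], atol=1e-10)
        direct = predict(scape, ds.scores[res.test_index])
        direct -= np.interp(direct, res.bias_bin_centers, res.bias_values)
        np.testing.assert_allclose(predict_bc(coords), direct, atol=1e-10)
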