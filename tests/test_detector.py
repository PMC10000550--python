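"""Preprocessing, augmentation and small-scale detector training."""

import numpy as np
import pytest

from nasometry import detector as det
from nasometry.landmarks import Point2D, View, ViewAnnotation
from nasometry.synth import generate_participants, sample_face, render


@pytest.fixture(scope="module")
def tiny_cfg():
    return det.DetectorConfig(view="frontal", input_size=32, epochs=2, batch_size=4, seed=0)


class TestPreprocess:
    def test_large_rgb_input_resized_with_recorded_scale(self):
        img = np.full((3456, 5184, 3), 120, dtype=np.uint8)
        out, amap = det.preprocess(img, 416)
        assert out.shape == (416, 416)
        assert amap.scale == pytest.approx(416 / 5184)

    def test_already_gray_square_input_only_normalized(self):
        img = (np.random.default_rng(0).uniform(0, 255, size=(416, 416))).astype(np.uint8)
        out, amap = det.preprocess(img, 416)
        assert amap.scale == 1.0
        np.testing.assert_allclose(out, img / 255.0, atol=1e-6)

    def test_green_background_blanked(self):
        p = sample_face(2, overrides={"noise_sd": 0.0})
        img = render(p, "frontal")
        out, _ = det.preprocess(img, 128)
        assert out[0, 0] == 0.0  # corner was pure green background

    def test_affine_round_trip_within_half_pixel(self):
        rng = np.random.default_rng(1)
        img = np.zeros((900, 700), dtype=np.uint8)
        _, amap = det.preprocess(img, 256)
        pts = rng.uniform(0, [700, 900], size=(50, 2))
        back = amap.to_original(amap.to_model(pts))
        assert np.max(np.abs(back - pts)) < 0.5


class TestAugment:
    def _pair(self, cfg):
        p = sample_face(3, overrides={"noise_sd": 0.0})
        img = render(p, "frontal").mean(axis=2).astype(np.float32) / 255.0
        from nasometry.synth import project

        pts = dict(project(p, "frontal").points)
        return img, pts

    def test_identity_parameters_return_input(self):
        cfg = det.DetectorConfig(view="frontal", input_size=416, rot_deg=0.0, scale_range=(1.0, 1.0), flip_prob=0.0)
        img, pts = self._pair(cfg)
        out, new = det.augment(img, pts, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(out, img)
        assert new == {k: Point2D(*v) for k, v in pts.items()}

    def test_flip_swaps_sides_and_mirrors_u(self):
        cfg = det.DetectorConfig(view="frontal", input_size=416, rot_deg=0.0, scale_range=(1.0, 1.0), flip_prob=1.0)
        img, pts = self._pair(cfg)
        _, new = det.augment(img, pts, cfg, np.random.default_rng(0))
        w = img.shape[1]
        cx = (w - 1) / 2.0
        assert new["al_r"].u == pytest.approx(2 * cx - pts["al_l"].u)
        assert new["al_r"].v == pytest.approx(pts["al_l"].v)
        assert new["prn"].u == pytest.approx(2 * cx - pts["prn"].u)

    def test_lateral_view_never_flips(self):
        cfg = det.DetectorConfig(view="lateral", input_size=416, rot_deg=0.0, scale_range=(1.0, 1.0), flip_prob=1.0)
        img, pts = self._pair(cfg)
        _, new = det.augment(img, pts, cfg, np.random.default_rng(0))
        assert new == {k: Point2D(*v) for k, v in pts.items()}

    def test_rotation_round_trip_restores_landmarks(self):
        img = np.zeros((64, 64), dtype=np.float32)
        pts = {"prn": (40.0, 22.0), "n": (30.0, 12.0)}
        cfg_fwd = det.DetectorConfig(view="frontal", input_size=64, rot_deg=0.0, scale_range=(1.3, 1.3), flip_prob=0.0)
        cfg_bwd = det.DetectorConfig(
            view="frontal", input_size=64, rot_deg=0.0, scale_range=(1 / 1.3, 1 / 1.3), flip_prob=0.0
        )
        _, fwd = det.augment(img, pts, cfg_fwd, np.random.default_rng(0))
        _, back = det.augment(img, fwd, cfg_bwd, np.random.default_rng(0))
        for pid in pts:
            assert back[pid].u == pytest.approx(pts[pid][0], abs=1e-6)
            assert back[pid].v == pytest.approx(pts[pid][1], abs=1e-6)


class TestModel:
    def test_output_dimension_is_twice_landmark_count(self):
        cfg = det.DetectorConfig(view="lateral", input_size=64)
        assert cfg.n_landmarks == 19
        model = det.build_model(cfg)
        out = model.forward(np.zeros((1, 64, 64, 1), dtype=np.float32))
        assert out.shape == (1, 38)

    def test_parameter_count_matches_layer_shape_arithmetic(self):
        cfg = det.DetectorConfig(view="frontal", input_size=64)
        model = det.build_model(cfg)
        assert model.n_params() == det.analytic_n_params(cfg)

    def test_table_architecture_conv_stack(self):
        cfg = det.DetectorConfig(view="frontal", input_size=64)
        convs = [l for l in det.build_model(cfg).layers if isinstance(l, __import__("nasometry.nn", fromlist=["nn"]).Conv2D)]
        assert [(c.out_ch, c.k) for c in convs] == [(32, 5), (32, 3), (64, 3), (64, 3), (128, 3), (256, 3)]

    def test_invalid_input_size_rejected(self):
        with pytest.raises(det.DetectorConfigError):
            det.DetectorConfig(view="frontal", input_size=100)


@pytest.fixture(scope="module")
def small_dataset():
    recs = generate_participants(8, seed=20, overrides={"image_size": 64}, views=(View.FRONTAL,))
    return [(r["images"]["frontal"], r["annotations"]["frontal"]) for r in recs]


class TestTraining:
    def test_loss_finite_and_decreasing(self, small_dataset):
        cfg = det.DetectorConfig(
            view="frontal", input_size=32, epochs=5, batch_size=4, seed=1, val_fraction=0.0, augment=False
        )
        d = det.train(small_dataset, cfg)
        losses = d.history.train_loss
        assert len(losses) == 5
        assert all(np.isfinite(losses))
        assert losses[-1] < losses[0]

    def test_same_seed_reproduces_identical_history(self, small_dataset):
        cfg = det.DetectorConfig(
            view="frontal", input_size=32, epochs=2, batch_size=4, seed=2, val_fraction=0.25, augment=True
        )
        h1 = det.train(small_dataset, cfg).history
        h2 = det.train(small_dataset, cfg).history
        assert h1.train_loss == h2.train_loss
        assert h1.val_nme == h2.val_nme

    def test_empty_dataset_rejected(self):
        with pytest.raises(det.DetectorConfigError):
            det.train([], det.DetectorConfig(view="frontal", input_size=32))

    def test_view_mismatch_rejected(self, small_dataset):
        cfg = det.DetectorConfig(view="lateral", input_size=32)
        with pytest.raises(det.DetectorConfigError, match="view"):
            det.train(small_dataset, cfg)

    def test_predict_preserves_order_and_bounds(self, small_dataset):
        cfg = det.DetectorConfig(
            view="frontal", input_size=32, epochs=1, batch_size=4, seed=3, val_fraction=0.0, augment=False
        )
        d = det.train(small_dataset, cfg)
        images = [img for img, _ in small_dataset]
        anns = det.predict(images, d)
        assert len(anns) == len(images)
        for ann, (img, _) in zip(anns, small_dataset):
            w, h = ann.image_size
            assert (w, h) == (img.shape[1], img.shape[0])
            for pt in ann.points.values():
                assert 0 <= pt.u <= w - 1 and 0 <= pt.v <= h - 1

    def test_checkpoint_round_trip(self, small_dataset, tmp_path):
        cfg = det.DetectorConfig(
            view="frontal", input_size=32, epochs=1, batch_size=4, seed=4, val_fraction=0.0, augment=False
        )
        d = det.train(small_dataset, cfg)
        path = tmp_path / "model.npz"
        d.save(path)
        loaded = det.Detector.load(path)
        img = small_dataset[0][0]
        a = det.predict([img], d)[0]
        b = det.predict([img], loaded)[0]
        for pid in a.points:
            assert a.points[pid] == b.points[pid]
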