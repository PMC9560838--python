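"""Dice loss, augmentation, patch sampling, training loop, prediction."""

import numpy as np
import pytest

from echotip import segmentation as seg
from echotip import synth
from echotip.evaluate import dice_accuracy


GEOM = synth.SectorGeometry()


def _frame(seed=1, **scene_kwargs):
    return synth.render_frame(synth.SceneConfig(seed=seed, **scene_kwargs), GEOM, (150, 110), 10.0)


def _blank_frame():
    return synth.render_frame(
        synth.SceneConfig(seed=2, catheter_intensity=0.0), GEOM, (150, 110), 0.0
    )


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        m = np.zeros((8, 8))
        m[2:5, 2:5] = 1
        assert seg.dice_loss(m, m, smoothing=0.0) == pytest.approx(0.0)

    def test_disjoint_is_one(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        a[0, 0] = 1
        b[7, 7] = 1
        assert seg.dice_loss(a, b, smoothing=0.0) == pytest.approx(1.0)

    def test_counting_oracle_tp2_fp1_fn1(self):
        """TP=2, FP=1, FN=1 -> loss = 1 - 2*2/(2*2+1+1) = 1/3."""
        pred = np.array([1, 1, 1, 0, 0], dtype=float)
        true = np.array([1, 1, 0, 1, 0], dtype=float)
        assert seg.dice_loss(pred, true, smoothing=0.0) == pytest.approx(1 / 3)

    def test_symmetric_on_hard_masks(self, rng):
        a = (rng.random((16, 16)) > 0.6).astype(float)
        b = (rng.random((16, 16)) > 0.6).astype(float)
        assert seg.dice_loss(a, b, 0.0) == pytest.approx(seg.dice_loss(b, a, 0.0))

    def test_bounds_and_empty_vs_empty_smoothed(self, rng):
        for _ in range(10):
            p = rng.random((8, 8))
            t = (rng.random((8, 8)) > 0.5).astype(float)
            assert 0.0 <= seg.dice_loss(p, t, 1.0) <= 1.0
        z = np.zeros((8, 8))
        assert seg.dice_loss(z, z, smoothing=1.0) == pytest.approx(0.0)

    def test_complement_of_accuracy_on_hard_masks(self, rng):
        a = (rng.random((12, 12)) > 0.7).astype(float)
        b = (rng.random((12, 12)) > 0.7).astype(float)
        assert seg.dice_loss(a, b, 0.0) + dice_accuracy(a, b) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg.dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestAugmentDataset:
    def test_factor_one_is_identity(self):
        frames = [_frame(1)]
        out = seg.augment_dataset(frames, 1, seed=0)
        assert len(out) == 1 and out[0] is frames[0]

    def test_tenfold_enlargement(self):
        frames = [_frame(s) for s in range(3)]
        assert len(seg.augment_dataset(frames, 10, seed=0)) == 30

    def test_geometric_transform_commutes_on_masks(self):
        """The mask transformed alongside the image agrees with the same
        transform applied independently to the mask (Dice >= 0.95)."""
        frame = _frame(3)
        twin = synth.EchoFrame(
            image=frame.mask.astype(np.float32),
            mask=frame.mask.copy(),
            geometry=frame.geometry,
            tip_pixel=frame.tip_pixel,
        )
        config = seg.TrainConfig(augment_intensity=False)
        out = seg.augment_dataset([twin], 2, seed=5, config=config)[1]
        independent = (out.image > 0.5).astype(np.uint8)
        assert dice_accuracy(independent, out.mask) >= 0.95

    def test_masks_stay_binary(self):
        out = seg.augment_dataset([_frame(4)], 3, seed=1)
        for f in out:
            assert set(np.unique(f.mask)).issubset({0, 1})


class TestSamplePatch:
    CFG = seg.desk_config(seed=0)

    def test_empty_mask_frame_only_negative(self, rng):
        frame = _blank_frame()
        for _ in range(10):
            assert not seg.sample_patch(frame, self.CFG, rng).is_positive
        with pytest.raises(seg.NoTargetError):
            seg.sample_patch(frame, self.CFG, rng, want_positive=True)

    def test_fully_foreground_frame_always_positive(self, rng):
        frame = synth.EchoFrame(
            image=np.ones((128, 128), dtype=np.float32),
            mask=np.ones((128, 128), dtype=np.uint8),
            geometry=GEOM,
            tip_pixel=(64, 64),
        )
        for _ in range(10):
            assert seg.sample_patch(frame, self.CFG, rng).is_positive

    def test_positive_fraction_near_rate(self, rng):
        frame = _frame(5)
        n = 2000
        hits = sum(seg.sample_patch(frame, self.CFG, rng).is_positive for _ in range(n))
        assert 0.93 <= hits / n <= 0.97

    def test_patch_shape_and_corner_bounds(self, rng):
        frame = _frame(6)
        s = seg.sample_patch(frame, self.CFG, rng)
        assert s.image_patch.shape == self.CFG.patch_shape
        r, c = s.corner
        assert 0 <= r <= frame.image.shape[0] - 64
        assert 0 <= c <= frame.image.shape[1] - 64

    def test_small_frame_zero_padded(self, rng):
        frame = synth.EchoFrame(
            image=np.ones((40, 40), dtype=np.float32),
            mask=np.ones((40, 40), dtype=np.uint8),
            geometry=GEOM,
            tip_pixel=(20, 20),
        )
        s = seg.sample_patch(frame, self.CFG, rng)
        assert s.image_patch.shape == (1, 64, 64)


class TestTraining:
    def test_identical_seeds_reproduce_loss_history(self, study_split):
        train_f, val_f, _ = study_split
        config = seg.desk_config(seed=3, max_iterations=30, validation_interval=10)
        _, h1 = seg.train(config, train_f[:6], val_f[:2])
        _, h2 = seg.train(config, train_f[:6], val_f[:2])
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.best_iteration == h2.best_iteration

    def test_early_stopping_patience_mechanics(self):
        """A task solved at once (empty-target frames, smoothed loss 0) never
        improves after the first check, so training stops after the patience
        window."""
        blank = [_blank_frame() for _ in range(2)]
        config = seg.desk_config(
            seed=0, max_iterations=200, validation_interval=10,
            early_stopping_patience_iterations=20,
        )
        model, hist = seg.train(config, blank, blank)
        assert hist.stopped_at < 200
        assert hist.stopped_at - hist.best_iteration >= 20

    def test_training_loss_decreases(self, desk_model):
        hist = desk_model["history"]
        n = max(1, len(hist.train_loss) // 10)
        assert np.median(hist.train_loss[-n:]) < np.median(hist.train_loss[:n])

    def test_loss_history_csv(self, desk_model):
        csv = desk_model["history"].to_csv()
        lines = csv.strip().splitlines()
        assert lines[0] == "iteration,split,dice_loss"
        assert any(",validation," in ln for ln in lines)


class TestPrediction:
    def test_threshold_extremes(self):
        frame = _frame(7)
        config = seg.desk_config(seed=0)
        model = seg.build_unet(config)
        config.binarization_threshold = 1.0
        assert seg.predict(model, frame, config).sum() == 0
        config.binarization_threshold = 0.0
        assert seg.predict(model, frame, config).all()

    def test_prediction_shape_matches_frame(self, desk_model):
        frame = _frame(8)
        mask = seg.predict(desk_model["model"], frame, desk_model["config"])
        assert mask.shape == frame.image.shape

    def test_flip_equivariance_statistical(self, desk_model, study_frames):
        """predict(flip(x)) vs flip(predict(x)) agree on average (Dice >= 0.8)."""
        model, config = desk_model["model"], desk_model["config"]
        scores = []
        for frame in study_frames[20:40]:
            direct = seg.predict(model, frame.image[:, ::-1], config)
            flipped = seg.predict(model, frame, config)[:, ::-1]
            scores.append(dice_accuracy(direct, flipped))
        assert np.mean(scores) >= 0.8

    def test_save_load_round_trip(self, desk_model, tmp_path):
        frame = _frame(9)
        model, config = desk_model["model"], desk_model["config"]
        seg.save_model(model, config, tmp_path / "m.npz")
        model2, config2 = seg.load_model(tmp_path / "m.npz")
        assert np.array_equal(
            seg.predict(model, frame, config), seg.predict(model2, frame, config2)
        )
        assert config2.unet_depth == config.unet_depth
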