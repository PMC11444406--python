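"""Multi-scale pipeline: scale algebra, patching, training loop, persistence."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from shapenca import autograd as ag
from shapenca.model import (
    ScaleSchedule,
    ShapeGuidedNCASegmenter,
    TrainConfig,
    TrainingDivergenceError,
    batch_duplicate,
    downscale_image,
    downscale_shape,
    forward_full,
    patchify,
    train,
    upscale_mask,
)
from tests.conftest import make_phantom_arrays


class TestDownscaleShape:
    def test_volume_worked_example(self):
        assert downscale_shape([640, 640, 48], d=2, n=4) == (40, 40, 3)

    def test_identity_cases(self):
        assert downscale_shape([100, 50], d=1, n=5) == (100, 50)
        assert downscale_shape([100, 50], d=2, n=0) == (100, 50)

    def test_planar_case(self):
        assert downscale_shape([256, 256], d=2, n=3) == (32, 32)

    def test_composition(self):
        for shape in [(640, 480), (37, 53), (1024, 17)]:
            for a in range(3):
                for b in range(3):
                    once = downscale_shape(downscale_shape(shape, 2, a), 2, b)
                    assert once == downscale_shape(shape, 2, a + b)

    def test_collapsed_dimension_rejected(self):
        with pytest.raises(ValueError):
            downscale_shape([8, 8], d=2, n=4)

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            downscale_shape([8, 8], d=0, n=1)
        with pytest.raises(ValueError):
            downscale_shape([8, 8], d=2, n=-1)

    def test_schedule_levels_and_validation(self):
        sched = ScaleSchedule(d=2, n=2, base_shape=(64, 64))
        assert sched.levels == [(64, 64), (32, 32), (16, 16)]
        with pytest.raises(ValueError):
            ScaleSchedule(d=2, n=4, base_shape=(64, 64)).validate()


class TestDownscaleImage:
    def test_constant_image(self):
        out = downscale_image(np.full((16, 16), 3.0), d=2, n=2)
        assert out.shape == (4, 4)
        np.testing.assert_allclose(out, 3.0)

    def test_block_mean_oracle(self):
        img = np.arange(16, dtype=float).reshape(4, 4)
        out = downscale_image(img, d=2, n=1)
        expected = np.array(
            [[img[:2, :2].mean(), img[:2, 2:].mean()],
             [img[2:, :2].mean(), img[2:, 2:].mean()]]
        )
        np.testing.assert_allclose(out, expected)

    def test_zero_iterations_identity(self, rng):
        img = rng.random((12, 12))
        np.testing.assert_array_equal(downscale_image(img, d=2, n=0), img)


class TestUpscale:
    def test_unit_factors_identity(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(upscale_mask(m, 1, 1), m)

    def test_nearest_roundtrip(self, rng):
        m = (rng.random((40, 40)) > 0.5).astype(np.uint8)
        up = upscale_mask(m, 16, 16)
        assert up.shape == (640, 640)
        np.testing.assert_array_equal(downscale_image(up, d=16, n=1), m)

    def test_single_pixel_block(self):
        m = np.zeros((3, 3)); m[1, 1] = 1
        up = upscale_mask(m, 2, 2)
        np.testing.assert_array_equal(up[2:4, 2:4], 1)
        assert up.sum() == 4

    def test_bilinear_probability_map(self, rng):
        p = rng.random((5, 5))
        up = upscale_mask(p, 2, 3, method="bilinear")
        assert up.shape == (10, 15)
        assert up.min() >= 0 and up.max() <= 1

    def test_invalid_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            upscale_mask(rng.random((4, 4)), 0, 2)


class TestPatchify:
    def test_full_size_identity(self, rng):
        img = rng.random((16, 16))
        mask = (img > 0.5).astype(float)
        pi, pm, off = patchify(img, mask, (16, 16), np.random.default_rng(0))
        assert off == (0, 0)
        np.testing.assert_array_equal(pi, img)
        np.testing.assert_array_equal(pm, mask)

    def test_seeded_offsets_reproducible(self, rng):
        img = rng.random((64, 64))
        offs_a = [patchify(img, img, (32, 32), np.random.default_rng(3))[2]
                  for _ in range(5)]
        offs_b = [patchify(img, img, (32, 32), np.random.default_rng(3))[2]
                  for _ in range(5)]
        assert offs_a == offs_b

    def test_offsets_uniform_over_quadrants(self, rng):
        """200 crops of 32^2 from 64^2: offsets fill [0, 32]^2 uniformly."""
        img = rng.random((64, 64))
        crop_rng = np.random.default_rng(99)
        counts = np.zeros(4)
        for _ in range(200):
            _, _, (oy, ox) = patchify(img, img, (32, 32), crop_rng)
            assert 0 <= oy <= 32 and 0 <= ox <= 32
            counts[(oy >= 16) * 2 + (ox >= 16)] += 1
        # offsets range over 33 values; 17 of them are >= 16
        p_hi = 17 / 33
        probs = np.array(
            [(1 - p_hi) ** 2, (1 - p_hi) * p_hi, p_hi * (1 - p_hi), p_hi**2]
        )
        assert chisquare(counts, 200 * probs).pvalue > 0.01

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            patchify(rng.random((8, 8)), rng.random((8, 8)), (9, 9),
                     np.random.default_rng(0))


class TestBatchDuplicate:
    def test_identity_factor(self):
        batch = np.arange(12).reshape(3, 2, 2)
        np.testing.assert_array_equal(batch_duplicate(batch, 1), batch)

    def test_pairs_are_bit_identical(self):
        batch = np.random.default_rng(0).random((3, 4, 4))
        out = batch_duplicate(batch, 2)
        assert out.shape[0] == 6
        np.testing.assert_array_equal(out[:3], out[3:])

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            batch_duplicate(np.zeros((2, 2, 2)), 0)

    def test_stochastic_firing_decorrelates_duplicates(self, rng):
        """Duplicated states diverge after one stochastic training step."""
        model = ShapeGuidedNCASegmenter(n_hidden=4, hidden_width=8).initialize()
        c = model.n_channels_
        state = np.tile(rng.standard_normal((1, c, 16, 16)).astype(np.float32),
                        (2, 1, 1, 1))
        keep = np.ones((1, c, 1, 1), dtype=np.float32)
        keep[0, 0] = 0
        out = model._step(ag.constant(state), model.fine_rule_,
                          np.random.default_rng(0), ag.constant(keep),
                          training=True)
        assert np.abs(out.data[0] - out.data[1]).max() > 0


class TestForward:
    def test_untrained_zero_classifier_gives_half(self):
        model = ShapeGuidedNCASegmenter(
            n_hidden=4, hidden_width=8, n_levels=1, steps_coarse=2, steps_fine=2
        ).initialize()
        img = np.random.default_rng(0).random((32, 32)).astype(np.float32)
        probs = forward_full(model, img, np.random.default_rng(1))
        np.testing.assert_allclose(probs, 0.5, atol=1e-6)

    def test_output_shape_and_range(self, trained_model, phantom_batch):
        X, _ = phantom_batch
        probs = trained_model.predict_proba(X[:3])
        assert probs.shape == X[:3].shape
        assert probs.min() >= 0 and probs.max() <= 1

    def test_odd_sized_input_is_padded_and_cropped_back(self, trained_model, rng):
        img = rng.random((37, 41)).astype(np.float32)
        probs = trained_model.predict_proba(img)
        assert probs.shape == (37, 41)

    def test_rejects_unnormalized_image(self, trained_model, rng):
        with pytest.raises(ValueError):
            forward_full(trained_model, rng.random((16, 16)) * 40 - 20)

    def test_too_small_input_rejected(self, trained_model):
        with pytest.raises(ValueError):
            trained_model.predict_proba(np.zeros((4, 4), dtype=np.float32))


class TestTraining:
    def test_learning_improves_over_initial(self, trained_model):
        hist = trained_model.history_
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        assert hist["val_dice"].max() > hist["val_dice"].iloc[0]

    def test_history_schema(self, trained_model):
        assert list(trained_model.history_.columns) == [
            "epoch", "train_loss", "val_loss", "val_dice"
        ]
        assert trained_model.n_epochs_ == len(trained_model.history_)

    def test_fixed_seed_reproduces_history(self):
        X, y, _ = make_phantom_arrays(8, seed=5)
        kwargs = dict(n_hidden=4, hidden_width=8, n_levels=1, steps_coarse=2,
                      steps_fine=2, max_epochs=3, steps_per_epoch=2, batch_size=2,
                      learning_rate=1e-3, random_state=7)
        h1 = ShapeGuidedNCASegmenter(**kwargs).fit(X, y).history_
        h2 = ShapeGuidedNCASegmenter(**kwargs).fit(X, y).history_
        pd.testing.assert_frame_equal(h1, h2)

    def test_patience_semantics_on_flat_validation(self):
        """With patience 1 and a never-improving validation loss the fit
        stops after exactly two epochs."""

        class FlatValidation(ShapeGuidedNCASegmenter):
            def _validation_metrics(self, Xval, yval, rng):
                return 1.0, 0.0

        X, y, _ = make_phantom_arrays(6, seed=2)
        model = FlatValidation(
            n_hidden=4, hidden_width=8, n_levels=1, steps_coarse=1, steps_fine=1,
            max_epochs=50, steps_per_epoch=1, batch_size=2, early_stop_patience=1,
        )
        model.fit(X, y)
        assert len(model.history_) == 2

    def test_divergence_raises_and_keeps_checkpoint(self):
        class Diverging(ShapeGuidedNCASegmenter):
            def _forward(self, imgs, masks, rng, training):
                if training:
                    return ag.constant(np.float32(np.nan)), None
                return super()._forward(imgs, masks, rng, training)

        X, y, _ = make_phantom_arrays(4, seed=3)
        model = Diverging(n_hidden=4, hidden_width=8, n_levels=1,
                          steps_coarse=1, steps_fine=1, max_epochs=5,
                          steps_per_epoch=1, batch_size=2)
        with pytest.raises(TrainingDivergenceError):
            model.fit(X, y)
        assert hasattr(model, "coarse_rule_")  # last checkpoint retained

    def test_empty_dataset_rejected(self):
        model = ShapeGuidedNCASegmenter()
        with pytest.raises(ValueError):
            model.fit(np.zeros((0, 8, 8)), np.zeros((0, 8, 8)))

    def test_shape_mismatch_rejected(self):
        model = ShapeGuidedNCASegmenter()
        with pytest.raises(ValueError):
            model.fit(np.zeros((2, 8, 8)), np.zeros((2, 4, 4)))

    def test_train_wrapper_accepts_pairs(self):
        X, y, _ = make_phantom_arrays(6, seed=8)
        model = ShapeGuidedNCASegmenter(n_hidden=4, hidden_width=8, n_levels=1,
                                        steps_coarse=1, steps_fine=1)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2, steps_per_epoch=1,
                          batch_size=2, seed=1)
        fitted, history = train(model, list(zip(X, y)), cfg)
        assert fitted is model and len(history) >= 1

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(alpha=2.0).validate()
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=0).validate()
        with pytest.raises(ValueError):
            train(ShapeGuidedNCASegmenter(), [], TrainConfig(max_epochs=1))


class TestPersistence:
    def test_save_load_roundtrip_identical_outputs(self, trained_model,
                                                   phantom_batch, tmp_path):
        X, _ = phantom_batch
        path = tmp_path / "model.npz"
        trained_model.save(path)
        loaded = ShapeGuidedNCASegmenter.load(path)
        a = trained_model.predict_proba(X[:2], rng=np.random.default_rng(42))
        b = loaded.predict_proba(X[:2], rng=np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_loaded_params_match(self, trained_model, tmp_path):
        path = tmp_path / "model.npz"
        trained_model.save(path)
        loaded = ShapeGuidedNCASegmenter.load(path)
        assert loaded.get_params() == trained_model.get_params()

    def test_sklearn_param_interface(self):
        model = ShapeGuidedNCASegmenter(n_hidden=5)
        assert model.get_params()["n_hidden"] == 5
        model.set_params(alpha=0.25)
        assert model.alpha == 0.25

    def test_duplicate_invariance_at_inference(self, trained_model, phantom_batch):
        """Duplicated inputs with a shared RNG state give identical maps."""
        X, _ = phantom_batch
        pair = np.stack([X[0], X[0]])
        probs = trained_model.predict_proba(pair, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(probs[0], probs[1])


class TestAugmentation:
    def test_elastic_augmentation_trains_and_stays_binary(self):
        """Training with elastic augmentation runs and warped masks are
        still valid soft-binary targets."""
        X, y, _ = make_phantom_arrays(8, seed=6)
        model = ShapeGuidedNCASegmenter(
            n_hidden=4, hidden_width=8, n_levels=1, steps_coarse=2, steps_fine=2,
            max_epochs=2, steps_per_epoch=2, batch_size=2, augment=True,
            random_state=0,
        )
        model.fit(X, y)
        assert len(model.history_) == 2
        rng = np.random.default_rng(0)
        wi, wm = model._elastic_augment(X[:3], y[:3], rng)
        assert wi.shape == X[:3].shape
        assert set(np.unique(wm)) <= {0.0, 1.0}

    def test_augmentation_deterministic_under_seed(self):
        X, y, _ = make_phantom_arrays(4, seed=6)
        model = ShapeGuidedNCASegmenter().initialize()
        a = model._elastic_augment(X, y, np.random.default_rng(3))
        b = model._elastic_augment(X, y, np.random.default_rng(3))
        np.testing.assert_array_equal(a[0], b[0])
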