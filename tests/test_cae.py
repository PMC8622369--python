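"""Autoencoder topology: shape algebra, loss oracle, training behaviour."""

import numpy as np
import pytest

from caeprep import (
    ConvAutoencoder,
    ImageDataset,
    build_cae,
    generate_dataset,
    reconstruction_loss,
    SyntheticSpec,
)
from caeprep.exceptions import ConfigurationError, ShapeError, TrainingError


def _zeros_dataset(m=32, h=8, w=8):
    return ImageDataset(np.zeros((m, h, w, 3), np.float32),
                        np.zeros(m, int), ["z"])


class TestArchitecture:
    @pytest.mark.parametrize("size,latent", [
        (1024, 256),  # full-resolution inputs compress 1024 -> 256 per side
        (600, 150),
        (64, 16),
        (4, 1),
    ])
    def test_latent_shape_quarter_resolution(self, size, latent):
        arch = build_cae(size, size)
        assert arch.latent_shape == (latent, latent, 3)
        assert arch.output_shape == (size, size, 3)

    def test_symmetric_layer_sequence(self):
        arch = build_cae(64, 64)
        kernels = [layer["kernel"] for layer in arch.layers]
        filters = [layer["filters"] for layer in arch.layers]
        assert kernels == [4, 2, 2, 4]
        assert filters == [32, 3, 32, 3]

    @pytest.mark.parametrize("h,w", [(30, 64), (64, 30), (2, 2), (0, 4)])
    def test_indivisible_sizes_rejected(self, h, w):
        with pytest.raises(ConfigurationError):
            build_cae(h, w)


class TestEncodeDecode:
    def test_shape_contracts_untrained(self, tiny_ds):
        model = ConvAutoencoder(16, 16, seed=0)
        encoded = model.encode(tiny_ds)
        assert encoded.images.shape == (tiny_ds.n_samples, 4, 4, 3)
        assert np.array_equal(encoded.labels, tiny_ds.labels)
        decoded = model.decode(encoded)
        assert decoded.images.shape == tiny_ds.images.shape

    def test_outputs_in_unit_interval(self, tiny_ds):
        model = ConvAutoencoder(16, 16, seed=1)
        encoded = model.encode(tiny_ds)
        decoded = model.decode(encoded)
        for arr in (encoded.images, decoded.images):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_encode_deterministic(self, tiny_ds):
        model = ConvAutoencoder(16, 16, seed=2)
        a = model.encode(tiny_ds).images
        b = model.encode(tiny_ds).images
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self, tiny_ds):
        model = ConvAutoencoder(32, 32, seed=0)
        with pytest.raises(ShapeError):
            model.encode(tiny_ds)
        with pytest.raises(ShapeError):
            model.decode(tiny_ds)  # 16x16 is not the 8x8 latent


class TestReconstructionLoss:
    def test_identity_is_zero(self, rng):
        x = rng.random((3, 4, 4, 3))
        assert reconstruction_loss(x, x) == 0.0

    def test_unit_vector_case(self):
        assert reconstruction_loss(np.array([0.0, 1.0, 0.0]),
                                   np.array([1.0, 0.0, 0.0])) == 1.0

    def test_batch_mean(self):
        x = np.zeros((2, 4))
        x_hat = np.array([[1.0, 1.0, 0, 0], [1, 1, 1, 1]])  # 1.0 and 2.0
        assert reconstruction_loss(x_hat, x) == pytest.approx(1.5)

    def test_brute_force_oracle(self, rng):
        """Agrees with an elementwise double loop to 1e-6."""
        for _ in range(5):
            x = rng.random((4, 3, 3, 3))
            x_hat = rng.random((4, 3, 3, 3))
            expected = 0.0
            for k in range(4):
                acc = 0.0
                for v, w in zip(x_hat[k].ravel(), x[k].ravel()):
                    acc += (v - w) ** 2
                expected += 0.5 * acc
            expected /= 4
            assert reconstruction_loss(x_hat, x) == pytest.approx(
                expected, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestTraining:
    def test_constant_target_is_learnable(self):
        ds = _zeros_dataset()
        model = ConvAutoencoder(8, 8, learning_rate=0.01, batch_size=4,
                                max_epochs=30, early_stop_patience=30,
                                seed=0).fit(ds)
        history = model.history_["train_loss"]
        assert history[-1] < 0.1 * history[0]

    def test_seeded_determinism(self):
        ds = _zeros_dataset()
        kwargs = dict(learning_rate=0.01, batch_size=4, max_epochs=5, seed=3)
        a = ConvAutoencoder(8, 8, **kwargs).fit(ds).history_
        b = ConvAutoencoder(8, 8, **kwargs).fit(ds).history_
        assert a == b

    def test_early_stop_after_patience_without_improvement(self):
        # a vanishing learning rate freezes the weights, so the validation
        # loss never improves after epoch 1 and patience=1 stops at epoch 2
        ds = _zeros_dataset()
        model = ConvAutoencoder(8, 8, learning_rate=1e-30, batch_size=8,
                                max_epochs=50, early_stop_patience=1,
                                seed=0).fit(ds)
        assert len(model.history_["train_loss"]) == 2
        assert model.history_["best_epoch"] == 1

    def test_best_validation_checkpointing(self, tiny_ds):
        model = ConvAutoencoder(16, 16, learning_rate=1e-3, batch_size=8,
                                max_epochs=6, seed=4).fit(tiny_ds)
        val = model.history_["val_loss"]
        assert min(val) <= val[0]

    def test_too_few_samples(self):
        ds = _zeros_dataset(m=1)
        with pytest.raises(TrainingError):
            ConvAutoencoder(8, 8, seed=0).fit(ds)


def test_checkpoint_round_trip(tmp_path, tiny_ds):
    model = ConvAutoencoder(16, 16, learning_rate=1e-3, batch_size=8,
                            max_epochs=2, seed=5).fit(tiny_ds)
    path = tmp_path / "cae.npz"
    model.save(path)
    loaded = ConvAutoencoder.load(path)
    assert np.array_equal(loaded.encode(tiny_ds).images,
                          model.encode(tiny_ds).images)


def test_training_denoises_smooth_signal():
    """Reconstructions land closer to the clean pattern than the noisy input."""
    spec = SyntheticSpec(n_classes=2, samples_per_class=32, height=32,
                         width=32, signal_amplitude=0.5, noise_sigma=0.2,
                         clutter_amplitude=0.1, seed=6)
    clean_spec = SyntheticSpec(**{**spec.__dict__, "noise_sigma": 0.0,
                                  "clutter_amplitude": 0.0})
    noisy = generate_dataset(spec)
    clean = generate_dataset(clean_spec)
    model = ConvAutoencoder(32, 32, learning_rate=1e-3, batch_size=16,
                            max_epochs=10, early_stop_patience=10,
                            seed=6).fit(noisy)
    recon = model.reconstruct(noisy)
    mse_recon = float(np.mean((recon.images - clean.images) ** 2))
    mse_noisy = float(np.mean((noisy.images - clean.images) ** 2))
    assert mse_recon < mse_noisy
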