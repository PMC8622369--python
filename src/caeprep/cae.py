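"""The convolutional autoencoder: a fixed symmetric 4-layer topology.

The encoder maps an ``H x W x 3`` image to an ``H/4 x W/4 x 3`` latent that
is itself a small RGB image (sigmoid output in [0, 1]); the decoder mirrors
the encoder with transposed convolutions.  Layer by layer:

===========  ======  ======  ======  ===============
stage        kernel  stride  pad     output
===========  ======  ======  ======  ===============
conv (32)    4 x 4   2       1       H/2 x W/2 x 32, ReLU
conv (3)     2 x 2   2       0       H/4 x W/4 x 3,  sigmoid
deconv (32)  2 x 2   2       0       H/2 x W/2 x 32, ReLU
deconv (3)   4 x 4   2       1       H x W x 3,      sigmoid
===========  ======  ======  ======  ===============

Training minimises the mean over samples of half the squared Euclidean
reconstruction error, J = (1/M) sum_k 0.5 * ||x_hat(k) - x(k)||^2, with Adam
at learning rate 1e-3 by default, a seeded stratified 10% validation split
and keep-best early stopping on the validation loss.

After training, the decoder is discarded by the pipeline and the encoder's
quarter-resolution output feeds the classifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as _io
from ._nn import (
    Conv2D,
    ConvTranspose2D,
    ReLU,
    Sequential,
    Sigmoid,
    fit_network,
    squared_error_loss,
)
from .containers import ImageDataset
from .exceptions import ConfigurationError, ShapeError, TrainingError


@dataclass
class CAEArchitecture:
    """The fixed topology, parameterised only by the input size."""

    input_height: int
    input_width: int
    encoder_activation: str = "sigmoid"
    layers: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, w = self.input_height, self.input_width
        if h % 4 or w % 4 or h < 4 or w < 4:
            raise ConfigurationError(
                f"input size must be divisible by 4 and >= 4, got {h}x{w}"
            )
        if self.encoder_activation not in ("sigmoid", "relu"):
            raise ConfigurationError(
                "encoder_activation must be 'sigmoid' or 'relu'"
            )
        if not self.layers:
            self.layers = [
                {"type": "conv", "filters": 32, "kernel": 4, "stride": 2,
                 "pad": 1, "activation": "relu",
                 "output": (h // 2, w // 2, 32)},
                {"type": "conv", "filters": 3, "kernel": 2, "stride": 2,
                 "pad": 0, "activation": self.encoder_activation,
                 "output": (h // 4, w // 4, 3)},
                {"type": "deconv", "filters": 32, "kernel": 2, "stride": 2,
                 "pad": 0, "activation": "relu",
                 "output": (h // 2, w // 2, 32)},
                {"type": "deconv", "filters": 3, "kernel": 4, "stride": 2,
                 "pad": 1, "activation": "sigmoid",
                 "output": (h, w, 3)},
            ]

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        """Shape of the encoder output (H/4, W/4, 3)."""
        return (self.input_height // 4, self.input_width // 4, 3)

    @property
    def output_shape(self) -> tuple[int, int, int]:
        return (self.input_height, self.input_width, 3)


def build_cae(height: int, width: int,
              encoder_activation: str = "sigmoid") -> CAEArchitecture:
    """Return the fixed 4-layer topology for ``height`` x ``width`` inputs."""
    return CAEArchitecture(height, width, encoder_activation)


@dataclass
class CAETrainSettings:
    """Autoencoder training hyperparameters (Adam throughout)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.early_stop_patience < 1:
            raise ConfigurationError("early_stop_patience must be >= 1")


def reconstruction_loss(x_hat: np.ndarray, x: np.ndarray) -> float:
    """J = (1/M) sum_k 0.5 * ||x_hat(k) - x(k)||^2 over a batch.

    The squared norm runs over every pixel and channel of sample ``k``.
    """
    x_hat = np.asarray(x_hat, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if x_hat.shape != x.shape:
        raise ShapeError(f"shape mismatch: {x_hat.shape} vs {x.shape}")
    m = x.shape[0] if x.ndim > 1 else 1
    return 0.5 * float(np.sum((x_hat - x) ** 2)) / m


class ConvAutoencoder:
    """Trainable convolutional autoencoder with the fixed topology above.

    Parameters mirror :class:`CAETrainSettings`; ``fit`` trains in place and
    returns ``self`` with ``history_`` populated.
    """

    def __init__(self, height: int, width: int, *,
                 settings: CAETrainSettings | None = None,
                 encoder_activation: str = "sigmoid", **overrides):
        if settings is None:
            settings = CAETrainSettings(**overrides)
        elif overrides:
            raise ConfigurationError("pass either settings or keyword overrides")
        self.architecture = build_cae(height, width, encoder_activation)
        self.settings = settings
        self._init_networks(np.random.default_rng(settings.seed))
        self.history_: dict | None = None

    def _init_networks(self, rng: np.random.Generator) -> None:
        act = self.architecture.encoder_activation
        self.encoder = Sequential([
            Conv2D(3, 32, kernel=4, stride=2, pad=1, rng=rng),
            ReLU(),
            Conv2D(32, 3, kernel=2, stride=2, pad=0, rng=rng),
            Sigmoid() if act == "sigmoid" else ReLU(),
        ])
        self.decoder = Sequential([
            ConvTranspose2D(3, 32, kernel=2, stride=2, pad=0, rng=rng),
            ReLU(),
            ConvTranspose2D(32, 3, kernel=4, stride=2, pad=1, rng=rng),
            Sigmoid(),
        ])
        self._net = Sequential(self.encoder.layers + self.decoder.layers)

    # -- training ---------------------------------------------------------

    def fit(self, ds: ImageDataset) -> "ConvAutoencoder":
        """Train on ``ds`` (reconstruction target = input) and return self."""
        self._check_input(ds.images)
        if ds.n_samples < 2:
            raise TrainingError("need at least 2 samples to train")
        split = _io.split_train_validation(
            ds, self.settings.validation_fraction, self.settings.seed
        )
        x_train = split.train.images.astype(np.float32)
        x_val = split.validation.images.astype(np.float32)
        rng = np.random.default_rng([self.settings.seed, 1])
        self.history_ = fit_network(
            self._net, x_train, x_train, x_val, x_val, squared_error_loss,
            learning_rate=self.settings.learning_rate,
            batch_size=self.settings.batch_size,
            max_epochs=self.settings.max_epochs,
            patience=self.settings.early_stop_patience,
            rng=rng,
        )
        return self

    # -- inference --------------------------------------------------------

    def _check_input(self, images: np.ndarray, latent: bool = False) -> None:
        want = self.architecture.latent_shape if latent \
            else self.architecture.output_shape
        if tuple(images.shape[1:]) != want:
            raise ShapeError(
                f"expected images of shape {want}, got {tuple(images.shape[1:])}"
            )

    def _run(self, net: Sequential, images: np.ndarray,
             batch_size: int = 64) -> np.ndarray:
        out = [net.forward(images[i:i + batch_size].astype(np.float32))
               for i in range(0, images.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def encode(self, ds: ImageDataset) -> ImageDataset:
        """Compress to the H/4 x W/4 x 3 latent; labels carried through."""
        self._check_input(ds.images)
        return ds.with_images(self._run(self.encoder, ds.images))

    def decode(self, ds: ImageDataset) -> ImageDataset:
        """Reconstruct H x W x 3 images from a latent dataset."""
        self._check_input(ds.images, latent=True)
        return ds.with_images(self._run(self.decoder, ds.images))

    def reconstruct(self, ds: ImageDataset) -> ImageDataset:
        """decode(encode(ds)) in one pass."""
        return self.decode(self.encode(ds))

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: architecture echo + weights."""
        meta = {
            "architecture": {
                "input_height": self.architecture.input_height,
                "input_width": self.architecture.input_width,
                "encoder_activation": self.architecture.encoder_activation,
            },
            "settings": asdict(self.settings),
        }
        arrays = {f"w{i}": p for i, p in enumerate(self._net.params())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ConvAutoencoder":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            arch = meta["architecture"]
            model = cls(
                arch["input_height"], arch["input_width"],
                settings=CAETrainSettings(**meta["settings"]),
                encoder_activation=arch["encoder_activation"],
            )
            model._net.set_state(
                [data[f"w{i}"] for i in range(len(model._net.params()))]
            )
        return model


def train_cae(ds: ImageDataset,
              settings: CAETrainSettings | None = None) -> ConvAutoencoder:
    """Build and train a :class:`ConvAutoencoder` sized to ``ds``."""
    settings = settings or CAETrainSettings()
    model = ConvAutoencoder(ds.height, ds.width, settings=settings)
    return model.fit(ds)
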