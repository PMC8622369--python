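"""CNN classification stage.

The working backbone is a small size-agnostic reference CNN: three stride-2
conv blocks (16/32/64 filters, 3x3 kernels) followed by global average
pooling and a softmax head, so the same network accepts full-resolution
images and quarter-resolution encoder outputs without resizing.  The named
ImageNet backbones (VGG/ResNet/DenseNet/MobileNet) are declared in the spec
surface but require an external pretrained-weight runtime; requesting one
raises :class:`~caeprep.exceptions.CapabilityError` rather than silently
substituting a different model.

Training minimises mean cross-entropy with Adam, a seeded stratified 10%
validation split and keep-best early stopping, mirroring the autoencoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import io as _io
from ._nn import (
    Conv2D,
    Dense,
    GlobalAveragePool,
    ReLU,
    Sequential,
    fit_network,
    softmax_cross_entropy_loss,
)
from .containers import ImageDataset
from .exceptions import CapabilityError, ConfigurationError, ShapeError, TrainingError

_PRETRAINED_BACKBONES = ("vgg", "resnet", "densenet", "mobilenet")


@dataclass
class ClassifierSpec:
    """Backbone choice plus training hyperparameters."""

    backbone: str = "reference_small_cnn"
    n_classes: int = 2
    pretrained: bool = False
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    early_stop_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.backbone not in (("reference_small_cnn",) + _PRETRAINED_BACKBONES):
            raise ConfigurationError(f"unknown backbone {self.backbone!r}")


def cross_entropy_cost(probabilities: np.ndarray, targets: np.ndarray) -> float:
    """Mean over samples of -sum_i l_i log(l_hat_i).

    ``probabilities`` rows must be probability vectors; ``targets`` is the
    matching one-hot matrix.  Probabilities are floored at 1e-12 before the
    logarithm.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if probabilities.shape != targets.shape or probabilities.ndim != 2:
        raise ShapeError(
            f"shape mismatch: {probabilities.shape} vs {targets.shape}"
        )
    logp = np.log(np.maximum(probabilities, 1e-12))
    return -float(np.sum(targets * logp)) / probabilities.shape[0]


class SmallCNNClassifier:
    """The reference backbone: conv(16)-conv(32)-conv(64) -> GAP -> softmax.

    Accepts any RGB input with H, W >= 8 thanks to the global-pooling head.
    ``fit`` returns ``self`` with ``history_`` populated.
    """

    def __init__(self, spec: ClassifierSpec):
        if spec.backbone in _PRETRAINED_BACKBONES:
            raise CapabilityError(
                f"backbone {spec.backbone!r} needs a pretrained-weight runtime "
                "which is not configured; no fallback is substituted"
            )
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self._net = Sequential([
            Conv2D(3, 16, kernel=3, stride=2, pad=1, rng=rng), ReLU(),
            Conv2D(16, 32, kernel=3, stride=2, pad=1, rng=rng), ReLU(),
            Conv2D(32, 64, kernel=3, stride=2, pad=1, rng=rng), ReLU(),
            GlobalAveragePool(),
            Dense(64, spec.n_classes, rng=rng),
        ])
        self.class_names: list[str] = []
        self.history_: dict | None = None

    def fit(self, ds: ImageDataset) -> "SmallCNNClassifier":
        present = np.unique(ds.labels)
        if present.size < 2:
            raise TrainingError("need at least 2 classes present to train")
        if ds.n_classes != self.spec.n_classes:
            raise ShapeError(
                f"dataset has {ds.n_classes} classes, spec says "
                f"{self.spec.n_classes}"
            )
        if min(ds.height, ds.width) < 8:
            raise ShapeError("reference CNN needs H, W >= 8")
        self.class_names = list(ds.class_names)
        split = _io.split_train_validation(
            ds, self.spec.validation_fraction, self.spec.seed
        )
        eye = np.eye(self.spec.n_classes, dtype=np.float32)
        rng = np.random.default_rng([self.spec.seed, 1])
        self.history_ = fit_network(
            self._net,
            split.train.images.astype(np.float32), eye[split.train.labels],
            split.validation.images.astype(np.float32),
            eye[split.validation.labels],
            softmax_cross_entropy_loss,
            learning_rate=self.spec.learning_rate,
            batch_size=self.spec.batch_size,
            max_epochs=self.spec.max_epochs,
            patience=self.spec.early_stop_patience,
            rng=rng,
        )
        return self

    def predict_proba(self, ds: ImageDataset) -> np.ndarray:
        """(M, N) class-probability matrix (rows sum to 1)."""
        if ds.images.shape[-1] != 3:
            raise ShapeError("expected RGB input")
        out = []
        for i in range(0, ds.n_samples, 64):
            logits = self._net.forward(ds.images[i:i + 64].astype(np.float32))
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z.astype(np.float64))
            out.append(ez / ez.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def predict(self, ds: ImageDataset) -> np.ndarray:
        return self.predict_proba(ds).argmax(axis=1)


def fit_classifier(spec: ClassifierSpec, ds: ImageDataset) -> SmallCNNClassifier:
    """Build the backbone named by ``spec`` and train it on ``ds``."""
    model = SmallCNNClassifier(spec)
    return model.fit(ds)


def predict_proba(model: SmallCNNClassifier, ds: ImageDataset) -> np.ndarray:
    return model.predict_proba(ds)
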