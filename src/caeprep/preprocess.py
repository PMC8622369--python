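"""The three preprocessing arms compared by the pipeline.

* ``traditional`` — identity: raw images go straight to the classifier.
* ``md`` — non-local means denoising applied image-wise (same resolution).
* ``cae`` — a trained autoencoder's encoder compresses each image to
  quarter resolution.

All three preserve sample count, labels and the [0, 1] intensity range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.restoration import denoise_nl_means, estimate_sigma

from .cae import ConvAutoencoder
from .containers import ImageDataset
from .exceptions import ConfigurationError

APPROACH_NAMES = ("traditional", "md", "cae")


@dataclass
class Approach:
    """One dataset -> dataset transform, identified by name."""

    name: str
    parameters: dict = field(default_factory=dict)
    model: Optional[ConvAutoencoder] = None

    def __post_init__(self) -> None:
        if self.name not in APPROACH_NAMES:
            raise ConfigurationError(
                f"approach must be one of {APPROACH_NAMES}, got {self.name!r}"
            )


def traditional() -> Approach:
    return Approach("traditional")


def mean_denoising(patch_radius: int = 1, search_radius: int = 5,
                   h: float = 0.1) -> Approach:
    """Non-local means denoising arm with the given filter settings."""
    return Approach("md", {"patch_radius": patch_radius,
                           "search_radius": search_radius, "h": h})


def cae_compression(model: ConvAutoencoder) -> Approach:
    """Encoder-compression arm backed by a trained autoencoder."""
    return Approach("cae", model=model)


def nlm_denoise(img: np.ndarray, patch_radius: int = 1, search_radius: int = 5,
                h: float = 0.1) -> np.ndarray:
    """Non-local means filtering of one (H, W, 3) image.

    Each output pixel is a weighted average over an
    ``(2*search_radius+1)^2`` window, with weights
    ``exp(-max(d^2 - 2*sigma_est^2, 0) / h^2)`` computed from squared
    distances ``d^2`` between ``(2*patch_radius+1)^2`` patches.  Channels
    are filtered independently; the noise level ``sigma_est`` comes from a
    robust wavelet-based estimator.  Output is clipped to [0, 1].
    """
    img = np.asarray(img, dtype=np.float64)
    if patch_radius < 0 or search_radius < 0:
        raise ConfigurationError("radii must be >= 0")
    if h <= 0:
        raise ConfigurationError("h must be > 0")
    if 2 * patch_radius + 1 > min(img.shape[0], img.shape[1]):
        raise ConfigurationError("patch larger than the image")
    if search_radius == 0:
        # the search window is the pixel itself: identity up to clipping
        return np.clip(img, 0.0, 1.0)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        channel = img[:, :, c]
        sigma = float(estimate_sigma(channel))
        out[:, :, c] = denoise_nl_means(
            channel,
            patch_size=2 * patch_radius + 1,
            patch_distance=search_radius,
            h=h,
            sigma=sigma,
            fast_mode=False,
        )
    return np.clip(out, 0.0, 1.0)


def apply_approach(approach: Approach, ds: ImageDataset) -> ImageDataset:
    """Apply one preprocessing arm to a whole dataset (labels untouched)."""
    if approach.name == "traditional":
        return ds.with_images(ds.images.copy())
    if approach.name == "md":
        p = approach.parameters
        denoised = np.stack([
            nlm_denoise(img, p.get("patch_radius", 1),
                        p.get("search_radius", 5), p.get("h", 0.1))
            for img in ds.images
        ]).astype(ds.images.dtype)
        return ds.with_images(denoised)
    if approach.model is None:
        raise ConfigurationError(
            "cae approach requires a trained ConvAutoencoder"
        )
    return approach.model.encode(ds)
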