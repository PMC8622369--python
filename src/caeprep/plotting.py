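"""Qualitative figures: original images next to their compressed latents."""

from __future__ import annotations

import numpy as np

from .cae import ConvAutoencoder
from .containers import ImageDataset


def show_compression_pairs(model: ConvAutoencoder, ds: ImageDataset,
                           n: int = 4, include_reconstruction: bool = False):
    """Matplotlib figure with one row per sample: original, latent
    (and optionally the reconstruction).  Returns the figure."""
    import matplotlib.pyplot as plt

    n = min(n, ds.n_samples)
    subset = ds.subset(np.arange(n))
    encoded = model.encode(subset)
    cols = 3 if include_reconstruction else 2
    fig, axes = plt.subplots(n, cols, figsize=(2.2 * cols, 2.2 * n),
                             squeeze=False)
    decoded = model.decode(encoded) if include_reconstruction else None
    for i in range(n):
        panels = [(subset.images[i], "original"),
                  (encoded.images[i], "compressed")]
        if decoded is not None:
            panels.append((decoded.images[i], "reconstructed"))
        for j, (img, title) in enumerate(panels):
            ax = axes[i][j]
            ax.imshow(np.clip(img, 0, 1))
            ax.set_axis_off()
            if i == 0:
                ax.set_title(title)
        axes[i][0].set_ylabel(ds.class_names[int(subset.labels[i])])
    fig.tight_layout()
    return fig


def plot_training_history(history: dict):
    """Train/validation loss curves of a fitted model."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    epochs = np.arange(1, len(history["train_loss"]) + 1)
    ax.plot(epochs, history["train_loss"], label="train")
    ax.plot(epochs, history["val_loss"], label="validation")
    ax.axvline(history["best_epoch"], ls="--", c="gray", lw=1,
               label=f"best epoch {history['best_epoch']}")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.legend()
    fig.tight_layout()
    return fig
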