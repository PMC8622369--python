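"""Core in-memory containers: labeled image datasets and metric tables.

An :class:`ImageDataset` is the unit every pipeline stage consumes and
produces: an ``(M, H, W, 3)`` float array of intensities in ``[0, 1]`` plus an
integer label per image.  Compressed (encoder-output) datasets are ordinary
``ImageDataset`` instances at quarter resolution, so they can be fed to any
classifier or written back to PNG unchanged.

A :class:`MetricTable` is the blocks x treatments matrix consumed by the
aligned-rank statistics: one row per experimental block (dataset x classifier
pair), one column per preprocessing approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ShapeError


@dataclass
class ImageDataset:
    """M RGB images in [0, 1] with integer class labels.

    Parameters
    ----------
    images
        Array of shape ``(M, H, W, 3)`` with values in ``[0, 1]``.
    labels
        Integer array of shape ``(M,)``; each value indexes ``class_names``.
    class_names
        One name per class, in label order.
    """

    images: np.ndarray
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ShapeError(
                f"images must have shape (M, H, W, 3), got {self.images.shape}"
            )
        if self.labels.shape != (self.images.shape[0],):
            raise ShapeError(
                f"labels shape {self.labels.shape} does not match "
                f"M={self.images.shape[0]}"
            )
        if not self.class_names:
            n = int(self.labels.max()) + 1 if self.labels.size else 0
            self.class_names = [f"class_{i}" for i in range(n)]
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ShapeError("labels must index class_names")

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def height(self) -> int:
        return self.images.shape[1]

    @property
    def width(self) -> int:
        return self.images.shape[2]

    def subset(self, indices: np.ndarray) -> "ImageDataset":
        """Return the dataset restricted to ``indices`` (copy)."""
        indices = np.asarray(indices)
        return ImageDataset(
            self.images[indices].copy(),
            self.labels[indices].copy(),
            list(self.class_names),
        )

    def with_images(self, images: np.ndarray) -> "ImageDataset":
        """Return a dataset with transformed images and untouched labels."""
        return ImageDataset(images, self.labels.copy(), list(self.class_names))


@dataclass
class SplitDatasets:
    """A stratified train/validation partition of one dataset."""

    train: ImageDataset
    validation: ImageDataset
    fraction_validation: float


@dataclass
class MetricTable:
    """n blocks x k treatments matrix of one performance metric.

    ``values[i, j]`` is the metric achieved by treatment ``j`` (a
    preprocessing approach) in block ``i`` (a dataset x classifier pair).
    """

    values: np.ndarray
    block_labels: list[str]
    treatment_labels: list[str]
    metric_name: str = ""
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("values must be a 2-D blocks x treatments matrix")
        n, k = self.values.shape
        if n < 1 or k < 2:
            raise ShapeError(f"need >=1 blocks and >=2 treatments, got {n}x{k}")
        if len(self.block_labels) != n or len(self.treatment_labels) != k:
            raise ShapeError("label lengths must match the value matrix")
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("metric table contains missing or non-finite entries")

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_treatments(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.block_labels, columns=self.treatment_labels
        )

    @classmethod
    def concat(cls, tables: list["MetricTable"]) -> "MetricTable":
        """Stack tables block-wise (treatments must agree in order)."""
        first = tables[0]
        for t in tables[1:]:
            if t.treatment_labels != first.treatment_labels:
                raise ShapeError("cannot stack tables with different treatments")
        return cls(
            np.vstack([t.values for t in tables]),
            [b for t in tables for b in t.block_labels],
            list(first.treatment_labels),
            first.metric_name,
            first.higher_is_better,
        )
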