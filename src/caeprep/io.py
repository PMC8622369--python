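"""Reading and writing the formats the pipeline touches.

Image datasets live on disk as class-subfolder trees of 8-bit RGB PNG/JPEG
files (``root/<class_name>/<file>``); intensities are normalised to [0, 1]
on load (value / 255).  Metric tables are plain CSV with a header row of
treatment labels and a first column of block labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pathlib import Path

from PIL import Image

from .containers import ImageDataset, MetricTable, SplitDatasets
from .exceptions import ParseError, ShapeError, SplitError

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


def load_image_folder(root: str | Path) -> ImageDataset:
    """Load ``root/<class>/<image>`` into an :class:`ImageDataset`.

    Class labels follow the lexicographic order of the subfolder names and
    files are read in sorted order, so the result is independent of
    filesystem enumeration order.  Non-RGB images are converted to RGB; all
    images must share one H x W.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    images, labels = [], []
    class_names = []
    shape = None
    for label, d in enumerate(class_dirs):
        files = sorted(
            f for f in d.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            continue
        class_names.append(d.name)
        for f in files:
            with Image.open(f) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ShapeError(
                    f"{f} has shape {arr.shape[:2]}, expected {shape[:2]}; "
                    "mixed image sizes are not supported"
                )
            images.append(arr)
            labels.append(len(class_names) - 1)
    if not images:
        raise ParseError(f"no decodable images found under {root}")
    return ImageDataset(np.stack(images), np.asarray(labels), class_names)


def save_image_folder(ds: ImageDataset, root: str | Path) -> list[Path]:
    """Write ``ds`` as 8-bit RGB PNGs under ``root/<class_name>/<index>.png``."""
    root = Path(root)
    paths = []
    counters = dict.fromkeys(range(ds.n_classes), 0)
    for img, label in zip(ds.images, ds.labels):
        d = root / ds.class_names[int(label)]
        d.mkdir(parents=True, exist_ok=True)
        idx = counters[int(label)]
        counters[int(label)] += 1
        arr = np.clip(np.rint(np.asarray(img, dtype=np.float64) * 255.0), 0, 255)
        path = d / f"{idx:05d}.png"
        Image.fromarray(arr.astype(np.uint8), mode="RGB").save(path)
        paths.append(path)
    return paths


def split_train_validation(
    ds: ImageDataset, fraction: float, seed: int
) -> SplitDatasets:
    """Stratified random train/validation split.

    Each class contributes ``round(fraction * class_count)`` samples (at
    least 1) to the validation part.  Reproducible from ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise SplitError(f"fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    val_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for c in range(ds.n_classes):
        members = np.flatnonzero(ds.labels == c)
        if members.size < 2:
            raise SplitError(
                f"class {ds.class_names[c]!r} has {members.size} sample(s); "
                "need >= 2 to split"
            )
        n_val = max(1, int(np.floor(fraction * members.size + 0.5)))
        n_val = min(n_val, members.size - 1)
        perm = rng.permutation(members)
        val_idx.append(perm[:n_val])
        train_idx.append(perm[n_val:])
    train = ds.subset(np.sort(np.concatenate(train_idx)))
    validation = ds.subset(np.sort(np.concatenate(val_idx)))
    return SplitDatasets(train, validation, fraction)


def read_metric_table(
    csv_path: str | Path,
    metric_name: str = "",
    higher_is_better: bool = True,
) -> MetricTable:
    """Read a blocks x treatments metric table from CSV.

    Expected layout: header row = treatment labels, first column = block
    labels, numeric body.  Ragged rows or non-numeric cells raise
    :class:`ParseError` naming the offending cell.
    """
    csv_path = Path(csv_path)
    try:
        # cells are parsed as text and converted one by one: exact float
        # round trip plus a named cell in every error message
        frame = pd.read_csv(csv_path, index_col=0, dtype=str,
                            skip_blank_lines=True)
    except Exception as exc:  # pandas raises various parse errors
        raise ParseError(f"cannot parse {csv_path}: {exc}") from exc
    values = np.full(frame.shape, np.nan)
    for i, row in enumerate(frame.itertuples(index=False)):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{csv_path}: non-numeric cell at row {frame.index[i]!r}, "
                    f"column {frame.columns[j]!r}: {cell!r}"
                ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{csv_path}: missing value at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )
    name = metric_name or csv_path.stem
    return MetricTable(
        values,
        [str(b) for b in frame.index],
        [str(t) for t in frame.columns],
        name,
        higher_is_better,
    )


def write_metric_table(table: MetricTable, csv_path: str | Path) -> None:
    """Write ``table`` as CSV (lossless full-precision round trip)."""
    frame = table.to_frame()
    frame.index.name = "block"
    # repr-precision floats round-trip exactly through float()
    frame.to_csv(csv_path, float_format="%.17g")
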