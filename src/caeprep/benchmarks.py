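"""Shipped benchmark metric tables.

Published accuracy / geometric-mean / AUC results of the three preprocessing
approaches (Traditional, MD, CAE) across four CNN backbones on three image
benchmarks — plant disease, skin cancer and deepfake detection.  Each CSV is
one 4-blocks x 3-treatments table; :func:`combined_table` stacks the three
datasets into the 12-block table the published statistical comparison uses.

The GM columns are kept on the scale they were published at (which is not a
consistent 0-100 recall scale across datasets); they are meaningful only as
rank inputs, never as recomputation targets.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .containers import MetricTable
from .exceptions import ConfigurationError
from .io import read_metric_table

DATASETS = ("plant", "skin", "deepfake")
METRICS = ("accuracy", "gm", "auc")
TREATMENTS = ("Traditional", "MD", "CAE")


def fixture_path(dataset: str, metric: str) -> Path:
    """Filesystem path of one shipped CSV table."""
    if dataset not in DATASETS:
        raise ConfigurationError(f"dataset must be one of {DATASETS}")
    if metric not in METRICS:
        raise ConfigurationError(f"metric must be one of {METRICS}")
    return Path(str(resources.files("caeprep") / "data" / "benchmarks"
                    / f"{dataset}_{metric}.csv"))


def benchmark_table(dataset: str, metric: str) -> MetricTable:
    """One dataset's 4 x 3 table for ``metric`` (blocks = CNN backbones)."""
    return read_metric_table(fixture_path(dataset, metric), metric_name=metric)


def combined_table(metric: str) -> MetricTable:
    """The 12-block table: {plant, skin, deepfake} x 4 backbones."""
    tables = []
    for ds in DATASETS:
        t = benchmark_table(ds, metric)
        tables.append(MetricTable(
            t.values, [f"{ds}/{b}" for b in t.block_labels],
            t.treatment_labels, metric, t.higher_is_better,
        ))
    return MetricTable.concat(tables)
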