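"""Full experiment grid: datasets x approaches x classifiers -> stats.

For every dataset the runner obtains a train/test pair, prepares each
preprocessing arm (training an autoencoder on the raw training set for the
``cae`` arm), fits every classifier on each arm's training output, evaluates
on the matching test output and collects one metric table per metric with
one block per (dataset, classifier) pair and one column per approach.
Each table is written as CSV and fed to the aligned-ranks comparison.

Block order is fixed: config dataset order x classifier order, so the
statistics are reproducible from the CSVs alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as _io
from .cae import CAETrainSettings, train_cae
from .classifier import ClassifierSpec, fit_classifier
from .containers import ImageDataset, MetricTable
from .exceptions import CaeprepError, ConfigurationError
from .metrics import evaluate_predictions
from .preprocess import (
    Approach,
    apply_approach,
    cae_compression,
    mean_denoising,
    traditional,
)
from .stats import FriedmanAlignedRanks
from .synthetic import SyntheticSpec, generate_dataset

_METRIC_KEYS = {"accuracy": "accuracy", "gm": "gm", "auc": "auc"}


@dataclass
class DatasetSource:
    """Either a class-folder tree on disk or a synthetic spec."""

    name: str
    path: Optional[str] = None
    test_path: Optional[str] = None
    synthetic: Optional[SyntheticSpec] = None
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if (self.path is None) == (self.synthetic is None):
            raise ConfigurationError(
                f"dataset {self.name!r}: give exactly one of path / synthetic"
            )


@dataclass
class ApproachConfig:
    name: str
    parameters: dict = field(default_factory=dict)


@dataclass
class ExperimentConfig:
    datasets: list[DatasetSource]
    approaches: list[ApproachConfig]
    classifiers: list[dict]
    metrics: list[str] = field(default_factory=lambda: ["accuracy", "gm", "auc"])
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "experiment_out"

    def __post_init__(self) -> None:
        if not (self.datasets and self.approaches and self.classifiers
                and self.metrics):
            raise ConfigurationError(
                "need at least one dataset, approach, classifier and metric"
            )
        for m in self.metrics:
            if m not in _METRIC_KEYS:
                raise ConfigurationError(f"unknown metric {m!r}")

    # -- round trip through YAML -----------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "datasets": [
                {k: (asdict(v) if isinstance(v, SyntheticSpec) else v)
                 for k, v in asdict(d).items() if v is not None}
                for d in self.datasets
            ],
            "approaches": [asdict(a) for a in self.approaches],
            "classifiers": self.classifiers,
            "metrics": self.metrics,
            "alpha": self.alpha,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text())
        datasets = []
        for d in doc["datasets"]:
            d = dict(d)
            if "synthetic" in d and d["synthetic"] is not None:
                d["synthetic"] = SyntheticSpec(**d["synthetic"])
            datasets.append(DatasetSource(**d))
        approaches = [ApproachConfig(**a) for a in doc["approaches"]]
        return cls(
            datasets=datasets,
            approaches=approaches,
            classifiers=list(doc["classifiers"]),
            metrics=list(doc.get("metrics", ["accuracy", "gm", "auc"])),
            alpha=float(doc.get("alpha", 0.05)),
            seed=int(doc.get("seed", 0)),
            output_dir=str(doc.get("output_dir", "experiment_out")),
        )


def _resolve_dataset(src: DatasetSource,
                     seed: int) -> tuple[ImageDataset, ImageDataset]:
    if src.synthetic is not None:
        return (generate_dataset(src.synthetic, draw=0),
                generate_dataset(src.synthetic, draw=1))
    full = _io.load_image_folder(src.path)
    if src.test_path:
        return full, _io.load_image_folder(src.test_path)
    split = _io.split_train_validation(full, src.test_fraction, seed)
    return split.train, split.validation


def _build_approach(cfg: ApproachConfig, train: ImageDataset,
                    seed: int) -> Approach:
    params = dict(cfg.parameters)
    if cfg.name == "traditional":
        return traditional()
    if cfg.name == "md":
        return mean_denoising(
            patch_radius=int(params.get("patch_radius", 1)),
            search_radius=int(params.get("search_radius", 5)),
            h=float(params.get("h", 0.1)),
        )
    if cfg.name == "cae":
        settings = CAETrainSettings(
            learning_rate=float(params.get("learning_rate", 1e-3)),
            batch_size=int(params.get("batch_size", 32)),
            max_epochs=int(params.get("max_epochs", 30)),
            early_stop_patience=int(params.get("patience", 5)),
            seed=seed,
        )
        return cae_compression(train_cae(train, settings))
    raise ConfigurationError(f"unknown approach {cfg.name!r}")


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the grid; write metric CSVs, stats JSON and a run manifest.

    Returns a dict with the metric tables and fitted comparison results.
    Any stage failure is re-raised naming the (dataset, approach,
    classifier) triple, after a FAILED marker is written next to whatever
    partial outputs exist.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    block_labels: list[str] = []
    columns = [a.name for a in cfg.approaches]
    rows: dict[str, list[list[float]]] = {m: [] for m in cfg.metrics}
    manifest: dict = {"seed": cfg.seed, "stages": []}
    t_start = time.time()
    try:
        for ds_i, src in enumerate(cfg.datasets):
            stage = (src.name, "-", "-")
            train, test = _resolve_dataset(src, cfg.seed + ds_i)
            arms = {}
            for ap in cfg.approaches:
                stage = (src.name, ap.name, "-")
                t0 = time.time()
                approach = _build_approach(ap, train, cfg.seed + ds_i)
                arms[ap.name] = (apply_approach(approach, train),
                                 apply_approach(approach, test))
                manifest["stages"].append({
                    "stage": "preprocess", "dataset": src.name,
                    "approach": ap.name,
                    "seconds": round(time.time() - t0, 3),
                })
            for clf_i, clf_cfg in enumerate(cfg.classifiers):
                backbone = clf_cfg.get("backbone", "reference_small_cnn")
                block_labels.append(f"{src.name}/{backbone}")
                per_metric: dict[str, list[float]] = {m: [] for m in cfg.metrics}
                for ap in cfg.approaches:
                    stage = (src.name, ap.name, backbone)
                    t0 = time.time()
                    arm_train, arm_test = arms[ap.name]
                    spec = ClassifierSpec(
                        backbone=backbone,
                        n_classes=arm_train.n_classes,
                        learning_rate=float(clf_cfg.get("learning_rate", 1e-3)),
                        batch_size=int(clf_cfg.get("batch_size", 32)),
                        max_epochs=int(clf_cfg.get("max_epochs", 20)),
                        early_stop_patience=int(clf_cfg.get("patience", 5)),
                        seed=cfg.seed + 31 * ds_i + clf_i,
                    )
                    model = fit_classifier(spec, arm_train)
                    scores = model.predict_proba(arm_test)
                    result = evaluate_predictions(scores, arm_test.labels)
                    for m in cfg.metrics:
                        per_metric[m].append(result[_METRIC_KEYS[m]])
                    manifest["stages"].append({
                        "stage": "classify", "dataset": src.name,
                        "approach": ap.name, "classifier": backbone,
                        "seconds": round(time.time() - t0, 3),
                        "accuracy": result["accuracy"],
                    })
                for m in cfg.metrics:
                    rows[m].append(per_metric[m])
    except Exception as exc:
        (out / "FAILED").write_text(
            f"failed at dataset={stage[0]} approach={stage[1]} "
            f"classifier={stage[2]}: {exc}\n"
        )
        raise CaeprepError(
            f"experiment failed at dataset={stage[0]}, approach={stage[1]}, "
            f"classifier={stage[2]}: {exc}"
        ) from exc

    tables: dict[str, MetricTable] = {}
    reports: dict[str, object] = {}
    for m in cfg.metrics:
        table = MetricTable(rows[m], list(block_labels), list(columns), m)
        tables[m] = table
        _io.write_metric_table(table, out / f"{m}.csv")
        if table.n_blocks >= 2:
            res = FriedmanAlignedRanks(table).fit(alpha=cfg.alpha)
            reports[m] = res
            (out / f"{m}_stats.json").write_text(
                json.dumps(res.to_dict(), indent=2)
            )
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"tables": tables, "reports": reports, "manifest": manifest}


def compare_tables(tables: list[MetricTable], alpha: float = 0.05):
    """Stats-only mode: stack tables block-wise and run the comparison."""
    combined = tables[0] if len(tables) == 1 else MetricTable.concat(tables)
    return FriedmanAlignedRanks(combined).fit(alpha=alpha)
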