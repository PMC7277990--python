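"""End-to-end experiment orchestration.

Runs the full pipeline — dataset (synthetic or on disk), pre-processing,
stratified k-fold partition with dev carve, class-balancing
augmentation, training, evaluation — for every (fold, run) cell, and
aggregates the per-cell metric rows into the report tables: a
fold x run metric table with mean and standard-deviation rows, per-run
confusion matrices, and the across-runs average confusion matrix in
row-percent form.  Every artifact carries the configuration hash and
seeds; completed (fold, run) cells are skipped on re-run, so an
interrupted experiment resumes where it stopped.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import augmentation as aug
from . import dataset_io, metrics, partitioning
from .model import SpermHeadCNNClassifier
from .synthetic_data import SyntheticDatasetConfig, generate_dataset

logger = logging.getLogger("spermhead")

__all__ = ["ExperimentConfig", "run_experiment", "report", "preprocess_dataset"]


@dataclass
class ExperimentConfig:
    """One structured description of a full cross-validation experiment."""

    out_dir: str = "runs/experiment"
    # data source: either a synthetic generator config or a directory
    synthetic: dict | None = None
    data_root: str | None = None
    manifest: str | None = None
    # pre-processing preset: "scian" (orient + 3ch), "hushem" (orient +
    # center-crop + 3ch) or "none" (3ch only)
    preprocess: str = "scian"
    crop_size: int = 90
    # partition / augmentation protocol
    k: int = 5
    runs: int = 3
    dev_fraction: float = 0.2
    cap: int = aug.DEFAULT_CAP
    uniform_augmentation: bool = False
    rotation_limit: int = 5
    # model
    architecture: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 1 or self.k < 2:
            raise ValueError("need runs >= 1 and k >= 2")
        if self.synthetic is None and self.data_root is None:
            raise ValueError("configure either a synthetic source or data_root")
        if self.preprocess not in ("scian", "hushem", "none"):
            raise ValueError("preprocess must be scian, hushem or none")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preprocess_dataset(ds: dataset_io.LabeledDataset, preset: str,
                       crop_size: int = 90) -> dataset_io.LabeledDataset:
    """Apply a preset's pre-processing chain to every record."""
    if preset == "none":
        return ds.map_images(dataset_io.to_three_channels)

    def chain(px: np.ndarray) -> np.ndarray:
        out = dataset_io.normalize_orientation(px)
        if preset == "hushem":
            out = dataset_io.center_crop(out, crop_size)
        return dataset_io.to_three_channels(out)

    return ds.map_images(chain)


def _load_source(config: ExperimentConfig) -> dataset_io.LabeledDataset:
    if config.synthetic is not None:
        syn = SyntheticDatasetConfig(**config.synthetic)
        return generate_dataset(syn)
    return dataset_io.load_dataset(config.data_root, config.manifest)


def _write_aug_manifest(path: Path, plan: aug.AugmentationPlan,
                        train_set: dataset_io.LabeledDataset) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path_or_virtual_id", "class_name", "source_id",
                    "rotation_deg", "translation", "flip"])
        for rec in train_set.records:
            for t in plan.selected[rec.class_name]:
                vid = rec.id if t == aug.IDENTITY else \
                    f"{rec.id}#r{t.rotation_deg:+d}_{t.translation}_{t.flip}"
                w.writerow([vid, rec.class_name, rec.id,
                            t.rotation_deg, t.translation, t.flip])


def run_experiment(config: ExperimentConfig,
                   only_cell: tuple[int, int] | None = None) -> Path:
    """Execute k x runs train/evaluate cycles; returns the bundle directory.

    ``only_cell=(fold, run)`` trains just that cell (no aggregation),
    which together with resumability lets cells be distributed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "provenance.json").write_text(json.dumps(
        {"config_hash": chash, "base_seed": config.base_seed,
         "run_seeds": [config.base_seed + r for r in range(1, config.runs + 1)],
         "config": dataclasses.asdict(config)}, indent=2, default=str))

    stage = "load"
    try:
        ds = _load_source(config)
        stage = "preprocess"
        ds = preprocess_dataset(ds, config.preprocess, config.crop_size)
        stage = "partition"
        plan = partitioning.stratified_kfold(ds, config.k, seed=config.base_seed)
        if config.dev_fraction > 0:
            plan = partitioning.carve_dev_set(plan, ds, config.dev_fraction)
        plan.to_csv(out / "folds.csv")
    except Exception as exc:
        raise RuntimeError(f"stage={stage} failed (seed={config.base_seed}): {exc}") from exc

    space = aug.AugmentationSpace(rotation_limit=config.rotation_limit)
    for fold in range(1, config.k + 1):
        for run in range(1, config.runs + 1):
            if only_cell is not None and (fold, run) != tuple(only_cell):
                continue
            cell = out / f"fold{fold}_run{run}"
            if (cell / "metrics.csv").exists():
                logger.info("skipping completed cell fold=%d run=%d", fold, run)
                continue
            seed = config.base_seed + run
            try:
                _run_cell(config, ds, plan, space, fold, run, seed, cell, chash)
            except Exception as exc:
                raise RuntimeError(
                    f"stage=train/evaluate fold={fold} run={run} seed={seed}: {exc}"
                ) from exc
    if only_cell is None:
        _aggregate(out, config)
    return out


def _run_cell(config: ExperimentConfig, ds, plan, space, fold: int, run: int,
              seed: int, cell: Path, chash: str) -> None:
    cell.mkdir(parents=True, exist_ok=True)
    train_set = ds.subset(plan.train_ids(fold))
    test_set = ds.subset(plan.test_ids(fold))
    aplan = aug.build_plan(train_set.class_counts(), space=space, cap=config.cap,
                           uniform=config.uniform_augmentation, seed=seed)
    _write_aug_manifest(cell / "augmentation.csv", aplan, train_set)
    aug_set = aug.materialize(train_set, aplan)
    x_train, y_train = aug_set.arrays()
    dev = None
    if fold == 1 and plan.dev_ids:
        x_dev, y_dev = ds.subset(plan.dev_ids).arrays()
        dev = (x_dev, y_dev)
    clf = SpermHeadCNNClassifier(**config.architecture, **config.training,
                                 random_state=seed)
    logger.info("fold %d run %d: training on %d images", fold, run, len(x_train))
    clf.fit(x_train, y_train, dev=dev)
    pd.DataFrame(clf.history_).to_csv(cell / "history.csv", index=False)

    x_test, y_test = test_set.arrays()
    proba = clf.predict_proba(x_test)
    y_pred = clf.classes_[proba.argmax(axis=1)]
    cm = metrics.confusion_from_predictions(y_test, y_pred, list(ds.class_names))
    # align score columns to the dataset class order
    order = [list(clf.classes_).index(c) for c in ds.class_names]
    row = metrics.metric_report(cm, proba[:, order], y_test)
    row.update({"fold": fold, "run": run, "seed": seed, "config_hash": chash,
                "best_epoch": clf.best_epoch_})
    pd.DataFrame([row]).to_csv(cell / "metrics.csv", index=False)
    cm.to_frame().to_csv(cell / "cm_counts.csv")
    pd.DataFrame(metrics.percent_views(cm), index=ds.class_names,
                 columns=ds.class_names).to_csv(cell / "cm_percent.csv")


def _collect(out: Path, config: ExperimentConfig) -> tuple[pd.DataFrame, list]:
    rows, missing = [], []
    for fold in range(1, config.k + 1):
        for run in range(1, config.runs + 1):
            cell = out / f"fold{fold}_run{run}"
            if (cell / "metrics.csv").exists():
                rows.append(pd.read_csv(cell / "metrics.csv"))
            else:
                missing.append((fold, run))
    frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return frame, missing


def _aggregate(out: Path, config: ExperimentConfig) -> None:
    frame, missing = _collect(out, config)
    if missing:
        raise RuntimeError(f"incomplete bundle; missing (fold, run) cells: {missing}")
    numeric = frame.drop(columns=["fold", "run", "seed", "config_hash"])
    summary = pd.concat([
        frame,
        pd.DataFrame([{"fold": "average", **numeric.mean().to_dict()},
                      {"fold": "std", **numeric.std(ddof=1).to_dict()}]),
    ], ignore_index=True)
    summary.to_csv(out / "metrics_all.csv", index=False)
    # across-runs average confusion matrix, in row-percent space
    mats = []
    names = None
    for fold in range(1, config.k + 1):
        for run in range(1, config.runs + 1):
            m = pd.read_csv(out / f"fold{fold}_run{run}" / "cm_percent.csv", index_col=0)
            names = list(m.index)
            mats.append(m.to_numpy())
    avg = np.mean(mats, axis=0)
    pd.DataFrame(avg, index=names, columns=names).to_csv(out / "cm_percent_avg.csv")


def report(bundle: str | Path) -> dict:
    """Render the comparison-table layout from a completed bundle.

    Returns a dict with the average confusion matrix (percent), the
    per-class TPR row and the headline averages; also writes
    ``report.csv`` and ``report.txt`` into the bundle directory.
    """
    out = Path(bundle)
    prov = json.loads((out / "provenance.json").read_text())
    cfg = prov["config"]
    k, runs = int(cfg["k"]), int(cfg["runs"])
    missing = [(f, r) for f in range(1, k + 1) for r in range(1, runs + 1)
               if not (out / f"fold{f}_run{r}" / "metrics.csv").exists()]
    if missing:
        raise RuntimeError(f"incomplete bundle; missing (fold, run) cells: {missing}")
    if not (out / "cm_percent_avg.csv").exists():
        _aggregate(out, ExperimentConfig(**{k_: v for k_, v in cfg.items()}))
    avg = pd.read_csv(out / "cm_percent_avg.csv", index_col=0)
    class_names = list(avg.index)
    sizes = _test_class_sizes(out, class_names)
    cm = metrics.percent_to_counts(avg.to_numpy(), sizes, class_names)
    macro = metrics.average_metrics(cm, "macro")
    headline = {
        "per_class_tpr": {c: float(avg.to_numpy()[i, i]) for i, c in enumerate(class_names)},
        "accuracy": 100.0 * metrics.accuracy_weighted_tpr(cm),
        "recall_macro": 100.0 * macro["recall"],
        "precision_macro": 100.0 * macro["precision"],
        "specificity_macro": 100.0 * macro["specificity"],
        "f1_macro": 100.0 * macro["f1"],
        "config_hash": prov["config_hash"],
    }
    row = {**{f"tpr_{c}": v for c, v in headline["per_class_tpr"].items()},
           **{k_: v for k_, v in headline.items() if k_ not in ("per_class_tpr",)}}
    pd.DataFrame([row]).to_csv(out / "report.csv", index=False)
    lines = ["Average confusion matrix (row %):", avg.round(1).to_string(), "",
             "Per-class TPR (%): " + "  ".join(
                 f"{c}={headline['per_class_tpr'][c]:.0f}" for c in class_names),
             f"Accuracy (weighted avg TPR): {headline['accuracy']:.0f}%",
             f"Macro recall: {headline['recall_macro']:.0f}%  "
             f"precision: {headline['precision_macro']:.0f}%  "
             f"specificity: {headline['specificity_macro']:.0f}%  "
             f"F1: {headline['f1_macro']:.0f}%",
             f"config hash: {prov['config_hash']}"]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return headline


def _test_class_sizes(out: Path, class_names: list[str]) -> np.ndarray:
    """Average per-class test-fold size, from the stored fold plan."""
    plan = partitioning.FoldPlan.from_csv(out / "folds.csv")
    quotas = plan.class_quotas()
    return np.array([np.mean(quotas[c]) for c in class_names])
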