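"""End-to-end pipeline runner: simulate → preprocess → features → CV → report.

All artifacts are written under a single output directory; every stage is
seeded from the run configuration, so repeating a run reproduces the same
bytes.  Outputs are staged in memory and written last, so a failed stage
leaves no partial report files behind.
"""

from __future__ import annotations

import csv
import logging
import time
from pathlib import Path

import numpy as np

from .config import RunConfig
from .evaluation import roc_curve_auc
from .features import feature_table
from .image import CLASS_LABELS, load_image
from .phantom import DatasetManifest, generate_dataset
from .pipeline import crossval_pipeline, fold_report

logger = logging.getLogger("thermoclass")


def load_manifest_images(manifest_path: str | Path):
    """Read every image referenced by a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise IOError(f"manifest not found: {manifest_path}")
    manifest = DatasetManifest.read_csv(manifest_path)
    images, labels = [], []
    for rel, label, _ in manifest.records:
        tg = load_image(manifest_path.parent / rel)
        tg.label = label
        images.append(tg)
        labels.append(label)
    return images, labels


def write_fold_csv(report: dict, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["fold", "accuracy", "precision_macro", "sensitivity_macro",
                    "specificity_macro", "f1_macro", "auc_macro", "n_errors"])
        for f in report["folds"]:
            w.writerow([f["fold"], f["accuracy"], f["precision_macro"],
                        f["sensitivity_macro"], f["specificity_macro"],
                        f["f1_macro"], f["auc_macro"], f["n_errors"]])


def write_roc_csv(y, decisions, path: Path) -> None:
    """Pooled held-out ROC points, one row per (class, threshold)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "threshold", "fpr", "tpr"])
        for c, name in enumerate(CLASS_LABELS):
            binary = (np.asarray(y) == c).astype(int)
            if binary.min() == binary.max():
                continue
            fpr, tpr, thr, _ = roc_curve_auc(decisions[:, c], binary)
            for t, fp, tp in zip(thr, fpr, tpr):
                w.writerow([name, t, fp, tp])


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full study on synthetic phantoms and write all artifacts.

    Writes data/ (images + manifest), features.csv, report.json,
    folds.csv, roc.csv.  Returns the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    sim = config.simulate
    counts = {label: sim.n_per_class for label in CLASS_LABELS}
    stage = "simulate"
    try:
        generate_dataset(counts, out_dir / "data", seed=config.seed,
                         height=sim.height, width=sim.width,
                         noise_sd=sim.noise_sd,
                         background_gradient=sim.background_gradient,
                         write_masks=sim.write_masks)
        logger.info("simulate: %d images in %.1fs", sum(counts.values()), time.time() - t0)

        stage = "load"
        images, labels = load_manifest_images(out_dir / "data" / "manifest.csv")

        stage = "features"
        names = [r[0] for r in DatasetManifest.read_csv(out_dir / "data" / "manifest.csv").records]
        df = feature_table(images, names, config.features.build())

        stage = "crossval"
        cfg = config.to_pipeline_config()
        k = config.evaluation.k
        folds, pooled_y, pooled_dec = crossval_pipeline(
            images, labels, cfg, k=k, seed=config.seed, return_pooled=True)
        report = fold_report(folds)
        report["seed"] = config.seed
        logger.info("crossval: mean accuracy %.3f in %.1fs",
                    report["mean_accuracy"], time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    df.to_csv(out_dir / "features.csv", index=False)
    (out_dir / "report.json").write_text(_dump_json(report))
    write_fold_csv(report, out_dir / "folds.csv")
    write_roc_csv(pooled_y, pooled_dec, out_dir / "roc.csv")
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return report


def _dump_json(obj) -> str:
    import json

    return json.dumps(obj, indent=2, sort_keys=True)
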