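"""End-to-end classification pipeline and model persistence.

Stages: phantom simulation (or a manifest of images on disk) →
preprocessing → input preparation (pooled pixels for the network path, or
the hand-crafted feature vector as a fallback) → residual-network
embedding + SVM head → evaluation.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .evaluation import FoldResult, error_histogram, kfold_cross_validate
from .features import FeatureConfig, extract_features
from .image import CLASS_LABELS, Thermogram
from .network import NetworkConfig, NetworkModel, TrainConfig, network_forward, train_network
from .preprocess import PreprocessConfig, preprocess
from .svm import KernelSpec, SVMModel, svm_train


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to go from raw thermograms to fold metrics.

    The classification path conditions images *without* rank equalization
    by default: per-image histogram equalization maps every image to the
    same intensity distribution, which is useful for display but removes
    the absolute thermal contrast that separates lesion classes.  The
    enhancement chain (DEHE) remains the default of
    :func:`~thermoclass.preprocess.preprocess` itself.

    ``augment`` trains on the 8 dihedral transforms (rotations/flips) of
    each patch and uses orbit-averaged embeddings, making the classifier
    invariant to the lattice symmetries of the thermogram.
    """

    mode: str = "network"  # "network" (pooled pixels) or "features" (hand-crafted)
    pool_size: int = 16    # network input = pool_size² pixels (local-mean resize)
    preprocess: PreprocessConfig = PreprocessConfig(equalization="none")
    features: FeatureConfig = FeatureConfig()
    network: NetworkConfig | None = None  # None → sized from the input
    train: TrainConfig = TrainConfig()
    kernel: KernelSpec = KernelSpec(kind="rbf")
    svm_c: float = 10.0
    augment: bool = True


def dihedral_orbit(X: np.ndarray, hw: int) -> np.ndarray:
    """The 8 lattice symmetries (4 rotations × reflection) of each flat patch.

    Input (B, hw²) → output (B, 8, hw²), original first.
    """
    X = np.atleast_2d(X)
    ims = X.reshape(-1, hw, hw)
    orbit = []
    for k in range(4):
        r = np.rot90(ims, k, axes=(1, 2))
        orbit.append(r)
        orbit.append(r[:, :, ::-1])
    return np.stack([o.reshape(len(ims), -1) for o in orbit], axis=1)


def prepare_inputs(images: list[Thermogram], cfg: PipelineConfig,
                   preprocessed: bool = False) -> np.ndarray:
    """Preprocess each image and flatten it into the classifier input matrix.

    Network mode: local-mean pooling to ``pool_size``² pixels, centered to
    roughly zero mean.  Feature mode: the per-image feature vector with
    degenerate entries imputed to 0.
    """
    rows = []
    for img in images:
        proc = img if preprocessed else preprocess(img, cfg.preprocess)
        if cfg.mode == "network":
            pooled = resize(proc.pixels, (cfg.pool_size, cfg.pool_size),
                            anti_aliasing=True)
            rows.append(pooled.ravel() - 0.5)
        elif cfg.mode == "features":
            fv = extract_features(proc, cfg.features)
            rows.append(np.nan_to_num(np.asarray(fv.to_row()), nan=0.0))
        else:
            raise ValueError(f"unknown pipeline mode {cfg.mode!r}")
    return np.asarray(rows)


@dataclass
class TrainedClassifier:
    """Frozen feature extractor + margin head, ready for prediction.

    Embeddings are standardized with the training-set mean/scale before
    they reach the kernel machine.
    """

    config: PipelineConfig
    network: NetworkModel | None
    svm: SVMModel
    emb_mean: np.ndarray | None = None
    emb_scale: np.ndarray | None = None
    training_losses: list[float] = field(default_factory=list)

    def embed(self, X: np.ndarray) -> np.ndarray:
        if self.network is None:
            emb = np.atleast_2d(X)
        elif self.config.augment:
            orbit = dihedral_orbit(X, self.config.pool_size)
            B, G, D = orbit.shape
            emb = network_forward(orbit.reshape(B * G, D), self.network)
            emb = emb.reshape(B, G, -1).mean(axis=1)
        else:
            emb = network_forward(X, self.network)
        if self.emb_mean is not None:
            emb = (emb - self.emb_mean) / self.emb_scale
        return emb

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svm.decision_values(self.embed(X))

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.embed(X))


def fit_classifier(X: np.ndarray, y: np.ndarray, cfg: PipelineConfig,
                   seed: int = 0) -> TrainedClassifier:
    """Train the residual network on the hinge surrogate, then fit the SVM
    on frozen embeddings (feature mode skips the network)."""
    n_classes = int(np.max(y)) + 1
    if cfg.mode == "network":
        net_cfg = cfg.network or NetworkConfig(kind="conv", input_hw=cfg.pool_size)
        if cfg.augment:
            orbit = dihedral_orbit(X, cfg.pool_size)
            X_fit = orbit.reshape(-1, orbit.shape[2])
            y_fit = np.repeat(y, orbit.shape[1])
        else:
            X_fit, y_fit = X, y
        net, log = train_network(X_fit, y_fit, n_classes, net_cfg, cfg.train, seed=seed)
        losses = log.losses
    else:
        net, losses = None, []
    partial = TrainedClassifier(config=cfg, network=net, svm=None)  # type: ignore[arg-type]
    emb = partial.embed(X)
    mean = emb.mean(axis=0)
    scale = emb.std(axis=0)
    scale[scale < 1e-12] = 1.0
    emb_std = (emb - mean) / scale
    svm = svm_train(emb_std, y, kernel=cfg.kernel, C=cfg.svm_c, seed=seed)
    return TrainedClassifier(config=cfg, network=net, svm=svm, emb_mean=mean,
                             emb_scale=scale, training_losses=losses)


def predict(img: Thermogram, clf: TrainedClassifier) -> tuple[str, np.ndarray]:
    """Classify one raw thermogram.

    Returns the class label (argmax of the one-vs-rest decision values in
    fixed enum order; exact ties resolve to the lowest class index) and
    the decision-value vector.
    """
    X = prepare_inputs([img], clf.config)
    dec = clf.decision_values(X)[0]
    return CLASS_LABELS[int(np.argmax(dec))], dec


def crossval_pipeline(images: list[Thermogram], labels: list[str],
                      cfg: PipelineConfig = PipelineConfig(), k: int = 5,
                      seed: int = 0, return_pooled: bool = False):
    """Stratified k-fold CV of the full pipeline on labeled thermograms.

    With ``return_pooled`` also returns the held-out true labels and
    decision values pooled over folds (for ROC export).
    """
    y = np.array([CLASS_LABELS.index(l) for l in labels], dtype=np.int64)
    X = prepare_inputs(images, cfg)
    collected: list[np.ndarray] = []

    def fit_predict(X_tr, y_tr, X_te, fold_seed):
        clf = fit_classifier(X_tr, y_tr, cfg, seed=fold_seed)
        dec = clf.decision_values(X_te)
        collected.append(dec)
        return clf.predict_indices(X_te), dec

    folds = kfold_cross_validate(X, y, fit_predict, k=k, seed=seed)
    if not return_pooled:
        return folds
    from .evaluation import kfold_indices

    pooled_y = np.concatenate([y[te] for _, te in kfold_indices(y, k, seed)])
    return folds, pooled_y, np.vstack(collected)


def fold_report(folds: list[FoldResult]) -> dict:
    """JSON-ready nested report for a CV run."""
    errors, err_mean, err_std = error_histogram(folds)
    return {
        "schema_version": 1,
        "n_folds": len(folds),
        "folds": [
            {
                "fold": f.fold_index,
                "accuracy": f.metrics.accuracy,
                "precision_macro": f.metrics.macro_precision,
                "sensitivity_macro": f.metrics.macro_sensitivity,
                "specificity_macro": f.metrics.macro_specificity,
                "f1_macro": f.metrics.macro_f1,
                "auc_macro": f.macro_auc,
                "auc_per_class": f.auc_per_class,
                "n_errors": f.n_errors,
                "confusion": f.confusion.tolist(),
            }
            for f in folds
        ],
        "mean_accuracy": float(np.mean([f.metrics.accuracy for f in folds])),
        "error_counts": errors,
        "error_mean": err_mean,
        "error_std": err_std,
    }


# --------------------------------------------------------------------------
# model persistence: JSON header + raw little-endian float32 blobs

_MAGIC = b"TCMODEL1"


def _collect_arrays(clf: TrainedClassifier) -> tuple[dict, list[np.ndarray]]:
    arrays: list[np.ndarray] = []
    header: dict = {"schema_version": 1, "mode": clf.config.mode,
                    "pool_size": clf.config.pool_size,
                    "augment": clf.config.augment,
                    "svm_scheme": clf.svm.scheme,
                    "classes": clf.svm.classes, "entries": []}

    def add(name: str, arr: np.ndarray) -> None:
        header["entries"].append({"name": name, "shape": list(arr.shape)})
        arrays.append(np.ascontiguousarray(arr, dtype="<f4"))

    if clf.network is not None:
        nc = clf.network.config
        header["network"] = {
            "kind": nc.kind, "input_hw": nc.input_hw, "input_dim": nc.input_dim,
            "prn_widths": list(nc.prn_widths),
            "backbone_widths": list(nc.backbone_widths),
            "blocks_per_stage": nc.blocks_per_stage, "fusion": nc.fusion,
        }
        for path, blocks in (("prn", clf.network.prn_blocks),
                             ("backbone", clf.network.backbone_blocks)):
            for i, blk in enumerate(blocks):
                for pname in ("W1", "b1", "W2", "b2"):
                    add(f"{path}.{i}.{pname}", getattr(blk, pname))
                if blk.P is not None:
                    add(f"{path}.{i}.P", blk.P)
    if clf.emb_mean is not None:
        add("emb_mean", clf.emb_mean)
        add("emb_scale", clf.emb_scale)
    for c in clf.svm.classes:
        m = clf.svm.machines[c]
        header.setdefault("svm", {})[str(c)] = {
            "bias": m.bias, "kernel": {"kind": m.kernel.kind, "gamma": m.kernel.gamma,
                                       "coef0": m.kernel.coef0, "degree": m.kernel.degree},
        }
        add(f"svm.{c}.support_vectors", m.support_vectors)
        add(f"svm.{c}.support_alphas", m.support_alphas)
        add(f"svm.{c}.support_labels", m.support_labels)
    return header, arrays


def save_model(clf: TrainedClassifier, path: str | Path) -> None:
    """Single-file archive: magic, JSON header, then float32 blobs."""
    header, arrays = _collect_arrays(clf)
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        for arr in arrays:
            fh.write(arr.tobytes())


def load_model(path: str | Path) -> TrainedClassifier:
    from .svm import BinarySVM

    with open(path, "rb") as fh:
        if fh.read(8) != _MAGIC:
            raise IOError(f"{path} is not a thermoclass model file")
        n = struct.unpack("<I", fh.read(4))[0]
        header = json.loads(fh.read(n).decode())
        data: dict[str, np.ndarray] = {}
        for entry in header["entries"]:
            shape = tuple(entry["shape"])
            count = int(np.prod(shape)) if shape else 1
            arr = np.frombuffer(fh.read(4 * count), dtype="<f4").reshape(shape)
            data[entry["name"]] = arr.astype(np.float64)

    network = None
    cfg_kwargs: dict = {"mode": header["mode"], "pool_size": header["pool_size"],
                        "augment": header.get("augment", False)}
    if "network" in header:
        nc = header["network"]
        net_cfg = NetworkConfig(kind=nc["kind"], input_hw=nc["input_hw"],
                                input_dim=nc["input_dim"],
                                prn_widths=tuple(nc["prn_widths"]),
                                backbone_widths=tuple(nc["backbone_widths"]),
                                blocks_per_stage=nc["blocks_per_stage"],
                                fusion=nc["fusion"])
        network = NetworkModel.init(net_cfg, seed=0)
        for path_name, blocks in (("prn", network.prn_blocks),
                                  ("backbone", network.backbone_blocks)):
            for i, blk in enumerate(blocks):
                blk.W1 = data[f"{path_name}.{i}.W1"]; blk.b1 = data[f"{path_name}.{i}.b1"]
                blk.W2 = data[f"{path_name}.{i}.W2"]; blk.b2 = data[f"{path_name}.{i}.b2"]
                if blk.P is not None:
                    blk.P = data[f"{path_name}.{i}.P"]
        cfg_kwargs["network"] = net_cfg

    svm = SVMModel(classes=header["classes"], scheme=header["svm_scheme"])
    for c in header["classes"]:
        info = header["svm"][str(c)]
        ks = info["kernel"]
        svm.machines[c] = BinarySVM(
            support_vectors=data[f"svm.{c}.support_vectors"],
            support_alphas=data[f"svm.{c}.support_alphas"],
            support_labels=data[f"svm.{c}.support_labels"],
            bias=info["bias"],
            kernel=KernelSpec(kind=ks["kind"], gamma=ks["gamma"],
                              coef0=ks["coef0"], degree=ks["degree"]))
    return TrainedClassifier(config=PipelineConfig(**cfg_kwargs), network=network, svm=svm,
                             emb_mean=data.get("emb_mean"), emb_scale=data.get("emb_scale"))
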