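"""End-to-end orchestration: data -> preprocessing -> augmentation ->
feature extraction -> fusion/tree heads -> evaluation.

Every run is driven by a :class:`PipelineConfig` (YAML-serializable, always
seeded) and leaves a self-describing run directory behind: the resolved
config, per-epoch training history, evaluation reports, model checkpoints and
a reproducibility record (package versions + seed). Identical config + seed
reproduce identical reports bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augment import balance_training_set, build_policy, default_policy
from .backbones import build_backbone, checksum
from .errors import DataError, ParameterError
from .evaluation import (EvalReport, comparison_table, confusion_matrix,
                         metrics_from_cm)
from .fluorescence import FluorescenceConfig, fluorescence_simulate
from .fusion import (build_fusion_model, extract_pooled, predict_proba_features,
                     save_fusion_model, train_on_features)
from .gbt import GBTConfig, fit_gbt, predict_gbt
from .image import load_image, resize, save_image
from .synthetic import (CLASS_LABELS, DatasetManifest, GeneratorParams,
                        generate_dataset, load_image_folder)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "compare_models"]

logger = logging.getLogger("cadeye")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one end-to-end run.

    ``resize_width``/``resize_height`` follow the width x height convention of
    image spec sheets (default 700 x 600 -> arrays of shape (600, 700, 3)).
    ``data_dir`` switches from synthetic generation to any user-supplied
    class-per-subdirectory image folder.
    """

    seed: int = 0
    workdir: str = "cadeye_run"
    data_dir: str | None = None
    n_per_class: int = 50
    raw_height: int = 1264
    raw_width: int = 1125
    test_fraction: float = 0.15
    # preprocessing
    alpha: float = 2.0
    suppress_blue: bool = True
    colormap: str = "none"
    resize_width: int = 700
    resize_height: int = 600
    normalization: str = "unit"
    # augmentation
    balance: bool = True
    augment_policy: list | None = None   # None -> package default policy
    # model
    backbone_scale: str = "tiny"
    fusion_mode: str = "concat"
    head_variant: str = "extended"
    head_type: str = "both"              # softmax | gbt | both
    epochs: int = 15
    learning_rate: float = 3e-3
    batch_size: int = 32
    val_fraction: float = 0.1
    # tree head
    gbt_eta: float = 0.3
    gbt_lam: float = 1.0
    gbt_tau: int = 50
    gbt_max_depth: int = 3
    gbt_representation: str = "penultimate"   # penultimate | probabilities

    def __post_init__(self):
        if self.resize_width < 1 or self.resize_height < 1:
            raise ParameterError("resize target must be positive")
        if self.head_type not in ("softmax", "gbt", "both"):
            raise ParameterError(f"unknown head type {self.head_type!r}")
        if self.seed is None:
            raise ParameterError("every run must be seeded")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_yaml(path_or_text) -> "PipelineConfig":
        text = path_or_text
        p = Path(str(path_or_text))
        if p.exists():
            text = p.read_text()
        return PipelineConfig(**(yaml.safe_load(text) or {}))


@dataclass
class PipelineResult:
    reports: dict                 # head name -> EvalReport
    history: list
    manifest: DatasetManifest
    class_names: list
    workdir: Path
    backbone_checksums: dict


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
            logger.info("stage %-14s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("data")
def _stage_data(cfg: PipelineConfig, workdir: Path) -> DatasetManifest:
    if cfg.data_dir is not None:
        manifest = load_image_folder(cfg.data_dir, cfg.test_fraction, cfg.seed)
    else:
        params = GeneratorParams(raw_height=cfg.raw_height, raw_width=cfg.raw_width,
                                 n_per_class=cfg.n_per_class, seed=cfg.seed,
                                 test_fraction=cfg.test_fraction)
        manifest = generate_dataset(params, workdir / "raw")
    logger.info("data: %d images, %d classes", len(manifest.records),
                manifest.records["label"].nunique())
    return manifest


@_stage("preprocess")
def _stage_preprocess(cfg: PipelineConfig, manifest: DatasetManifest,
                      workdir: Path) -> DatasetManifest:
    fcfg = FluorescenceConfig(alpha=cfg.alpha, suppress_blue=cfg.suppress_blue,
                              colormap=cfg.colormap)
    out_root = workdir / "processed"
    rows = []
    for rec in manifest.records.itertuples(index=False):
        img = load_image(rec.path)
        img = fluorescence_simulate(img, fcfg)
        img = resize(img, cfg.resize_width, cfg.resize_height)
        dest = out_root / rec.label / (Path(rec.path).stem + ".png")
        dest.parent.mkdir(parents=True, exist_ok=True)
        save_image(img, dest)
        rows.append({"path": str(dest), "label": rec.label,
                     "split": rec.split, "source": rec.source})
    logger.info("preprocess: %d images -> %dx%d", len(rows),
                cfg.resize_width, cfg.resize_height)
    return DatasetManifest(records=pd.DataFrame(rows))


@_stage("augment")
def _stage_augment(cfg: PipelineConfig, manifest: DatasetManifest) -> DatasetManifest:
    if not cfg.balance:
        return manifest
    policy = default_policy() if cfg.augment_policy is None \
        else build_policy(cfg.augment_policy)
    out = balance_training_set(manifest, policy, rng_seed=cfg.seed)
    logger.info("augment: train %d -> %d images",
                (manifest.records["split"] == "train").sum(),
                (out.records["split"] == "train").sum())
    return out


def _load_split(manifest: DatasetManifest, split: str, label_to_idx: dict):
    df = manifest.records[manifest.records["split"] == split]
    images = [load_image(p) for p in df["path"]]
    labels = np.array([label_to_idx[s] for s in df["label"]], dtype=np.int64)
    return images, labels


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all artifacts under the workdir."""
    cfg = config
    workdir = Path(cfg.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(workdir / "config.yaml")

    manifest = _stage_data(cfg, workdir)
    manifest = _stage_preprocess(cfg, manifest, workdir)
    manifest = _stage_augment(cfg, manifest)
    manifest.to_csv(workdir / "manifest.csv")

    labels_present = sorted(
        manifest.records["label"].unique(),
        key=lambda s: CLASS_LABELS.index(s) if s in CLASS_LABELS else 99)
    label_to_idx = {s: i for i, s in enumerate(labels_present)}
    num_classes = len(labels_present)
    if num_classes < 2:
        raise DataError("need at least two classes to train")

    t0 = time.perf_counter()
    bb_a = build_backbone("mobilenet_v2_like", cfg.backbone_scale, cfg.seed)
    bb_b = build_backbone("efficientnet_b0_like", cfg.backbone_scale, cfg.seed)
    checksums_before = {"mobilenet_v2_like": checksum(bb_a),
                        "efficientnet_b0_like": checksum(bb_b)}
    train_imgs, y_train = _load_split(manifest, "train", label_to_idx)
    test_imgs, y_test = _load_split(manifest, "test", label_to_idx)
    if len(train_imgs) == 0 or len(test_imgs) == 0:
        raise DataError("both train and test splits must be nonempty")
    fa_tr = extract_pooled(bb_a, train_imgs, normalization=cfg.normalization)
    fb_tr = extract_pooled(bb_b, train_imgs, normalization=cfg.normalization)
    fa_te = extract_pooled(bb_a, test_imgs, normalization=cfg.normalization)
    fb_te = extract_pooled(bb_b, test_imgs, normalization=cfg.normalization)
    logger.info("stage %-14s done in %.2fs (train %d, test %d images)",
                "extract", time.perf_counter() - t0, len(train_imgs), len(test_imgs))

    t0 = time.perf_counter()
    model = build_fusion_model(bb_a.output_channels, bb_b.output_channels,
                               num_classes, cfg.head_variant, cfg.fusion_mode,
                               cfg.seed)
    history = train_on_features(model, fa_tr, fb_tr, y_train, cfg.epochs,
                                seed=cfg.seed, lr=cfg.learning_rate,
                                batch_size=cfg.batch_size,
                                val_fraction=cfg.val_fraction)
    logger.info("stage %-14s done in %.2fs", "train-head", time.perf_counter() - t0)

    reports: dict[str, EvalReport] = {}
    if cfg.head_type in ("softmax", "both"):
        probs = predict_proba_features(model, fa_te, fb_te)
        cm = confusion_matrix(y_test, probs.argmax(axis=1), num_classes)
        reports["softmax"] = metrics_from_cm(cm, labels_present)
    gbt_ensemble = None
    if cfg.head_type in ("gbt", "both"):
        t0 = time.perf_counter()
        if cfg.gbt_representation == "probabilities":
            feats_tr = predict_proba_features(model, fa_tr, fb_tr)
            feats_te = predict_proba_features(model, fa_te, fb_te)
        else:
            feats_tr = model.penultimate(fa_tr, fb_tr)
            feats_te = model.penultimate(fa_te, fb_te)
        gbt_cfg = GBTConfig(eta=cfg.gbt_eta, lam=cfg.gbt_lam, tau=cfg.gbt_tau,
                            max_depth=cfg.gbt_max_depth, seed=cfg.seed)
        gbt_ensemble = fit_gbt(feats_tr, y_train, gbt_cfg)
        probs = predict_gbt(gbt_ensemble, feats_te)
        cm = confusion_matrix(y_test, probs.argmax(axis=1), num_classes)
        reports["gbt"] = metrics_from_cm(cm, labels_present)
        logger.info("stage %-14s done in %.2fs", "train-gbt", time.perf_counter() - t0)

    checksums_after = {"mobilenet_v2_like": checksum(bb_a),
                       "efficientnet_b0_like": checksum(bb_b)}
    if checksums_after != checksums_before:
        raise RuntimeError("freeze contract violated: backbone parameters changed")

    # artifacts
    pd.DataFrame(history).to_csv(workdir / "history.csv", index=False)
    for name, rep in reports.items():
        rep.to_json(workdir / f"report_{name}.json")
    primary = "gbt" if "gbt" in reports else "softmax"
    reports[primary].to_json(workdir / "report.json")
    save_fusion_model(model, workdir / "fusion_model")
    if gbt_ensemble is not None:
        with open(workdir / "gbt_model.json", "w") as fh:
            json.dump(gbt_ensemble.to_json(), fh)
    _write_reproducibility(cfg, workdir, checksums_after, labels_present)
    return PipelineResult(reports=reports, history=history, manifest=manifest,
                          class_names=labels_present, workdir=workdir,
                          backbone_checksums=checksums_after)


def _write_reproducibility(cfg, workdir, checksums, class_names):
    import PIL
    import scipy
    record = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "class_names": class_names,
        "backbone_checksums": checksums,
        "versions": {
            "cadeye": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "pillow": PIL.__version__,
        },
    }
    with open(workdir / "reproducibility.json", "w") as fh:
        json.dump(record, fh, indent=2)


def compare_models(configs, names=None) -> pd.DataFrame:
    """Run several configurations on equal epoch budgets and tabulate them.

    All configs must share the same epoch budget (a fairness constraint for
    model comparisons); each gets its own sub-workdir.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ParameterError("need at least two configurations to compare")
    epochs = {c.epochs for c in configs}
    if len(epochs) != 1:
        raise ParameterError(f"all configs must share one epoch budget, got {sorted(epochs)}")
    names = names or [f"model_{i}" for i in range(len(configs))]
    rows = []
    for name, cfg in zip(names, configs):
        cfg_i = replace(cfg, workdir=str(Path(cfg.workdir) / name))
        result = run_pipeline(cfg_i)
        primary = "gbt" if "gbt" in result.reports else "softmax"
        rows.append((name, result.reports[primary]))
    return comparison_table(rows)
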