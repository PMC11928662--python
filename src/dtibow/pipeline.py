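"""End-to-end experiment orchestration.

One *experiment cell* is a (detector × task × input) combination, where the
task is multiclass (NC/MCI/AD) or one of the three binary pairs and the
input is a single scalar map (RD, FA, MD), feature-level fusion of the
three, or decision-level fusion of the three per-map classifiers.  The five
inputs per task mirror the study design this package reproduces; each cell
is evaluated by stratified 10-fold cross-validation with the whole pipeline
refit per fold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bow import fuse_features
from .descriptors import (
    LocalFeature,
    SiftParams,
    SurfParams,
    extract_subject_features,
    features_from_frame,
    features_to_frame,
)
from .dti_maps import MAP_KINDS, read_mask, read_volume
from .model import (
    CVConfig,
    EvalReport,
    FeatureDataset,
    cross_validate,
    cross_validate_decision_fusion,
)

logger = logging.getLogger(__name__)

TASKS = {
    "multiclass": ("NC", "MCI", "AD"),
    "AD_vs_MCI": ("MCI", "AD"),
    "AD_vs_NC": ("NC", "AD"),
    "MCI_vs_NC": ("NC", "MCI"),
}

ROWS = ("RD", "FA", "MD", "feature_fusion", "decision_fusion")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full experiment grid."""

    manifest: str = "manifest.csv"
    out_dir: str = "results"
    detectors: tuple[str, ...] = ("SIFT", "SURF")
    tasks: tuple[str, ...] = tuple(TASKS)
    rows: tuple[str, ...] = ROWS
    axis: int = 2
    min_roi_pixels: int = 16
    percentiles: tuple[float, float] = (1.0, 99.0)
    sift: SiftParams = field(default_factory=SiftParams)
    surf: SurfParams = field(default_factory=SurfParams)
    K: int = 100
    fusion_mode: str = "descriptor_pool"  # or "histogram_concat"
    m_selected: int = 50
    folds: int = 10
    seed: int = 0
    svm_C: float | None = None
    svm_gamma: float | None = None
    codebook_scope: str = "fold"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("sift", SiftParams), ("surf", SurfParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("detectors", "tasks", "rows", "percentiles"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cv_config(self) -> CVConfig:
        return CVConfig(
            K=self.K,
            m_selected=self.m_selected,
            C=self.svm_C,
            gamma=self.svm_gamma,
            codebook_scope=self.codebook_scope,
        )


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the subject manifest CSV."""
    manifest = pd.read_csv(path)
    required = {"subject_id", "class_label", "mask_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks required columns: {sorted(missing)}")
    return manifest


def extract_manifest_features(
    manifest: pd.DataFrame, cfg: RunConfig, detector: str
) -> tuple[dict[str, dict[str, list[LocalFeature]]], dict[str, str]]:
    """Extract per-subject, per-map features for all subjects of a manifest."""
    features: dict[str, dict[str, list[LocalFeature]]] = {}
    labels: dict[str, str] = {}
    for _, row in manifest.iterrows():
        sid = str(row["subject_id"])
        mask = read_mask(row["mask_path"])
        maps = {}
        for kind in MAP_KINDS:
            col = f"{kind.lower()}_path"
            if col in manifest.columns and isinstance(row[col], str) and row[col]:
                maps[kind] = read_volume(row[col], expected_kind=kind)
        features[sid] = extract_subject_features(
            maps,
            mask,
            detector=detector,
            axis=cfg.axis,
            min_roi_pixels=cfg.min_roi_pixels,
            percentiles=cfg.percentiles,
            sift_params=cfg.sift,
            surf_params=cfg.surf,
        )
        labels[sid] = str(row["class_label"])
    return features, labels


def cache_features(
    features: dict[str, dict[str, list[LocalFeature]]], out_dir: str | Path
) -> None:
    """Persist per-subject feature tables as CSV (resumable intermediate)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, per_map in features.items():
        for kind, feats in per_map.items():
            features_to_frame(feats).to_csv(out_dir / f"{sid}_{kind}.csv", index=False)


def load_cached_features(
    cache_dir: str | Path, subject_ids: list[str]
) -> dict[str, dict[str, list[LocalFeature]]]:
    cache_dir = Path(cache_dir)
    out: dict[str, dict[str, list[LocalFeature]]] = {}
    for sid in subject_ids:
        per_map = {}
        for kind in MAP_KINDS:
            p = cache_dir / f"{sid}_{kind}.csv"
            if p.exists():
                per_map[kind] = features_from_frame(pd.read_csv(p))
        out[sid] = per_map
    return out


def _subset(
    features: dict[str, dict[str, list[LocalFeature]]],
    labels: dict[str, str],
    classes: tuple[str, ...],
) -> tuple[dict, dict]:
    keep = {s for s, c in labels.items() if c in classes}
    return (
        {s: features[s] for s in keep},
        {s: labels[s] for s in keep},
    )


def _single_map_dataset(
    features: dict, labels: dict, kind: str, detector: str
) -> FeatureDataset:
    missing = [s for s, per_map in features.items() if kind not in per_map]
    if missing:
        raise ValueError(f"{len(missing)} subjects lack {kind} features")
    return FeatureDataset(
        features={s: per_map[kind] for s, per_map in features.items()},
        labels=labels,
        detector=detector,
        source_maps=(kind,),
    )


def _fusion_dataset(
    features: dict, labels: dict, detector: str, mode: str
) -> FeatureDataset:
    missing = [
        s for s, per_map in features.items() if any(k not in per_map for k in MAP_KINDS)
    ]
    if missing:
        raise ValueError(f"{len(missing)} subjects lack one or more maps for fusion")
    if mode == "descriptor_pool":
        fused = {s: fuse_features(per_map) for s, per_map in features.items()}
    elif mode == "histogram_concat":
        fused = dict(features)
    else:
        raise ValueError(f"unknown fusion mode {mode!r}")
    return FeatureDataset(
        features=fused, labels=labels, detector=detector, source_maps=MAP_KINDS
    )


def run_cell(
    features: dict[str, dict[str, list[LocalFeature]]],
    labels: dict[str, str],
    detector: str,
    task: str,
    row: str,
    cfg: RunConfig,
) -> EvalReport:
    """Evaluate one experiment cell (detector × task × input)."""
    classes = TASKS[task]
    feats, labs = _subset(features, labels, classes)
    name = f"{detector}/{task}/{row}"
    cv_cfg = cfg.cv_config()
    if row in MAP_KINDS:
        ds = _single_map_dataset(feats, labs, row, detector)
        return cross_validate(ds, k=cfg.folds, seed=cfg.seed, config=cv_cfg, name=name)
    if row == "feature_fusion":
        ds = _fusion_dataset(feats, labs, detector, cfg.fusion_mode)
        return cross_validate(ds, k=cfg.folds, seed=cfg.seed, config=cv_cfg, name=name)
    if row == "decision_fusion":
        per_map = {
            kind: _single_map_dataset(feats, labs, kind, detector) for kind in MAP_KINDS
        }
        return cross_validate_decision_fusion(
            per_map, k=cfg.folds, seed=cfg.seed, config=cv_cfg, name=name
        )
    raise ValueError(f"unknown experiment row {row!r}")


def run_experiments(
    cfg: RunConfig,
    features_by_detector: dict[str, dict] | None = None,
    labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Run the full experiment grid and write summaries, ROC files and a log.

    Features may be passed in-memory (``features_by_detector[detector]``);
    otherwise they are extracted from the manifest.  A failing cell is
    logged and skipped; the rest proceed.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "roc").mkdir(exist_ok=True)

    if features_by_detector is None:
        manifest = load_manifest(cfg.manifest)
        features_by_detector = {}
        for det in cfg.detectors:
            feats, labels = extract_manifest_features(manifest, cfg, det)
            features_by_detector[det] = feats

    summaries = []
    for det in cfg.detectors:
        feats = features_by_detector[det]
        for task in cfg.tasks:
            for row in cfg.rows:
                try:
                    report = run_cell(feats, labels, det, task, row, cfg)
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    logger.error("cell %s/%s/%s failed: %s", det, task, row, exc)
                    warnings.warn(f"cell {det}/{task}/{row} aborted: {exc}", stacklevel=2)
                    continue
                summaries.append(report.summary())
                if report.roc_points is not None:
                    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(
                        out_dir / "roc" / f"{det}_{task}_{row}.csv", index=False
                    )
    summary = (
        pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    )
    summary.to_csv(out_dir / "summary.csv", index=False)
    log = dataclasses.asdict(cfg)
    log["n_cells_completed"] = len(summaries)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return summary
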