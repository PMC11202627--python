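"""End-to-end pipeline: images -> features -> balanced dataset -> classifier.

Wires the phantom generator (or an on-disk image manifest) through lumen
segmentation, wall measurement, patch splitting, color quantification, feature
assembly, SMOTE balancing, k-fold validation and group statistics, writing all
artifacts plus a reproducibility manifest to one output directory. Every
random stage is seeded from the single config seed, so rerunning the same
config reproduces identical CSV/JSON content.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import classify, colorfeat, dataset, morphometry, phantom, stats
from .types import BAND_NAMES, CLASSES, OctImagePair

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "extract_features", "features_to_dataset"]


@dataclass
class PipelineConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    output_dir: str = "octfib_out"
    input_manifest: str | None = None  # CSV with image paths; None -> phantoms
    phantom: dict = field(
        default_factory=lambda: {"n_per_class": 20, "n_alveoli": 30, "image_shape": [320, 320]}
    )
    segmentation: dict = field(default_factory=dict)
    color_bands: dict = field(
        default_factory=lambda: {"sat_min": colorfeat.DEFAULT_SAT_MIN, "val_min": colorfeat.DEFAULT_VAL_MIN}
    )
    patch: dict = field(default_factory=lambda: {"per_patch": 10, "min_last": 5})
    smote: dict = field(default_factory=lambda: {"k": 5, "mode": "inside_folds"})
    model: dict = field(default_factory=lambda: {"family": "gradient_boosting", "hyperparameters": {}})
    cv: dict = field(default_factory=lambda: {"k": 10})
    qc_overlays: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def seg_params(self) -> morphometry.SegmentationParams:
        return morphometry.SegmentationParams(**self.segmentation)

    def bands(self) -> list[colorfeat.HueBand]:
        return colorfeat.default_bands(
            sat_min=self.color_bands.get("sat_min", colorfeat.DEFAULT_SAT_MIN),
            val_min=self.color_bands.get("val_min", colorfeat.DEFAULT_VAL_MIN),
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def extract_features(
    pair: OctImagePair,
    seg_params: morphometry.SegmentationParams | None = None,
    bands: list[colorfeat.HueBand] | None = None,
    per_patch: int = 10,
    min_last: int = 5,
) -> tuple[list[pd.Series], dict]:
    """Segment one image pair and return its per-patch feature rows.

    Also returns per-image QC counts (alveoli found/kept, patches made) and
    the labeled lumen image for overlay rendering.
    """
    seg_params = seg_params or morphometry.SegmentationParams()
    labels_img, records = morphometry.segment_alveoli(pair.reflectance, seg_params)
    records = morphometry.measure_walls(labels_img, records, seg_params)
    kept = morphometry.filter_alveoli(records, seg_params)
    patches = dataset.split_into_patches(pair, kept, per_patch=per_patch, min_last=min_last)
    rows: list[pd.Series] = []
    for patch_pair, patch_records in patches:
        summary = morphometry.summarize_morphometry(patch_records)
        comp = colorfeat.color_percentages(patch_pair.birefringence, bands)
        row = dataset.build_feature_vector(
            summary,
            comp,
            meta={"image_id": pair.image_id, "patch_id": patch_pair.image_id, "label": pair.label},
        )
        if row is not None:
            rows.append(row)
    qc = {
        "alveoli_found": len(records),
        "alveoli_kept": len(kept),
        "patches": len(patches),
        "lumen_labels": labels_img,
    }
    return rows, qc


def features_to_dataset(features: pd.DataFrame) -> dataset.LabeledDataset:
    """Build a LabeledDataset from a feature table with a ``label`` column."""
    if "label" not in features.columns:
        raise ValueError("feature table has no 'label' column")
    return dataset.LabeledDataset(
        features=features.reset_index(drop=True), labels=features["label"].to_numpy()
    )


def _load_manifest_images(manifest_path: str) -> list[OctImagePair]:
    rows = pd.read_csv(manifest_path)
    required = {"path_reflectance", "path_birefringence", "label"}
    if not required <= set(rows.columns):
        raise ValueError(f"manifest {manifest_path} must have columns {sorted(required)}")
    pairs = []
    for i, row in rows.iterrows():
        try:
            refl = np.asarray(Image.open(row["path_reflectance"]).convert("L"))
            biref = np.asarray(Image.open(row["path_birefringence"]).convert("RGB"))
        except Exception as exc:
            raise RuntimeError(
                f"manifest row {i}: cannot read image "
                f"({row['path_reflectance']} / {row['path_birefringence']}): {exc}"
            ) from exc
        pairs.append(
            OctImagePair(
                reflectance=refl,
                birefringence=biref,
                label=row["label"],
                image_id=str(row.get("image_id", f"img_{i:03d}")),
            )
        )
    return pairs


def _write_qc_overlay(out_path: Path, pair: OctImagePair, lumen_labels: np.ndarray, seg_params) -> None:
    overlay = np.stack([pair.reflectance] * 3, axis=-1)
    edges = morphometry.canny_outlines(lumen_labels, seg_params)
    overlay[edges] = (255, 40, 40)
    Image.fromarray(overlay.astype(np.uint8), mode="RGB").save(out_path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the configured pipeline; returns the artifact directory.

    Artifacts: ``features.csv``, ``report.json`` + ``confusion.csv``,
    ``stats.csv``, per-image QC overlays under ``qc/`` and ``run_manifest.json``
    (config hash, seeds, package versions, stage counts).
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_params = config.seg_params()
    bands = config.bands()

    if config.input_manifest:
        pairs = _load_manifest_images(config.input_manifest)
        logger.info("loaded %d image pairs from %s", len(pairs), config.input_manifest)
    else:
        ph = config.phantom
        presets = phantom.class_presets(
            n_alveoli=ph.get("n_alveoli", 30),
            image_shape=tuple(ph.get("image_shape", (320, 320))),
            speckle_sigma=ph.get("speckle_sigma", 0.2),
        )
        cohort = phantom.generate_cohort(
            presets, n_per_class=ph.get("n_per_class", 20), seed=config.seed
        )
        pairs = [pair for pair, _, _ in cohort]
        logger.info("generated %d phantom pairs", len(pairs))

    qc_dir = out / "qc"
    if config.qc_overlays:
        qc_dir.mkdir(exist_ok=True)
    all_rows: list[pd.Series] = []
    counts = []
    for pair in pairs:
        t_img = time.time()
        rows, qc = extract_features(
            pair,
            seg_params,
            bands,
            per_patch=config.patch.get("per_patch", 10),
            min_last=config.patch.get("min_last", 5),
        )
        all_rows.extend(rows)
        if config.qc_overlays:
            _write_qc_overlay(qc_dir / f"{pair.image_id}_overlay.png", pair, qc["lumen_labels"], seg_params)
        counts.append(
            {
                "image_id": pair.image_id,
                "alveoli_found": qc["alveoli_found"],
                "alveoli_kept": qc["alveoli_kept"],
                "patches": qc["patches"],
            }
        )
        logger.info(
            "%s: %d alveoli (%d kept), %d patches [%.2fs]",
            pair.image_id,
            qc["alveoli_found"],
            qc["alveoli_kept"],
            qc["patches"],
            time.time() - t_img,
        )

    features = pd.DataFrame(all_rows)
    ordered_cols = list(dataset.METADATA_COLUMNS) + list(dataset.FEATURE_COLUMNS)
    features = features[ordered_cols]
    features.to_csv(out / "features.csv", index=False)

    ds = features_to_dataset(features)
    spec = classify.ModelSpec(
        family=config.model.get("family", "gradient_boosting"),
        hyperparameters=config.model.get("hyperparameters", {}),
    )
    report = classify.kfold_train_eval(
        ds,
        spec,
        k=config.cv.get("k", 10),
        seed=config.seed,
        smote_mode=config.smote.get("mode", "inside_folds"),
    )
    present = [c for c in CLASSES if c in set(ds.labels)]
    report_json = {
        "model": dataclasses.asdict(spec),
        "classes": present,
        "confusion": report.confusion.tolist(),
        "accuracy": report.accuracy,
        "correct": report.correct,
        "total": report.total,
        "per_class": report.per_class,
        "importances": report.importances,
        "fold_seed": report.fold_seed,
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=1))
    pd.DataFrame(report.confusion, index=present, columns=present).to_csv(out / "confusion.csv")

    stats_rows = []
    for col in dataset.FEATURE_COLUMNS:
        groups = [features.loc[features["label"] == c, col].to_numpy(float) for c in present]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                gc = stats.mann_whitney_u(groups[i], groups[j])
                stats_rows.append(
                    {"feature": col, "test": gc.test, "group_a": present[i], "group_b": present[j],
                     "statistic": gc.statistic, "p_value": gc.p_value}
                )
        try:
            gc = stats.anova_oneway(groups)
            stats_rows.append(
                {"feature": col, "test": gc.test, "group_a": "all", "group_b": "all",
                 "statistic": gc.statistic, "p_value": gc.p_value}
            )
            for pair_cmp in stats.tukey_hsd(groups, labels=present):
                stats_rows.append(
                    {"feature": col, "test": pair_cmp.test, "group_a": pair_cmp.groups[0],
                     "group_b": pair_cmp.groups[1], "statistic": pair_cmp.statistic,
                     "p_value": pair_cmp.p_value}
                )
        except stats.ZeroVarianceError:
            logger.warning("stats: %s has zero variance; ANOVA/Tukey skipped", col)
    pd.DataFrame(stats_rows).to_csv(out / "stats.csv", index=False)

    import sklearn
    import skimage

    manifest = {
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-image": skimage.__version__,
        },
        "n_images": len(pairs),
        "n_feature_rows": len(features),
        "per_image_counts": counts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, out)
    return out
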