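"""Patch splitting, feature-table assembly and SMOTE class balancing.

Each measurement-site image is split into vertical-strip sub-images of ten
alveoli each (grouped by centroid column) to enlarge the dataset; every patch
contributes one 25-column feature row: ten lumen-area statistics, ten
wall-thickness statistics, the four hue-band pixel percentages and the FiF.
Minority classes are then oversampled with SMOTE — synthetic rows interpolated
between same-class nearest neighbors — until all classes match the majority
count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .colorfeat import ColorComposition
from .morphometry import AlveolusRecord, MorphometrySummary, STAT_KEYS
from .types import BAND_NAMES, OctImagePair

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "METADATA_COLUMNS",
    "LabeledDataset",
    "split_into_patches",
    "build_feature_vector",
    "smote_balance",
]

#: The fixed 25-column feature schema, in order.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    [f"area_{k}" for k in STAT_KEYS]
    + [f"wall_{k}" for k in STAT_KEYS]
    + [f"percent_{b}" for b in BAND_NAMES]
    + ["fif"]
)

METADATA_COLUMNS: tuple[str, ...] = ("image_id", "patch_id", "label")


@dataclass
class LabeledDataset:
    """Feature matrix with per-row labels and provenance.

    ``provenance`` is "original" for measured rows and "synthetic" for rows
    created by :func:`smote_balance`.
    """

    features: pd.DataFrame
    labels: np.ndarray
    provenance: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.provenance is None:
            self.provenance = np.full(len(self.labels), "original", dtype=object)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if not (len(self.features) == len(self.labels) == len(self.provenance)):
            raise ValueError("features, labels and provenance lengths differ")
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ValueError(f"feature matrix missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def X(self) -> np.ndarray:
        return self.features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def split_into_patches(
    pair: OctImagePair,
    records: list[AlveolusRecord],
    per_patch: int = 10,
    min_last: int = 5,
) -> list[tuple[OctImagePair, list[AlveolusRecord]]]:
    """Split one image into vertical strips of ``per_patch`` alveoli each.

    Alveoli are ordered by centroid column; consecutive groups define strips
    whose column bounds are the group's bounding centroid columns (full image
    rows). A trailing group smaller than ``min_last`` is merged into the
    previous patch, so the patch record subsets always partition the input.
    """
    if not records:
        logger.warning("split_into_patches: no alveoli for %s; 0 patches", pair.image_id)
        return []
    order = sorted(records, key=lambda r: r.centroid[1])
    groups = [order[i : i + per_patch] for i in range(0, len(order), per_patch)]
    if len(groups) > 1 and len(groups[-1]) < min_last:
        groups[-2].extend(groups.pop())

    n_cols = pair.shape[1]
    patches = []
    for i, group in enumerate(groups):
        cols = [r.centroid[1] for r in group]
        c_lo = max(0, int(np.floor(min(cols))))
        c_hi = min(n_cols, int(np.ceil(max(cols))) + 1)
        patch_id = f"{pair.image_id}_p{i:02d}"
        patches.append((pair.crop_columns(c_lo, c_hi, patch_id=patch_id), group))
    return patches


def build_feature_vector(
    summary: MorphometrySummary,
    comp: ColorComposition,
    meta: dict | None = None,
) -> pd.Series | None:
    """One 25-column feature row plus metadata; ``None`` for invalid input.

    Column order follows :data:`FEATURE_COLUMNS`. An invalid summary (no
    alveoli, or no wall samples) yields ``None`` with a logged warning so the
    caller can skip the row.
    """
    meta = meta or {}
    if not summary.valid:
        logger.warning("build_feature_vector: invalid summary for %s; row skipped", meta)
        return None
    row: dict[str, float] = {}
    for k in STAT_KEYS:
        row[f"area_{k}"] = summary.area_stats[k]
    for k in STAT_KEYS:
        row[f"wall_{k}"] = summary.wall_stats[k]
    for b in BAND_NAMES:
        row[f"percent_{b}"] = comp.percent.get(b, 0.0)
    row["fif"] = comp.fif
    for key in METADATA_COLUMNS:
        if key in meta:
            row[key] = meta[key]
    vec = pd.Series(row)
    if vec[list(FEATURE_COLUMNS)].isna().any():
        raise ValueError("feature vector contains missing values")
    return vec


def smote_balance(ds: LabeledDataset, k: int = 5, seed: int = 0) -> LabeledDataset:
    """Oversample minority classes to the majority count with SMOTE.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u`` uniform in
    [0, 1], ``x_i`` a random original minority row and ``x_nn`` one of its
    ``k`` nearest same-class neighbors. Neighbors are found on z-scored
    features (the 25 columns have mixed units); because z-scoring is affine,
    interpolation is done directly on the raw scale. Original rows are
    preserved bit-exactly and synthetic rows are flagged in provenance.
    Deterministic for a fixed seed.
    """
    counts = ds.class_counts()
    if any(c < 2 for c in counts.values()):
        bad = [l for l, c in counts.items() if c < 2]
        raise ValueError(f"SMOTE needs >= 2 rows per class; classes {bad} too small")
    majority = max(counts.values())
    if all(c == majority for c in counts.values()):
        return LabeledDataset(
            features=ds.features.copy(),
            labels=ds.labels.copy(),
            provenance=ds.provenance.copy(),
        )

    rng = np.random.default_rng(seed)
    X = ds.X
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    new_rows: list[np.ndarray] = []
    new_labels: list[str] = []
    for label in sorted(counts):
        deficit = majority - counts[label]
        if deficit == 0:
            continue
        idx = np.flatnonzero(ds.labels == label)
        k_eff = min(k, len(idx) - 1)
        if k_eff < k:
            logger.warning(
                "smote_balance: class %s has %d rows; k lowered to %d", label, len(idx), k_eff
            )
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Z[idx])
        # column 0 of the query result is the point itself
        neighbors = nn.kneighbors(Z[idx], return_distance=False)[:, 1:]
        for _ in range(deficit):
            i = rng.integers(len(idx))
            j = neighbors[i][rng.integers(k_eff)]
            u = rng.uniform()
            new_rows.append(X[idx[i]] + u * (X[idx[j]] - X[idx[i]]))
            new_labels.append(label)

    synth = pd.DataFrame(new_rows, columns=list(FEATURE_COLUMNS))
    features = pd.concat([ds.features, synth], ignore_index=True)
    labels = np.concatenate([ds.labels, np.array(new_labels, dtype=object)])
    provenance = np.concatenate(
        [ds.provenance, np.full(len(new_labels), "synthetic", dtype=object)]
    )
    return LabeledDataset(features=features, labels=labels, provenance=provenance)
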