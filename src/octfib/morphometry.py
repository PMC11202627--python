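"""Alveolar lumen segmentation and morphometry on reflectance images.

Alveoli appear as dark lumens bounded by brighter speckled walls. The
segmentation chain works on the inverted reflectance image (alveolar areas
rendered as the bright phase against dark walls/tissue — equivalently, black
lumens against white walls before inversion): a white top-hat isolates the
lumens from the wall background, a Gaussian blur suppresses residual speckle,
Otsu (by default) binarizes, and a binary erosion/dilation pair removes small
boundary perturbations before the outlines are finalized with Canny edge
detection. Wall thickness is measured per alveolus by casting rays
from the lumen centroid at fixed angular increments and recording the radial
distance from the exit of the own lumen to the first entry into a neighboring
lumen; rays that reach no neighbor within ``max_ray_px`` are discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, morphology

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "AlveolusRecord",
    "MorphometrySummary",
    "segment_alveoli",
    "canny_outlines",
    "measure_walls",
    "filter_alveoli",
    "summarize_morphometry",
    "PERCENTILES",
]

#: Percentiles summarized for both area and wall distributions.
PERCENTILES: tuple[int, ...] = (10, 25, 33, 50, 67, 75, 90)

#: Ordered keys of one stats block in a MorphometrySummary.
STAT_KEYS: tuple[str, ...] = ("mean", "p10", "p25", "p33", "p50", "p67", "p75", "p90", "sd", "range")


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation and wall-measurement chain.

    ``speckle_size_px2`` is the nominal speckle grain area; lumens must exceed
    twice this area to be counted. ``n_rays``/``max_ray_px`` control the
    radial wall search.
    """

    tophat_radius_px: int = 12
    gaussian_sigma_px: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    erosion_radius_px: int = 2
    dilation_radius_px: int = 2
    canny_sigma_px: float = 1.0
    speckle_size_px2: float = 25.0
    max_ray_px: float = 100.0
    n_rays: int = 16

    def __post_init__(self) -> None:
        if min(self.tophat_radius_px, self.erosion_radius_px, self.dilation_radius_px) <= 0:
            raise ValueError("structuring-element radii must be > 0")
        if self.gaussian_sigma_px <= 0 or self.canny_sigma_px <= 0:
            raise ValueError("gaussian/canny sigmas must be > 0")
        if self.n_rays < 4:
            raise ValueError("n_rays must be >= 4")
        if self.max_ray_px <= 0:
            raise ValueError("max_ray_px must be > 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")


@dataclass
class AlveolusRecord:
    """One detected alveolus: lumen geometry plus radial wall samples."""

    centroid: tuple[float, float]
    area_px: int
    wall_thicknesses_px: list[float] = field(default_factory=list)
    boundary: np.ndarray | None = None
    label: int = 0

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")


@dataclass
class MorphometrySummary:
    """Pooled per-image area and wall statistics (10 values each).

    Each block holds mean, the 7 named percentiles (linear interpolation),
    population standard deviation and range, keyed by :data:`STAT_KEYS`.
    """

    area_stats: dict[str, float] = field(default_factory=dict)
    wall_stats: dict[str, float] = field(default_factory=dict)
    n_alveoli: int = 0
    n_wall_samples: int = 0
    valid: bool = False


def _stats_block(values: np.ndarray) -> dict[str, float]:
    pct = np.percentile(values, PERCENTILES)  # linear interpolation
    block = {"mean": float(values.mean())}
    block.update({f"p{p}": float(v) for p, v in zip(PERCENTILES, pct)})
    block["sd"] = float(values.std(ddof=0))
    block["range"] = float(values.max() - values.min())
    return block


def segment_alveoli(
    reflectance: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray, list[AlveolusRecord]]:
    """Segment alveolar lumens; returns (labeled lumen image, records).

    Records carry centroid (pixel mean of the component), lumen pixel area and
    an ordered boundary contour; wall thicknesses are filled by
    :func:`measure_walls`. A constant image yields zero records.
    """
    if params is None:
        params = SegmentationParams()
    if reflectance.ndim != 2:
        raise ValueError("reflectance must be a single-channel 2-D image")
    if min(reflectance.shape) < 2 * params.tophat_radius_px:
        raise ValueError(
            f"image {reflectance.shape} smaller than 2x top-hat radius {params.tophat_radius_px}"
        )
    # Lumens are dark; work on the inverted image so they are the features
    # the white top-hat keeps (structures smaller than the disk).
    img = 255.0 - reflectance.astype(float)

    enhanced = morphology.white_tophat(img, morphology.disk(params.tophat_radius_px))
    smoothed = ndimage.gaussian_filter(enhanced, params.gaussian_sigma_px)

    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            return np.zeros(reflectance.shape, dtype=int), []
        thresh = filters.threshold_otsu(smoothed)
    else:
        thresh = float(params.fixed_threshold)
    lumen = smoothed > thresh  # bright phase of the inverted image

    lumen = morphology.erosion(lumen, morphology.disk(params.erosion_radius_px))
    lumen = morphology.dilation(lumen, morphology.disk(params.dilation_radius_px))

    labels = measure.label(lumen, connectivity=2)
    records: list[AlveolusRecord] = []
    for region in measure.regionprops(labels):
        contours = measure.find_contours(labels == region.label, 0.5)
        boundary = max(contours, key=len) if contours else None
        records.append(
            AlveolusRecord(
                centroid=tuple(region.centroid),
                area_px=int(region.area),
                boundary=boundary,
                label=region.label,
            )
        )
    return labels, records


def canny_outlines(lumen_labels: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Finalized alveolar outlines: Canny edge map of the cleaned lumen mask.

    Used for the per-alveolus outline rendering and QC overlays; the ordered
    boundary stored on each record comes from sub-pixel contour tracing of the
    same mask.
    """
    if params is None:
        params = SegmentationParams()
    return feature.canny((lumen_labels > 0).astype(float), sigma=params.canny_sigma_px)


def measure_walls(
    lumen_labels: np.ndarray,
    records: list[AlveolusRecord],
    params: SegmentationParams | None = None,
) -> list[AlveolusRecord]:
    """Fill per-alveolus wall thicknesses by radial ray casting.

    From each centroid, ``n_rays`` rays at uniform angular increments are
    marched in 0.5-px steps. Per ray the thickness is the distance from the
    point where the ray leaves its own lumen to the point where it first
    enters any other lumen. Rays leaving the image or travelling more than
    ``max_ray_px`` through wall without reaching a neighbor are discarded.
    An isolated alveolus therefore yields an empty list.
    """
    if params is None:
        params = SegmentationParams()
    step = 0.5
    n_steps = int(np.ceil((params.max_ray_px + max(lumen_labels.shape)) / step))
    angles = 2 * np.pi * np.arange(params.n_rays) / params.n_rays
    dr, dc = np.sin(angles), np.cos(angles)
    t = step * np.arange(1, n_steps + 1)

    h, w = lumen_labels.shape
    for rec in records:
        r0, c0 = rec.centroid
        # floor(x + 0.5) rounding: np.rint's round-half-to-even would bias
        # rays that sample exactly on half-integer coordinates.
        rows = np.floor(r0 + t[None, :] * dr[:, None] + 0.5).astype(int)
        cols = np.floor(c0 + t[None, :] * dc[:, None] + 0.5).astype(int)
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        lab = np.full(rows.shape, -1, dtype=int)  # -1 marks off-image
        lab[inside] = lumen_labels[rows[inside], cols[inside]]

        thicknesses: list[float] = []
        own = rec.label
        for k in range(params.n_rays):
            ray = lab[k]
            out_own = np.flatnonzero(ray != own)
            if out_own.size == 0:
                continue
            i_exit = out_own[0]
            # Sub-pixel boundary crossings: midpoint between the last sample
            # on one side and the first on the other.
            t_exit = t[i_exit] - step / 2.0
            after = ray[i_exit:]
            hit = np.flatnonzero((after != own) & (after != 0) & (after != -1))
            off = np.flatnonzero(after == -1)
            limit = off[0] if off.size else after.size
            if hit.size == 0 or hit[0] >= limit:
                continue
            t_entry = t[i_exit + hit[0]] - step / 2.0
            thickness = t_entry - t_exit
            if 0 < thickness <= params.max_ray_px:
                thicknesses.append(float(thickness))
        rec.wall_thicknesses_px = thicknesses
    return records


def filter_alveoli(
    records: list[AlveolusRecord], params: SegmentationParams | None = None
) -> list[AlveolusRecord]:
    """Keep credible alveoli: area above twice the speckle size and not an
    areal outlier (inside the Tukey fences Q1 - 1.5 IQR, Q3 + 1.5 IQR of the
    per-image area distribution)."""
    if params is None:
        params = SegmentationParams()
    if not records:
        return []
    areas = np.array([r.area_px for r in records], dtype=float)
    q1, q3 = np.percentile(areas, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    min_area = 2.0 * params.speckle_size_px2
    return [
        r
        for r in records
        if r.area_px > min_area and lo <= r.area_px <= hi
    ]


def summarize_morphometry(records: list[AlveolusRecord]) -> MorphometrySummary:
    """Pooled mean / percentiles / population SD / range of lumen areas and
    wall thicknesses.

    With no records, or no wall samples across all records, the summary is
    flagged invalid so downstream feature rows can be skipped.
    """
    summary = MorphometrySummary()
    if not records:
        logger.warning("summarize_morphometry: no records; summary invalid")
        return summary
    areas = np.array([r.area_px for r in records], dtype=float)
    walls = np.concatenate([np.asarray(r.wall_thicknesses_px, dtype=float) for r in records]) \
        if any(r.wall_thicknesses_px for r in records) else np.array([])
    summary.n_alveoli = len(records)
    summary.n_wall_samples = int(walls.size)
    summary.area_stats = _stats_block(areas)
    if walls.size == 0:
        logger.warning("summarize_morphometry: no wall samples; summary invalid")
        return summary
    summary.wall_stats = _stats_block(walls)
    summary.valid = True
    return summary
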