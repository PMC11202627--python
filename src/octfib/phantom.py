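"""Synthetic reflectance/birefringence phantoms with known ground truth.

The generator emulates the statistical structure of rat-lung PS-OCT image
pairs across the three fibrosis severity classes: dark elliptical alveolar
lumens on a bright speckled tissue background, class-dependent lumen-area and
inter-lumen gap (wall) distributions, and a class-dependent hue composition of
the birefringence rendering, where the red/yellow (high-retardance) pixel
fraction increases with severity.

Class presets are calibrated to reported group means: mean lumen areas of
81.5 / 88.6 / 131.8 px^2 and mean wall gaps of 24.8 / 33.8 / 22.8 px for
advanced / mild / normal, with per-band colored-pixel fractions of
red 4.32/2.69/0.83 %, yellow 6.50/5.86/2.88 %, green 6.67/6.88/6.47 % and
blue 2.66/4.75/3.70 %. Standard deviations are set to 20 % of the mean (only
means are reported).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

from .types import BAND_NAMES, CLASSES, OctImagePair

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomPlacementError",
    "class_presets",
    "generate_phantom",
    "generate_cohort",
    "write_pair",
    "write_cohort",
]

# Default hue intervals on the half-degree [0, 180) scale used when painting
# colored (birefringent) pixels; matches colorfeat's default counting bands.
_BAND_HUES = {"red": (0.0, 20.0), "yellow": (20.0, 40.0), "green": (50.0, 80.0), "blue": (90.0, 120.0)}

_LUMEN_BASE = 20.0   # reflectance base level inside lumens
_WALL_BASE = 170.0   # reflectance base level of walls/tissue
_SPECKLE_CORR_SIGMA = 0.7  # px; correlation length of the speckle field


class PhantomPlacementError(RuntimeError):
    """Raised when the requested number of lumens cannot be placed."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} non-overlapping lumens; "
            "reduce n_alveoli or enlarge image_shape"
        )


@dataclass
class PhantomSpec:
    """Parameters of one synthetic image pair.

    Lumen areas (px^2) and inter-lumen gaps (px) are drawn from truncated
    normal distributions; ``color_fractions`` gives the target fraction of
    total image pixels painted in each hue band of the birefringence image.
    """

    label: str
    n_alveoli: int = 30
    area_mean_px: float = 100.0
    area_sd_px: float = 20.0
    wall_mean_px: float = 25.0
    wall_sd_px: float = 5.0
    color_fractions: dict[str, float] = field(
        default_factory=lambda: {b: 0.0 for b in BAND_NAMES}
    )
    speckle_sigma: float = 0.2
    image_shape: tuple[int, int] = (320, 320)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}")
        if self.n_alveoli < 0:
            raise ValueError("n_alveoli must be >= 0")
        if any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape must be positive")
        fr = [self.color_fractions.get(b, 0.0) for b in BAND_NAMES]
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("color fractions must lie in [0, 1]")
        if sum(fr) > 1.0:
            raise ValueError("color fractions must sum to <= 1")


@dataclass
class PhantomGroundTruth:
    """Exact placed geometry and color content of a phantom.

    ``gaps_px`` records the sampled inter-lumen gap used to place each lumen
    after the first (the generator's wall-thickness draws).
    """

    centroids: list[tuple[float, float]]
    areas_px: list[int]
    lumen_mask: np.ndarray
    band_pixel_counts: dict[str, int]
    gaps_px: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.centroids) != len(self.areas_px):
            raise ValueError("centroids and areas_px lengths differ")


def class_presets(
    n_alveoli: int = 30,
    image_shape: tuple[int, int] = (320, 320),
    speckle_sigma: float = 0.2,
) -> dict[str, PhantomSpec]:
    """Per-class phantom specs calibrated to the reported group means."""
    means = {
        #           area    wall    red     yellow  green   blue
        "advanced": (81.5, 24.8, 0.0432, 0.0650, 0.0667, 0.0266),
        "mild": (88.6, 33.8, 0.0269, 0.0586, 0.0688, 0.0475),
        "normal": (131.8, 22.8, 0.0083, 0.0288, 0.0647, 0.0370),
    }
    presets = {}
    for label, (area, wall, r, y, g, b) in means.items():
        presets[label] = PhantomSpec(
            label=label,
            n_alveoli=n_alveoli,
            area_mean_px=area,
            area_sd_px=0.2 * area,
            wall_mean_px=wall,
            wall_sd_px=0.2 * wall,
            color_fractions={"red": r, "yellow": y, "green": g, "blue": b},
            speckle_sigma=speckle_sigma,
            image_shape=image_shape,
        )
    return presets


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    """One draw from N(mean, sd) truncated to (lower, inf) by rejection."""
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x > lower:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed")


def _ellipse_radius(semi_row: float, semi_col: float, d_row: float, d_col: float) -> float:
    """Boundary distance from center along unit direction (d_row, d_col)."""
    return 1.0 / np.sqrt((d_row / semi_row) ** 2 + (d_col / semi_col) ** 2)


def _rasterize_ellipse(
    center: tuple[float, float],
    semi_row: float,
    semi_col: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Rows/cols of pixels whose centers fall inside the ellipse."""
    cr, cc = center
    r_lo = max(0, int(np.floor(cr - semi_row)))
    r_hi = min(shape[0] - 1, int(np.ceil(cr + semi_row)))
    c_lo = max(0, int(np.floor(cc - semi_col)))
    c_hi = min(shape[1] - 1, int(np.ceil(cc + semi_col)))
    rr, cc_grid = np.mgrid[r_lo : r_hi + 1, c_lo : c_hi + 1]
    inside = ((rr - cr) / semi_row) ** 2 + ((cc_grid - cc) / semi_col) ** 2 <= 1.0
    return rr[inside], cc_grid[inside]


def _speckle_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Multiplicative log-normal speckle with short-range spatial correlation."""
    if sigma <= 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, _SPECKLE_CORR_SIGMA)
    noise /= noise.std() or 1.0
    return np.exp(sigma * noise)


def generate_phantom(
    spec: PhantomSpec, max_attempts_per_lumen: int = 300
) -> tuple[OctImagePair, PhantomGroundTruth]:
    """Generate one reflectance/birefringence pair with exact ground truth.

    Lumens are non-overlapping axis-aligned ellipses (eccentricity drawn
    uniformly in [1, 1.5]) placed so that each new lumen sits at a sampled
    boundary-to-boundary gap from a previously placed one. The reflectance
    channel carries multiplicative log-normal speckle. Colored pixels in the
    birefringence rendering are drawn from wall (non-lumen) pixels, with hue
    uniform inside each band and saturation/value above counting thresholds;
    all remaining pixels are gray (zero saturation) so only deliberately
    painted pixels register in any hue band.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    lumen_mask = np.zeros(shape, dtype=bool)
    # 1-px dilated occupancy keeps placed lumens 8-disconnected.
    blocked = np.zeros(shape, dtype=bool)

    centers: list[tuple[float, float]] = []
    semis: list[tuple[float, float]] = []
    areas: list[int] = []
    gaps: list[float] = []

    def sample_geometry() -> tuple[float, float]:
        area = _trunc_normal(rng, spec.area_mean_px, spec.area_sd_px, 1.0)
        ecc = rng.uniform(1.0, 1.5)
        semi_minor = np.sqrt(area / (np.pi * ecc))
        semi_major = ecc * semi_minor
        if rng.random() < 0.5:
            return semi_minor, semi_major
        return semi_major, semi_minor

    def try_place(center, semi_row, semi_col) -> bool:
        cr, cc = center
        if not (
            semi_row + 2 <= cr <= shape[0] - semi_row - 3
            and semi_col + 2 <= cc <= shape[1] - semi_col - 3
        ):
            return False
        rr, cols = _rasterize_ellipse(center, semi_row, semi_col, shape)
        if rr.size == 0 or blocked[rr, cols].any():
            return False
        lumen_mask[rr, cols] = True
        dil = np.zeros(shape, dtype=bool)
        dil[rr, cols] = True
        blocked[:] |= ndimage.binary_dilation(dil, structure=np.ones((5, 5), bool))
        centers.append((float(cr), float(cc)))
        semis.append((semi_row, semi_col))
        areas.append(int(rr.size))
        return True

    for i in range(spec.n_alveoli):
        placed = False
        for _ in range(max_attempts_per_lumen):
            semi_row, semi_col = sample_geometry()
            if i == 0 or not centers:
                center = (
                    rng.uniform(semi_row + 2, shape[0] - semi_row - 3),
                    rng.uniform(semi_col + 2, shape[1] - semi_col - 3),
                )
                if try_place(center, semi_row, semi_col):
                    placed = True
                    break
            else:
                j = rng.integers(len(centers))
                gap = _trunc_normal(rng, spec.wall_mean_px, spec.wall_sd_px, 2.0)
                theta = rng.uniform(0, 2 * np.pi)
                d = (np.sin(theta), np.cos(theta))  # (d_row, d_col)
                dist = (
                    _ellipse_radius(*semis[j], *d)
                    + gap
                    + _ellipse_radius(semi_row, semi_col, *d)
                )
                center = (centers[j][0] + dist * d[0], centers[j][1] + dist * d[1])
                if try_place(center, semi_row, semi_col):
                    gaps.append(float(gap))
                    placed = True
                    break
        if not placed:
            raise PhantomPlacementError(len(centers), spec.n_alveoli)

    # Reflectance: dark lumens, bright walls, multiplicative speckle.
    base = np.where(lumen_mask, _LUMEN_BASE, _WALL_BASE)
    reflectance = np.clip(base * _speckle_field(rng, shape, spec.speckle_sigma), 0, 255)
    reflectance = reflectance.astype(np.uint8)

    # Birefringence: gray base (saturation 0), colored pixels on wall pixels.
    gray = np.clip(
        np.where(lumen_mask, _LUMEN_BASE, 0.55 * _WALL_BASE)
        * _speckle_field(rng, shape, spec.speckle_sigma * 0.5),
        0,
        255,
    ).astype(np.uint8)
    biref = np.stack([gray] * 3, axis=-1)

    n_total = shape[0] * shape[1]
    band_counts = {b: int(round(spec.color_fractions.get(b, 0.0) * n_total)) for b in BAND_NAMES}
    n_colored = sum(band_counts.values())
    wall_flat = np.flatnonzero(~lumen_mask)
    if n_colored > wall_flat.size:
        raise ValueError("not enough wall pixels to host the requested color fractions")
    chosen = rng.choice(wall_flat, size=n_colored, replace=False)
    offset = 0
    for b in BAND_NAMES:
        n_b = band_counts[b]
        if n_b == 0:
            continue
        idx = chosen[offset : offset + n_b]
        offset += n_b
        lo, hi = _BAND_HUES[b]
        # Stay 1 hue-unit inside the band so 8-bit quantization cannot push
        # a painted pixel across a band edge.
        hsv = np.empty((n_b, 3))
        hsv[:, 0] = rng.uniform(lo + 1.0, hi - 1.0, n_b) / 180.0
        hsv[:, 1] = rng.uniform(0.75, 0.95, n_b)
        hsv[:, 2] = rng.uniform(0.75, 0.95, n_b)
        rgb = np.clip(np.rint(skcolor.hsv2rgb(hsv[None, :, :])[0] * 255), 0, 255).astype(np.uint8)
        rows, cols = np.unravel_index(idx, shape)
        biref[rows, cols] = rgb

    pair = OctImagePair(
        reflectance=reflectance,
        birefringence=biref,
        label=spec.label,
        image_id=f"{spec.label}_{spec.seed}",
    )
    truth = PhantomGroundTruth(
        centroids=centers,
        areas_px=areas,
        lumen_mask=lumen_mask,
        band_pixel_counts=band_counts,
        gaps_px=gaps,
        seed=spec.seed,
    )
    return pair, truth


def generate_cohort(
    class_specs: dict[str, PhantomSpec] | None = None,
    n_per_class: int = 20,
    seed: int = 0,
) -> list[tuple[OctImagePair, PhantomGroundTruth, str]]:
    """Generate ``n_per_class`` phantoms per severity class.

    Per-item seeds are derived deterministically from the cohort seed via
    :class:`numpy.random.SeedSequence`, so the same cohort seed always yields
    the same images regardless of generation order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if class_specs is None:
        class_specs = class_presets()
    children = np.random.SeedSequence(seed).spawn(len(class_specs) * n_per_class)
    out = []
    i = 0
    for label in CLASSES:
        if label not in class_specs:
            continue
        for k in range(n_per_class):
            item_seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            spec = dataclasses.replace(class_specs[label], seed=item_seed)
            pair, truth = generate_phantom(spec)
            pair.image_id = f"{label}_{k:03d}"
            out.append((pair, truth, label))
    return out


def write_pair(
    out_dir: str | Path, stem: str, pair: OctImagePair, truth: PhantomGroundTruth | None = None
) -> dict[str, str]:
    """Write one pair as 8-bit PNGs plus an optional JSON ground-truth sidecar.

    Returns the mapping of artifact kind to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reflectance": str(out_dir / f"{stem}_reflectance.png"),
        "birefringence": str(out_dir / f"{stem}_birefringence.png"),
    }
    Image.fromarray(pair.reflectance, mode="L").save(paths["reflectance"])
    Image.fromarray(pair.birefringence, mode="RGB").save(paths["birefringence"])
    if truth is not None:
        sidecar = {
            "centroids": [list(c) for c in truth.centroids],
            "areas_px": truth.areas_px,
            "band_pixel_counts": truth.band_pixel_counts,
            "gaps_px": truth.gaps_px,
        }
        paths["ground_truth"] = str(out_dir / f"{stem}_truth.json")
        Path(paths["ground_truth"]).write_text(json.dumps(sidecar, indent=1))
    return paths


def write_cohort(
    out_dir: str | Path,
    cohort: list[tuple[OctImagePair, PhantomGroundTruth, str]],
) -> Path:
    """Write a cohort to disk with a manifest CSV; returns the manifest path."""
    import csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path_reflectance", "path_birefringence", "label", "seed", "image_id"])
        for pair, truth, label in cohort:
            paths = write_pair(out_dir, pair.image_id, pair, truth)
            writer.writerow(
                [paths["reflectance"], paths["birefringence"], label, truth.seed, pair.image_id]
            )
    return manifest
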