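"""Birefringence color quantification via fixed HSV hue bands.

Rendered phase-retardance images encode tissue birefringence as hue: red and
yellow mark strongly birefringent (collagen-rich, fibrotic) regions, green and
blue weaker retardance. Composition is measured by counting pixels whose HSV
hue falls inside fixed bands on the half-degree [0, 180) hue scale —
red [0, 20), yellow [20, 40), green [50, 80), blue [90, 120) — with a
saturation/value floor that keeps near-gray and near-black pixels out of every
band. The fibrosis invasion fraction (FiF) is the summed band-pixel fraction
of the image.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

from .types import BAND_NAMES

__all__ = [
    "HueBand",
    "ColorComposition",
    "default_bands",
    "hue_mask",
    "color_percentages",
    "fibrosis_invasion_fraction",
]

#: Default saturation/value floor (of 255) excluding gray/black background.
DEFAULT_SAT_MIN = 50
DEFAULT_VAL_MIN = 50


@dataclass(frozen=True)
class HueBand:
    """One half-open hue interval [hue_lo, hue_hi) on the [0, 180) scale."""

    name: str
    hue_lo: float
    hue_hi: float
    sat_min: float = DEFAULT_SAT_MIN
    val_min: float = DEFAULT_VAL_MIN

    def __post_init__(self) -> None:
        if not 0 <= self.hue_lo < self.hue_hi < 180:
            raise ValueError(f"require 0 <= hue_lo < hue_hi < 180, got [{self.hue_lo}, {self.hue_hi})")


def default_bands(sat_min: float = DEFAULT_SAT_MIN, val_min: float = DEFAULT_VAL_MIN) -> list[HueBand]:
    """The four standard retardance bands: red, yellow, green, blue."""
    edges = {"red": (0, 20), "yellow": (20, 40), "green": (50, 80), "blue": (90, 120)}
    return [HueBand(n, *edges[n], sat_min=sat_min, val_min=val_min) for n in BAND_NAMES]


@dataclass
class ColorComposition:
    """Per-band pixel percentages of an image plus the FiF score."""

    percent: dict[str, float] = field(default_factory=dict)
    fif: float = 0.0


def _as_hsv255(image: np.ndarray) -> np.ndarray:
    """HSV planes scaled to hue [0, 180), saturation/value [0, 255]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    hsv = skcolor.rgb2hsv(image)
    hsv[..., 0] *= 180.0
    hsv[..., 1:] *= 255.0
    return hsv


def hue_mask(image: np.ndarray, band: HueBand) -> np.ndarray:
    """Boolean mask of pixels inside one hue band.

    A pixel is selected iff hue in [hue_lo, hue_hi) AND saturation >= sat_min
    AND value >= val_min.
    """
    hsv = _as_hsv255(image)
    return (
        (hsv[..., 0] >= band.hue_lo)
        & (hsv[..., 0] < band.hue_hi)
        & (hsv[..., 1] >= band.sat_min)
        & (hsv[..., 2] >= band.val_min)
    )


def color_percentages(image: np.ndarray, bands: list[HueBand] | None = None) -> ColorComposition:
    """Percent of total image pixels in each band, plus the FiF.

    Bands must have pairwise-disjoint hue intervals so no pixel is counted
    twice. The denominator is the total pixel count of the image.
    """
    if bands is None:
        bands = default_bands()
    ivs = sorted((b.hue_lo, b.hue_hi) for b in bands)
    for (_, hi), (lo, _) in zip(ivs, ivs[1:]):
        if lo < hi:
            raise ValueError("hue bands must have pairwise-disjoint intervals")
    hsv = _as_hsv255(image)
    n_total = hsv.shape[0] * hsv.shape[1]
    percent = {}
    for band in bands:
        mask = (
            (hsv[..., 0] >= band.hue_lo)
            & (hsv[..., 0] < band.hue_hi)
            & (hsv[..., 1] >= band.sat_min)
            & (hsv[..., 2] >= band.val_min)
        )
        percent[band.name] = 100.0 * int(mask.sum()) / n_total
    comp = ColorComposition(percent=percent)
    comp.fif = fibrosis_invasion_fraction(comp)
    return comp


def fibrosis_invasion_fraction(comp: ColorComposition) -> float:
    """FiF: summed band-pixel fraction of the image, in [0, 1]."""
    if not comp.percent:
        raise ValueError("composition has no band percentages")
    return sum(comp.percent.values()) / 100.0
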