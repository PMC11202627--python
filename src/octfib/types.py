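"""Shared containers for image pairs and class labels."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed class order used everywhere (confusion-matrix rows, presets, reports).
CLASSES: tuple[str, ...] = ("advanced", "mild", "normal")

#: Hue-band names in canonical report order.
BAND_NAMES: tuple[str, ...] = ("red", "yellow", "green", "blue")


@dataclass
class OctImagePair:
    """Co-registered reflectance / birefringence images for one site.

    Attributes
    ----------
    reflectance : np.ndarray
        2-D uint8 grayscale structural image. Alveolar lumens appear dark,
        walls and tissue bright.
    birefringence : np.ndarray
        3-D uint8 RGB rendering of phase retardance; hue encodes the amount
        of birefringence (collagen content).
    label : str or None
        Optional severity class, one of :data:`CLASSES`.
    image_id : str
        Identifier used in feature tables and artifact filenames.
    """

    reflectance: np.ndarray
    birefringence: np.ndarray
    label: str | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be a 2-D grayscale image")
        if self.birefringence.ndim != 3 or self.birefringence.shape[2] != 3:
            raise ValueError("birefringence must be an RGB image (H, W, 3)")
        if self.reflectance.shape != self.birefringence.shape[:2]:
            raise ValueError("reflectance and birefringence shapes differ")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.reflectance.shape

    def crop_columns(self, col_lo: int, col_hi: int, patch_id: str = "") -> "OctImagePair":
        """Return a vertical-strip crop (full rows, columns [col_lo, col_hi))."""
        if not 0 <= col_lo < col_hi <= self.shape[1]:
            raise ValueError(f"invalid column bounds [{col_lo}, {col_hi})")
        return OctImagePair(
            reflectance=self.reflectance[:, col_lo:col_hi].copy(),
            birefringence=self.birefringence[:, col_lo:col_hi].copy(),
            label=self.label,
            image_id=patch_id or self.image_id,
        )
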