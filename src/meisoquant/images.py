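"""In-memory containers for calibrated 2D fluorescence images and ROI masks.

All physical quantities are in micrometres. Pixel index convention is 0-based
``(row, col)``; a pixel's *centre* sits at ``(index + 0.5) * pixel_size_um``
and its *corners* at ``index * pixel_size_um`` (used for Feret diameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class IntensityImage:
    """A single-channel 2D intensity grid with a physical pixel size.

    Parameters
    ----------
    values
        2D array of finite, non-negative intensities (any numeric dtype;
        stored as float64).
    pixel_size_um
        Physical edge length of a pixel in micrometres; must be > 0.
    bit_depth
        Optional acquisition bit depth (8 or 16), metadata only.
    """

    values: np.ndarray
    pixel_size_um: float
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"image must be 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("image contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2

    def with_values(self, values: np.ndarray) -> "IntensityImage":
        """Same calibration, new pixel data."""
        return IntensityImage(values, self.pixel_size_um, self.bit_depth)


@dataclass
class RoiMask:
    """Boolean region-of-interest mask congruent with an image grid."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError("ROI mask has no true pixel")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    @classmethod
    def full(cls, shape: tuple[int, int], pixel_size_um: float) -> "RoiMask":
        return cls(np.ones(shape, dtype=bool), pixel_size_um)
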