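"""Minimal 3-D image container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """A 3-D grid of scalar intensities with isotropic-or-not voxel spacing.

    Carrier type for PD-like / CET1-like volumes, binary ROI masks and
    pharmacokinetic parameter maps.  ``data`` is always 3-D; single-slice
    images use a trailing singleton axis.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def as_array(volume) -> np.ndarray:
    """Accept an ImageVolume or a bare array and return the 3-D ndarray."""
    if isinstance(volume, ImageVolume):
        return volume.data
    arr = np.asarray(volume)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D array, got ndim={arr.ndim}")
    return arr
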