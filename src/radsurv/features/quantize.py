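"""Fixed-bin-width gray-value discretization.

Intensities inside the ROI are binned with a fixed bin width (default 5
intensity units) anchored at the minimum in-ROI intensity, so the level
assignment is invariant to a global intensity shift:

    level(x) = floor((x - origin) / bin_width) + 1
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radsurv.image import as_array


@dataclass(frozen=True)
class QuantizationConfig:
    """Gray-level discretization settings.

    bin_width
        Width of each intensity bin, in image intensity units.
    origin
        Left edge of the first bin.  ``None`` (default) uses the minimum
        in-ROI intensity, which makes levels shift-invariant.
    """

    bin_width: float = 5.0
    origin: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")


@dataclass
class QuantizedROI:
    """Integer gray levels 1..ng on the ROI grid; 0 marks out-of-ROI voxels."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int

    @property
    def roi_levels(self) -> np.ndarray:
        """In-ROI levels as a flat integer array."""
        return self.levels[self.mask]


def discretize(volume, mask, cfg: QuantizationConfig = QuantizationConfig()) -> QuantizedROI:
    """Discretize in-ROI intensities to integer gray levels.

    A constant ROI yields the single level 1 (ng = 1), a valid degenerate
    case for all downstream texture matrices.
    """
    data = as_array(volume).astype(float)
    mask = as_array(mask).astype(bool)
    if mask.shape != data.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {data.shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = data[mask]
    origin = float(np.min(vals)) if cfg.origin is None else float(cfg.origin)
    levels = np.zeros(data.shape, dtype=np.int64)
    levels[mask] = np.floor((vals - origin) / cfg.bin_width).astype(np.int64) + 1
    if (levels[mask] < 1).any():
        raise ValueError("intensities below the discretization origin")
    return QuantizedROI(levels=levels, mask=mask, ng=int(levels.max()))
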