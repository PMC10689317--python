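"""Image filters producing derived images for feature extraction.

Three filter classes are supported, mirroring the usual radiomics
derived-image set:

* ``wavelet-XYZ`` — one sub-band of a one-level 3-D stationary (undecimated)
  wavelet decomposition with the coiflet-1 kernel, normalized so the bank is
  energy-preserving.  The sub-band name letters map to axes in array order
  (axis 0, axis 1, axis 2); ``L`` = low-pass (approximation), ``H`` =
  high-pass (detail).
* ``lbp`` — slice-wise 2-D local binary pattern codes (radius 1, 8 samples,
  uniform patterns).
* ``squareroot`` — elementwise sqrt(|x|).
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from skimage.feature import local_binary_pattern

from radsurv.image import as_array

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

DEFAULT_FILTERS = ("original", "squareroot", "lbp") + tuple(
    f"wavelet-{b}" for b in WAVELET_SUBBANDS
)

_WAVELET = "coif1"


def _swt_subbands(data: np.ndarray) -> dict[str, np.ndarray]:
    """All 8 sub-bands of a one-level stationary 3-D wavelet decomposition."""
    # swt requires even extents: edge-pad, transform, crop back
    pads = [(0, s % 2 if s > 1 else 2 - s) for s in data.shape]
    padded = np.pad(data, pads, mode="edge")
    coeffs = pywt.swtn(padded, _WAVELET, level=1, norm=True)[0]
    out = {}
    for key, arr in coeffs.items():
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = arr[tuple(slice(0, s) for s in data.shape)]
    return out


def _lbp(data: np.ndarray) -> np.ndarray:
    out = np.empty_like(data, dtype=float)
    with warnings.catch_warnings():
        # float input is intentional; LBP on derived images is standard here
        warnings.simplefilter("ignore", UserWarning)
        for k in range(data.shape[2]):
            # edge-pad so border pixels see in-image neighbor values
            padded = np.pad(data[:, :, k], 1, mode="edge")
            codes = local_binary_pattern(padded, P=8, R=1, method="uniform")
            out[:, :, k] = codes[1:-1, 1:-1]
    return out


def apply_filter(volume, filter_name: str) -> np.ndarray:
    """Apply a named filter to a 3-D volume, returning the derived image."""
    data = as_array(volume).astype(float)
    if filter_name == "original":
        return data.copy()
    if filter_name == "squareroot":
        return np.sqrt(np.abs(data))
    if filter_name == "lbp":
        return _lbp(data)
    if filter_name.startswith("wavelet-"):
        band = filter_name.split("-", 1)[1]
        if band not in WAVELET_SUBBANDS:
            raise ValueError(f"unknown wavelet sub-band {band!r}")
        return _swt_subbands(data)[band]
    raise ValueError(f"unknown filter {filter_name!r}")
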