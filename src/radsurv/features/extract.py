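"""Full feature extraction over an image set: shape from the original mask,
first-order + texture from the original and each configured filtered image.

Feature names follow the ``<filter>_<family>_<feature>`` convention
(e.g. ``wavelet-LHL_glszm_LAHGLE``); when several named images are
extracted together the image name is prepended as ``<image>__...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radsurv.features.filters import DEFAULT_FILTERS, _swt_subbands, apply_filter
from radsurv.features.firstorder import first_order
from radsurv.features.quantize import QuantizationConfig, discretize
from radsurv.features.shape import shape_features
from radsurv.features.texture import (
    glcm_features,
    gldm_features,
    glszm_features,
    ngtdm_features,
)
from radsurv.image import ImageVolume, as_array

_FAMILIES = {
    "glcm": glcm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}


@dataclass(frozen=True)
class FeatureConfig:
    """What to extract: discretization, derived images and feature families.

    The same fixed bin width is applied to original and filtered images
    alike; override ``bin_width`` to change it globally.
    """

    bin_width: float = 5.0
    filters: tuple[str, ...] = DEFAULT_FILTERS
    families: tuple[str, ...] = ("firstorder", "glcm", "glszm", "gldm", "ngtdm")
    include_shape: bool = True


def derived_images(volume, filters) -> dict[str, np.ndarray]:
    """Compute every requested derived image, sharing one wavelet transform."""
    data = as_array(volume).astype(float)
    wavelet_bands = [f for f in filters if f.startswith("wavelet-")]
    out: dict[str, np.ndarray] = {}
    if wavelet_bands:
        bands = _swt_subbands(data)
        for f in wavelet_bands:
            out[f] = bands[f.split("-", 1)[1]]
    for f in filters:
        if not f.startswith("wavelet-"):
            out[f] = apply_filter(data, f)
    return {f: out[f] for f in filters}


def extract_features(volume, mask, config: FeatureConfig = FeatureConfig(),
                     spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """Extract the configured features of one image, without the image prefix."""
    mask = as_array(mask).astype(bool)
    values: dict[str, float] = {}
    if config.include_shape:
        for k, v in shape_features(mask, spacing).items():
            _put(values, f"original_shape_{k}", v)
    qcfg = QuantizationConfig(bin_width=config.bin_width)
    for fname, img in derived_images(volume, config.filters).items():
        roi_vals = img[mask]
        if "firstorder" in config.families:
            for k, v in first_order(roi_vals, bin_width=config.bin_width).items():
                _put(values, f"{fname}_firstorder_{k}", v)
        texture_fams = [f for f in config.families if f in _FAMILIES]
        if texture_fams:
            q = discretize(img, mask, qcfg)
            for fam in texture_fams:
                for k, v in _FAMILIES[fam](q).items():
                    _put(values, f"{fname}_{fam}_{k}", v)
    return values


def _put(d: dict, key: str, value: float) -> None:
    if key in d:
        raise ValueError(f"feature name collision: {key!r}")
    d[key] = float(value)


def extract_all(volumes: dict, mask, config: FeatureConfig = FeatureConfig(),
                spacing=(1.0, 1.0, 1.0)) -> pd.Series:
    """Extract features for a named set of images sharing one ROI mask.

    Shape features are computed once from the mask; intensity features are
    prefixed with the image name as ``<image>__<filter>_<family>_<feature>``.
    """
    mask_arr = as_array(mask).astype(bool)
    out: dict[str, float] = {}
    if config.include_shape:
        for k, v in shape_features(mask_arr, spacing).items():
            _put(out, f"original_shape_{k}", v)
    img_cfg = FeatureConfig(bin_width=config.bin_width, filters=config.filters,
                            families=config.families, include_shape=False)
    for name, vol in volumes.items():
        data = as_array(vol)
        if data.shape != mask_arr.shape:
            raise ValueError(f"volume {name!r} grid {data.shape} != mask grid {mask_arr.shape}")
        sp = vol.spacing if isinstance(vol, ImageVolume) else spacing
        for k, v in extract_features(data, mask_arr, img_cfg, sp).items():
            _put(out, f"{name}__{k}", v)
    return pd.Series(out, dtype=float)
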