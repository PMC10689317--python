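"""High-resolution sliding-window radiomics feature maps.

A window x window patch (default 21, step 1) slides over each slice; at
every visited in-ROI pixel the named feature is computed on the patch
restricted to patch-intersect-ROI voxels (with per-patch discretization),
and the value is assigned to the center pixel.  The resulting per-slice
matrix is overlaid on the source image for visual interpretation of where
a model's features take their extreme values inside the tumor.

Patches are 2-D per slice and clipped at image borders; pixels whose patch
covers too little ROI (``min_roi_fraction``) or restricts to fewer than two
voxels are left out of the defined mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import nibabel as nib
import numpy as np

from radsurv.features.extract import derived_images
from radsurv.features.firstorder import first_order
from radsurv.features.quantize import QuantizationConfig, QuantizedROI, discretize
from radsurv.features.texture import (
    glcm_features,
    gldm_features,
    glszm_features,
    ngtdm_features,
)
from radsurv.image import as_array

logger = logging.getLogger(__name__)

_TEXTURE = {"glcm": glcm_features, "glszm": glszm_features,
            "gldm": gldm_features, "ngtdm": ngtdm_features}


@dataclass(frozen=True)
class FeatureMapConfig:
    """Sliding-window settings.

    window
        Patch edge length in pixels (odd, >= 3).  21 is a good compromise
        between feature-estimate stability and localization for ROIs whose
        shortest in-plane bounding-box edge is around 21 pixels.
    step
        Center-pixel stride; 1 gives a full-resolution map.
    feature
        Name in the ``<filter>_<family>_<feature>`` convention.
    min_roi_fraction
        Minimum fraction of the full window that must lie inside the ROI for
        the center pixel to be evaluated.
    global_origin
        Discretize each patch against the whole-volume in-ROI minimum instead
        of the patch minimum (patch-local origin is the default).
    """

    window: int = 21
    step: int = 1
    feature: str = "original_firstorder_Variance"
    min_roi_fraction: float = 0.25
    bin_width: float = 5.0
    global_origin: bool = False

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class FeatureMap:
    """Per-slice feature values aligned to the source pixel grid."""

    values: np.ndarray          # 2-D, NaN where undefined
    defined: np.ndarray         # 2-D bool, subset of the slice ROI
    slice_index: int
    feature: str
    config: FeatureMapConfig = field(repr=False, default=FeatureMapConfig())


def _parse_feature(name: str):
    parts = name.split("_", 2)
    if len(parts) != 3:
        raise ValueError(f"feature name {name!r} is not <filter>_<family>_<feature>")
    return parts


def _patch_value(values: np.ndarray, qpatch: QuantizedROI | None,
                 family: str, feat: str, bin_width: float = 5.0) -> float:
    if family == "firstorder":
        return first_order(values, bin_width=bin_width)[feat]
    return _TEXTURE[family](qpatch)[feat]


def compute_feature_map(volume, mask, cfg: FeatureMapConfig = FeatureMapConfig()
                        ) -> list[FeatureMap]:
    """Compute the sliding-window map of one named feature, slice by slice.

    Returns one FeatureMap per slice containing ROI pixels.  Visited centers
    lie on the grid ``window//2 + k*step`` so that ``step == window`` tiles
    the slice with non-overlapping patches.
    """
    data = as_array(volume).astype(float)
    m = as_array(mask).astype(bool)
    if m.shape != data.shape:
        raise ValueError("mask grid does not match the volume grid")
    filt, family, feat = _parse_feature(cfg.feature)
    if family != "firstorder" and family not in _TEXTURE:
        raise ValueError(f"unknown feature family {family!r}")
    filtered = derived_images(data, (filt,))[filt]

    # warn when the window exceeds the in-plane ROI bounding box
    idx = np.argwhere(m)
    bb = idx.max(axis=0) - idx.min(axis=0) + 1
    if cfg.window > min(bb[0], bb[1]):
        logger.warning("window %d exceeds the shortest in-plane ROI bounding-box "
                       "edge %d; patches will be ROI-starved", cfg.window, int(min(bb[0], bb[1])))

    half = cfg.window // 2
    area = float(cfg.window * cfg.window)
    origin = float(filtered[m].min())
    qcfg_global = QuantizationConfig(bin_width=cfg.bin_width, origin=origin)
    qcfg_local = QuantizationConfig(bin_width=cfg.bin_width)
    maps = []
    for k in range(data.shape[2]):
        sl_mask = m[:, :, k]
        if not sl_mask.any():
            continue
        sl_img = filtered[:, :, k]
        vals = np.full(sl_mask.shape, np.nan)
        centers_i = np.arange(half, sl_mask.shape[0], cfg.step)
        centers_j = np.arange(half, sl_mask.shape[1], cfg.step)
        for ci in centers_i:
            i0, i1 = max(ci - half, 0), min(ci + half + 1, sl_mask.shape[0])
            for cj in centers_j:
                if not sl_mask[ci, cj]:
                    continue
                j0, j1 = max(cj - half, 0), min(cj + half + 1, sl_mask.shape[1])
                pmask = sl_mask[i0:i1, j0:j1]
                n_in = int(pmask.sum())
                if n_in / area < cfg.min_roi_fraction or n_in < 2:
                    continue
                patch = sl_img[i0:i1, j0:j1]
                qpatch = None
                if family != "firstorder":
                    qcfg = qcfg_global if cfg.global_origin else qcfg_local
                    qpatch = discretize(patch, pmask, qcfg)
                vals[ci, cj] = _patch_value(patch[pmask], qpatch, family, feat,
                                            bin_width=cfg.bin_width)
        defined = np.isfinite(vals)
        maps.append(FeatureMap(values=vals, defined=defined, slice_index=k,
                               feature=cfg.feature, config=cfg))
    return maps


def overlay_map(fmap: FeatureMap, volume, out_png=None, out_nifti=None,
                vmin: float | None = None, vmax: float | None = None,
                cmap: str = "jet", title: str | None = None):
    """Render the map over the grayscale source slice; optionally write a PNG
    and a NIfTI of raw values (NaN outside the defined mask).

    The color scale spans the map's min/max unless a fixed range is given.
    Rendering is deterministic.
    """
    data = as_array(volume).astype(float)
    if data.shape[:2] != fmap.values.shape:
        raise ValueError("map grid does not match the volume grid")
    sl = data[:, :, fmap.slice_index]
    masked = np.ma.masked_invalid(fmap.values)
    if vmin is None:
        vmin = float(masked.min()) if masked.count() else 0.0
    if vmax is None:
        vmax = float(masked.max()) if masked.count() else 1.0

    fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
    ax.imshow(sl.T, cmap="gray", origin="lower")
    im = ax.imshow(masked.T, cmap=cmap, vmin=vmin, vmax=vmax,
                   origin="lower", alpha=0.85)
    fig.colorbar(im, ax=ax, fraction=0.046)
    ax.set_title(title or fmap.feature, fontsize=8)
    ax.axis("off")
    if out_png is not None:
        fig.savefig(out_png, metadata={"Software": None})
    if out_nifti is not None:
        raw = np.where(fmap.defined, fmap.values, np.nan)[:, :, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nib.save(nib.Nifti1Image(raw, np.eye(4)), str(out_nifti))
    return fig
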