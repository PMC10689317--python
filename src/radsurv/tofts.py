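"""Per-voxel extended Tofts pharmacokinetic mapping by the linearized model.

The extended Tofts model

    Ct(t) = v_p Cp(t) + Ktrans * int_0^t Cp(tau) exp(-k_ep (t - tau)) dtau

integrates to the exactly equivalent linear relation

    Ct(t_i) = a * int_0^{t_i} Cp + b * int_0^{t_i} Ct + c * Cp(t_i)

with a = Ktrans + k_ep v_p, b = -k_ep, c = v_p.  Each voxel is solved by
ordinary least squares on (cumulative-trapezoid) integrals, then
k_ep = -b, v_p = c, Ktrans = a - k_ep v_p, v_e = Ktrans / k_ep.

This linearization is deterministic (no starting values) and exact in the
noiseless, densely-sampled limit.  Voxels with k_ep <= 0 or out-of-range
volume fractions are flagged ``fit_ok = False`` rather than silently
clipped; pass ``clip=True`` for the clipped variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from radsurv.image import ImageVolume, as_array

logger = logging.getLogger(__name__)

_VE_KEP_RTOL = 1e-6  # relative tolerance of the v_e = Ktrans / k_ep invariant


@dataclass
class DCESeries:
    """Tissue concentration over time: data (T, nx, ny, nz) in mM, times in
    minutes (strictly increasing from 0), AIF Cp(t) in mM on the same grid."""

    data: np.ndarray
    times: np.ndarray
    aif: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.aif = np.asarray(self.aif, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DCE data must be 4-D (time, x, y, z)")
        if self.times.size != self.data.shape[0] or self.aif.size != self.times.size:
            raise ValueError("times/aif length must match the time dimension")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if not (np.all(np.isfinite(self.data)) and np.all(np.isfinite(self.aif))):
            raise ValueError("DCE series contains non-finite values")


@dataclass
class PKMaps:
    """Per-voxel extended-Tofts estimates with fit diagnostics."""

    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    fit_ok: np.ndarray
    residual: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


def fit_extended_tofts_linear(series: DCESeries, mask, clip: bool = False) -> PKMaps:
    """Estimate Ktrans, k_ep, v_e, v_p per masked voxel by linear least squares.

    Voxels whose concentration curve is identically zero are valid null
    tissue (all parameters 0, ``fit_ok`` True).  A singular design (e.g. an
    all-zero AIF) flags every voxel and logs a warning.
    """
    mask = as_array(mask).astype(bool)
    if mask.shape != series.data.shape[1:]:
        raise ValueError("mask grid does not match the DCE grid")
    t = series.times
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    cp = series.aif
    ct = series.data[:, mask]                       # (T, N)
    n_vox = ct.shape[1]

    u = cumulative_trapezoid(cp, t, initial=0.0)    # int Cp
    w = cumulative_trapezoid(ct, t, axis=0, initial=0.0)  # int Ct per voxel

    # normal equations, assembled vectorized over voxels
    uu, up, pp = u @ u, u @ cp, cp @ cp
    uw = u @ w            # (N,)
    wp = cp @ w
    ww = np.einsum("tn,tn->n", w, w)
    uy = u @ ct
    wy = np.einsum("tn,tn->n", w, ct)
    py = cp @ ct

    G = np.empty((n_vox, 3, 3))
    G[:, 0, 0] = uu; G[:, 0, 1] = uw; G[:, 0, 2] = up
    G[:, 1, 0] = uw; G[:, 1, 1] = ww; G[:, 1, 2] = wp
    G[:, 2, 0] = up; G[:, 2, 1] = wp; G[:, 2, 2] = pp
    rhs = np.stack([uy, wy, py], axis=1)

    null_voxel = np.max(np.abs(ct), axis=0) == 0
    scale = np.maximum(np.abs(G).max(axis=(1, 2)), 1.0)
    singular = np.abs(np.linalg.det(G / scale[:, None, None])) < 1e-12

    coef = np.zeros((n_vox, 3))
    solvable = ~singular
    if solvable.any():
        coef[solvable] = np.linalg.solve(G[solvable], rhs[solvable, :, None])[:, :, 0]
    if singular.any() and not null_voxel[singular].all():
        logger.warning("singular design for %d voxel(s); flagged fit_ok=False",
                       int((singular & ~null_voxel).sum()))

    a, b, c = coef[:, 0], coef[:, 1], coef[:, 2]
    kep = -b
    vp = c
    ktrans = a - kep * vp
    with np.errstate(divide="ignore", invalid="ignore"):
        ve = np.where(kep > 0, ktrans / np.where(kep > 0, kep, 1.0), 0.0)

    pred = u[:, None] * a + w * b + cp[:, None] * c
    residual = np.sqrt(np.mean((ct - pred) ** 2, axis=0))

    ok = (kep > 0) & (ktrans >= 0) & (ve >= 0) & (ve <= 1) & (vp >= 0) & (vp <= 1)
    ok |= null_voxel
    ok &= ~(singular & ~null_voxel)
    for arr in (ktrans, kep, ve, vp):
        arr[null_voxel] = 0.0
    residual[null_voxel] = 0.0

    if clip:
        ktrans = np.clip(ktrans, 0.0, None)
        kep = np.clip(kep, 0.0, None)
        vp = np.clip(vp, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ve = np.clip(np.where(kep > 0, ktrans / np.where(kep > 0, kep, 1.0), 0.0), 0.0, 1.0)

    def _grid(vals, dtype=float):
        g = np.zeros(mask.shape, dtype=dtype)
        g[mask] = vals
        return g

    return PKMaps(
        ktrans=_grid(ktrans), kep=_grid(kep), ve=_grid(ve), vp=_grid(vp),
        fit_ok=_grid(ok, dtype=bool), residual=_grid(residual),
        mask=mask, spacing=series.spacing,
    )


def pk_maps_to_volumes(maps: PKMaps) -> dict[str, ImageVolume]:
    """Export parameter maps as named ImageVolumes on the source grid.

    Non-fitted voxels are exported as 0 and recorded in the ``fit_ok``
    volume.  The v_e grid satisfies v_e = Ktrans / k_ep on fit_ok voxels.
    """
    okm = maps.fit_ok & maps.mask
    if okm.any():
        kt, ke, ve = maps.ktrans[okm], maps.kep[okm], maps.ve[okm]
        pos = ke > 0
        if pos.any():
            rel = np.abs(ve[pos] - kt[pos] / ke[pos]) / np.maximum(np.abs(ve[pos]), 1e-30)
            if np.max(rel) > _VE_KEP_RTOL:
                raise AssertionError("v_e = Ktrans / k_ep invariant violated on fit_ok voxels")
    out = {}
    for name, grid in (("ktrans", maps.ktrans), ("kep", maps.kep),
                       ("ve", maps.ve), ("vp", maps.vp)):
        data = np.where(okm, grid, 0.0)
        out[name] = ImageVolume(data, maps.spacing, name=name)
    out["fit_ok"] = ImageVolume(okm.astype(np.uint8), maps.spacing, name="fit_ok")
    return out
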