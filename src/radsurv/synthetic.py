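"""Synthetic phantom cohorts with known ground truth.

Every downstream stage (pharmacokinetic fitting, feature extraction,
survival modelling, feature maps) is testable without any real data:
the generator emits MR-like volumes whose in-ROI texture is a smoothed
Gaussian random field with subject-specific contrast, DCE concentration
series produced voxel-wise by the extended Tofts forward model under a
shared analytic population AIF, and progression-free-survival times drawn
from an exponential proportional-hazards model whose linear predictor
depends on the true (latent) heterogeneity covariates — not on extracted
features — so feature-to-risk recovery is a genuine end-to-end test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from radsurv.image import ImageVolume
from radsurv.tofts import DCESeries


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort.

    Texture contrast (in-ROI intensity standard deviation) and mean
    pharmacokinetic parameters vary between subjects; the per-subject
    latent draws are the "truth" covariates that drive the hazard.
    """

    n_subjects: int = 60
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    roi_semiaxes: tuple[float, float, float] = (10.0, 8.0, 6.0)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # MR-like texture: Gaussian random field smoothed to a correlation length
    smoothness: float = 1.5                      # Gaussian kernel sigma, voxels
    contrast_range: tuple[float, float] = (5.0, 40.0)   # in-ROI intensity SD
    base_intensity: float = 100.0
    background: float = 20.0
    # PK truth fields
    ktrans_range: tuple[float, float] = (0.05, 0.40)    # min^-1
    ve_range: tuple[float, float] = (0.20, 0.60)
    vp_range: tuple[float, float] = (0.01, 0.08)
    pk_spatial_cv: float = 0.3                   # relative spatial variation
    # DCE acquisition
    n_timepoints: int = 30
    dt_minutes: float = 0.1
    noise_sd: float = 0.02                       # mM, additive Gaussian
    # survival
    hazard_h0: float = 0.02                      # events / month
    beta: dict = field(default_factory=lambda: {
        "contrast_pd": 1.0, "contrast_cet1": 1.0, "ktrans_mean": 1.0,
    })
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.hazard_h0 <= 0:
            raise ValueError("hazard_h0 must be positive")
        lo_ve, hi_ve = self.ve_range
        lo_vp, hi_vp = self.vp_range
        if lo_ve <= 0 or lo_vp <= 0 or hi_ve + hi_vp > 1:
            raise ValueError("require 0 < v_e, v_p and v_e + v_p <= 1")


# Latent covariate channels, in the order they appear in the z matrix.
TRUTH_COVARIATES = ("contrast_pd", "contrast_cet1", "ktrans_mean", "ve_mean", "vp_mean")


@dataclass
class SubjectRecord:
    """One phantom subject: images, ROI, DCE series, latent truth, survival."""

    id: str
    volumes: dict[str, ImageVolume]
    roi: ImageVolume
    dce: DCESeries
    truth: dict
    survival: tuple[float, int] | None = None


# ---------------------------------------------------------------------------
# AIF
# ---------------------------------------------------------------------------

def population_aif(times_minutes) -> np.ndarray:
    """Fixed analytic population AIF: linear bolus ramp, bi-exponential decay.

    Shared by all subjects for reproducibility.  Units: mM, time in minutes.
    """
    t = np.asarray(times_minutes, dtype=float)
    peak, t_rise = 5.0, 0.25
    a1, m1 = 0.6, 3.0     # fast distribution phase, min^-1
    a2, m2 = 0.4, 0.2     # slow elimination phase, min^-1
    rising = t < t_rise
    cp = np.empty_like(t)
    cp[rising] = peak * t[rising] / t_rise
    tail = t[~rising] - t_rise
    cp[~rising] = peak * (a1 * np.exp(-m1 * tail) + a2 * np.exp(-m2 * tail))
    return cp


# ---------------------------------------------------------------------------
# Phantom images
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, semiaxes) -> np.ndarray:
    if any(2 * a + 1 > s for a, s in zip(semiaxes, shape)):
        raise ValueError(f"ROI semi-axes {semiaxes} do not fit inside volume {shape}")
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return r2 <= 1.0


def _grf(shape, smoothness, rng) -> np.ndarray:
    """Smooth Gaussian random field, standardized to zero mean / unit SD."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=smoothness, mode="reflect") if smoothness > 0 else noise
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def _subject_rng(config: CohortConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))


def generate_phantom(config: CohortConfig, subject_index: int) -> SubjectRecord:
    """Generate one phantom subject (without survival outcome).

    The latent draws ``z`` are uniform on [-1, 1] per covariate channel;
    each physical parameter is ``mid + z * halfwidth`` of its config range,
    so z is the exact standardized ground-truth covariate.
    """
    if subject_index >= config.n_subjects:
        raise IndexError(f"subject_index {subject_index} >= n_subjects {config.n_subjects}")
    rng = _subject_rng(config, subject_index)
    shape = tuple(config.volume_shape)
    mask = _ellipsoid_mask(shape, config.roi_semiaxes)

    z = {name: float(rng.uniform(-1.0, 1.0)) for name in TRUTH_COVARIATES}

    def _param(rng_range, zval):
        lo, hi = rng_range
        return 0.5 * (lo + hi) + zval * 0.5 * (hi - lo)

    contrast_pd = _param(config.contrast_range, z["contrast_pd"])
    contrast_cet1 = _param(config.contrast_range, z["contrast_cet1"])
    ktrans_mean = _param(config.ktrans_range, z["ktrans_mean"])
    ve_mean = _param(config.ve_range, z["ve_mean"])
    vp_mean = _param(config.vp_range, z["vp_mean"])

    volumes = {}
    realized = {}
    for name, contrast in (("PD", contrast_pd), ("CET1", contrast_cet1)):
        fld = _grf(shape, config.smoothness, rng)
        inroi = fld[mask]
        sd = inroi.std()
        fld_std = (fld - inroi.mean()) / sd if sd > 0 else np.zeros(shape)
        img = np.full(shape, config.background, dtype=float)
        img[mask] = config.base_intensity + contrast * fld_std[mask]
        volumes[name] = ImageVolume(img, config.spacing, name=name)
        realized[f"{name.lower()}_variance"] = float(np.var(img[mask]))

    # spatially varying PK truth fields (log-normal modulation, mean-preserving)
    sigma_ln = float(np.sqrt(np.log1p(config.pk_spatial_cv**2)))
    def _pk_field(mean):
        g = _grf(shape, config.smoothness, rng)
        return mean * np.exp(sigma_ln * g - 0.5 * sigma_ln**2)

    ktrans = np.where(mask, _pk_field(ktrans_mean), 0.0)
    ve = np.where(mask, np.clip(_pk_field(ve_mean), 0.02, 0.90), 1.0)
    vp = np.where(mask, np.clip(_pk_field(vp_mean), 0.002, 0.20), 0.0)
    scale = np.maximum(ve + vp, 1.0)  # enforce v_e + v_p <= 1
    ve, vp = ve / scale, vp / scale

    times = np.arange(config.n_timepoints) * config.dt_minutes
    aif = population_aif(times)
    conc = simulate_dce(ktrans, ve, vp, aif, times,
                        noise_sd=config.noise_sd, rng=rng)
    conc[:, ~mask] = 0.0

    truth = {
        "z": z,
        "params": {
            "contrast_pd": contrast_pd, "contrast_cet1": contrast_cet1,
            "ktrans_mean": ktrans_mean, "ve_mean": ve_mean, "vp_mean": vp_mean,
        },
        "realized": realized,
        "pk_fields": {"ktrans": ktrans, "ve": ve, "vp": vp},
    }
    dce = DCESeries(data=conc, times=times, aif=aif, spacing=config.spacing)
    return SubjectRecord(
        id=f"subj{subject_index:03d}",
        volumes=volumes,
        roi=ImageVolume(mask.astype(np.uint8), config.spacing, name="ROI"),
        dce=dce,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# DCE forward model
# ---------------------------------------------------------------------------

def simulate_dce(ktrans, ve, vp, aif, times, noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Extended Tofts forward model, exact for a piecewise-linear AIF.

        Ct(t) = v_p Cp(t) + Ktrans * int_0^t Cp(tau) exp(-k_ep (t - tau)) dtau,
        k_ep = Ktrans / v_e.

    Parameters are arrays of a common shape (or scalars); returns an array
    of shape ``(len(times),) + param_shape`` with additive Gaussian noise
    of standard deviation ``noise_sd`` (noiseless when 0).
    """
    times = np.asarray(times, dtype=float)
    aif = np.asarray(aif, dtype=float)
    if times.ndim != 1 or times.size != aif.size:
        raise ValueError("times and aif must be 1-D of equal length")
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")
    if not np.all(np.isfinite(aif)) or np.any(aif < 0):
        raise ValueError("aif must be finite and nonnegative")

    ktrans, ve, vp = np.broadcast_arrays(
        np.asarray(ktrans, float), np.asarray(ve, float), np.asarray(vp, float))
    if np.any((ve == 0) & (ktrans > 0)):
        raise ValueError("v_e = 0 with Ktrans > 0 leaves k_ep undefined")
    kep = np.where(ve > 0, ktrans / np.where(ve > 0, ve, 1.0), 0.0)

    shape = ktrans.shape
    out = np.empty((times.size,) + shape, dtype=float)
    integral = np.zeros(shape)
    out[0] = vp * aif[0]
    for i in range(1, times.size):
        dt = times[i] - times[i - 1]
        p0, p1 = aif[i - 1], aif[i]
        kdt = kep * dt
        expk = np.exp(-kdt)
        small = kdt < 1e-4
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(small, dt * (1 - kdt / 2 + kdt**2 / 6), (1 - expk) / np.where(kep > 0, kep, 1.0))
            b = np.where(small, dt**2 * (0.5 - kdt / 3 + kdt**2 / 8),
                         (1 - (1 + kdt) * expk) / np.where(kep > 0, kep, 1.0) ** 2)
        seg = p1 * a + (p0 - p1) / dt * b
        integral = integral * expk + seg
        out[i] = vp * p1 + ktrans * integral
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# Survival outcomes
# ---------------------------------------------------------------------------

def generate_survival(z, h0: float, beta, censor_rate: float = 0.0,
                      seed: int | np.random.Generator = 0):
    """Exponential proportional-hazards survival with independent censoring.

    Event times are drawn by inverse transform, T = -log(U) / (h0 exp(b'z)).
    The censoring distribution is exponential with its rate calibrated so
    that the expected censored fraction equals ``censor_rate``.

    Returns ``(time, event)`` arrays; time in months, event 1 = progression.
    """
    if h0 <= 0:
        raise ValueError("h0 must be positive")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if z.shape[1] != beta.size:
        raise ValueError(f"z has {z.shape[1]} covariates but beta has {beta.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = h0 * np.exp(z @ beta)
    t_event = rng.exponential(1.0 / rates)
    if censor_rate == 0:
        return t_event, np.ones(len(t_event), dtype=int)
    # P(censored_i) = mu / (mu + lambda_i) for independent exponential censoring
    def expected_censored(log_mu):
        mu = np.exp(log_mu)
        return float(np.mean(mu / (mu + rates))) - censor_rate
    log_mu = brentq(expected_censored, np.log(rates.min()) - 20, np.log(rates.max()) + 20)
    t_censor = rng.exponential(np.exp(-log_mu), size=len(t_event))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return time, event


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Full cohort: phantoms plus survival tied to the latent truth covariates."""
    subjects = [generate_phantom(config, i) for i in range(config.n_subjects)]
    names = list(config.beta.keys())
    z = np.array([[s.truth["z"][k] for k in names] for s in subjects])
    beta = np.array([config.beta[k] for k in names])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10**6]))
    time, event = generate_survival(z, config.hazard_h0, beta,
                                    config.censor_rate, rng)
    for s, t, e in zip(subjects, time, event):
        s.survival = (float(t), int(e))
    return subjects


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _save_nii(path: Path, data: np.ndarray, spacing) -> None:
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def write_cohort(cohort: list[SubjectRecord], out_dir, config: CohortConfig | None = None) -> dict:
    """Write a cohort to disk: NIfTI volumes/masks, 4-D DCE with a times
    sidecar, survival and truth CSVs, config JSON.  Returns the manifest."""
    if not cohort:
        raise ValueError("cohort is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": {}}
    surv_rows, truth_rows = [], []
    for s in cohort:
        sdir = out / s.id
        sdir.mkdir(exist_ok=True)
        files = {}
        for name, vol in s.volumes.items():
            p = sdir / f"{name.lower()}.nii.gz"
            _save_nii(p, vol.data, vol.spacing)
            files[name.lower()] = str(p.relative_to(out))
        p = sdir / "roi.nii.gz"
        _save_nii(p, s.roi.data.astype(np.uint8), s.roi.spacing)
        files["roi"] = str(p.relative_to(out))
        dce_path = sdir / "dce.nii.gz"
        _save_nii(dce_path, np.moveaxis(s.dce.data, 0, -1), s.dce.spacing)
        files["dce"] = str(dce_path.relative_to(out))
        sidecar = sdir / "dce_times.json"
        sidecar.write_text(json.dumps({
            "times_seconds": (s.dce.times * 60.0).tolist(),
            "aif_mM": s.dce.aif.tolist(),
        }, indent=1))
        files["dce_times"] = str(sidecar.relative_to(out))
        manifest["subjects"][s.id] = files
        if s.survival is not None:
            surv_rows.append({"id": s.id, "time_months": s.survival[0], "event": s.survival[1]})
        row = {"id": s.id}
        row.update({f"z_{k}": v for k, v in s.truth["z"].items()})
        row.update({f"param_{k}": v for k, v in s.truth["params"].items()})
        row.update({f"realized_{k}": v for k, v in s.truth["realized"].items()})
        truth_rows.append(row)
    if surv_rows:
        pd.DataFrame(surv_rows).to_csv(out / "survival.csv", index=False)
        manifest["survival"] = "survival.csv"
    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    manifest["truth"] = "truth.csv"
    if config is not None:
        (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=1))
        manifest["config"] = "config.json"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_cohort(out_dir) -> list[SubjectRecord]:
    """Read back a cohort written by :func:`write_cohort` (truth fields are
    restored from CSV scalars only, not the voxelwise PK truth)."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    surv = {}
    if "survival" in manifest:
        df = pd.read_csv(out / manifest["survival"])
        surv = {r["id"]: (float(r["time_months"]), int(r["event"])) for _, r in df.iterrows()}
    truth_df = pd.read_csv(out / manifest["truth"]).set_index("id")
    subjects = []
    for sid in sorted(manifest["subjects"]):
        files = manifest["subjects"][sid]
        def _load(key):
            img = nib.load(str(out / files[key]))
            return np.asarray(img.dataobj), tuple(float(v) for v in img.header.get_zooms()[:3])
        volumes = {}
        for key, name in (("pd", "PD"), ("cet1", "CET1")):
            data, spacing = _load(key)
            volumes[name] = ImageVolume(data, spacing, name=name)
        roi_data, spacing = _load("roi")
        dce_data, _ = _load("dce")
        sidecar = json.loads((out / files["dce_times"]).read_text())
        times = np.asarray(sidecar["times_seconds"]) / 60.0
        aif = np.asarray(sidecar["aif_mM"])
        row = truth_df.loc[sid]
        truth = {
            "z": {k[2:]: float(v) for k, v in row.items() if k.startswith("z_")},
            "params": {k[6:]: float(v) for k, v in row.items() if k.startswith("param_")},
            "realized": {k[9:]: float(v) for k, v in row.items() if k.startswith("realized_")},
        }
        subjects.append(SubjectRecord(
            id=sid,
            volumes=volumes,
            roi=ImageVolume(roi_data.astype(np.uint8), spacing, name="ROI"),
            dce=DCESeries(data=np.moveaxis(dce_data, -1, 0), times=times, aif=aif, spacing=spacing),
            truth=truth,
            survival=surv.get(sid),
        ))
    return subjects
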