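"""Phantom cohort generator: determinism, texture control, DCE forward
model against a quadrature oracle, survival distribution, and round-trip I/O."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from radsurv.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_phantom,
    generate_survival,
    population_aif,
    read_cohort,
    simulate_dce,
    write_cohort,
)


class TestPhantom:
    def test_same_seed_identical_voxels(self):
        cfg = CohortConfig(n_subjects=2, volume_shape=(20, 20, 12),
                           roi_semiaxes=(6, 5, 4), seed=3)
        a = generate_phantom(cfg, 0)
        b = generate_phantom(cfg, 0)
        assert np.array_equal(a.volumes["PD"].data, b.volumes["PD"].data)
        assert np.array_equal(a.dce.data, b.dce.data)
        assert a.truth["z"] == b.truth["z"]

    def test_zero_contrast_constant_roi(self):
        cfg = CohortConfig(n_subjects=2, volume_shape=(20, 20, 12),
                           roi_semiaxes=(6, 5, 4), contrast_range=(0.0, 0.0), seed=3)
        s = generate_phantom(cfg, 0)
        mask = s.roi.data.astype(bool)
        assert np.ptp(s.volumes["PD"].data[mask]) == 0.0
        assert s.truth["realized"]["pd_variance"] == 0.0

    def test_contrast_monotonicity_over_seeds(self):
        lo = CohortConfig(n_subjects=2, volume_shape=(20, 20, 12), roi_semiaxes=(6, 5, 4),
                          contrast_range=(10.0, 10.0))
        hi = dataclasses.replace(lo, contrast_range=(20.0, 20.0))
        vars_lo, vars_hi = [], []
        for seed in range(20):
            s1 = generate_phantom(dataclasses.replace(lo, seed=seed), 0)
            s2 = generate_phantom(dataclasses.replace(hi, seed=seed), 0)
            vars_lo.append(s1.truth["realized"]["pd_variance"])
            vars_hi.append(s2.truth["realized"]["pd_variance"])
        assert np.mean(vars_hi) > np.mean(vars_lo)

    def test_roi_must_fit_volume(self):
        cfg = CohortConfig(n_subjects=2, volume_shape=(10, 10, 10),
                           roi_semiaxes=(8, 8, 8))
        with pytest.raises(ValueError, match="fit"):
            generate_phantom(cfg, 0)

    def test_truth_fractions_valid(self):
        cfg = CohortConfig(n_subjects=3, volume_shape=(20, 20, 12), roi_semiaxes=(6, 5, 4))
        s = generate_phantom(cfg, 1)
        mask = s.roi.data.astype(bool)
        ve = s.truth["pk_fields"]["ve"][mask]
        vp = s.truth["pk_fields"]["vp"][mask]
        assert (ve > 0).all() and (vp > 0).all() and (ve + vp <= 1.0 + 1e-12).all()


class TestSimulateDCE:
    times = np.linspace(0.0, 5.0, 121)

    def test_null_kinetics(self):
        ct = simulate_dce(0.0, 0.4, 0.0, population_aif(self.times), self.times)
        assert np.all(ct == 0)

    def test_plasma_only_limit(self):
        aif = population_aif(self.times)
        ct = simulate_dce(0.0, 0.4, 0.05, aif, self.times)
        assert np.allclose(ct.ravel(), 0.05 * aif)

    def test_matches_quadrature_oracle(self):
        kt, ve, vp = 0.2, 0.4, 0.05
        kep = kt / ve
        aif = population_aif(self.times)
        ct = simulate_dce(kt, ve, vp, aif, self.times).ravel()
        for i in range(10, len(self.times), 25):
            t = self.times[i]
            integ, _ = quad(lambda u: population_aif([u])[0] * np.exp(-kep * (t - u)),
                            0, t, limit=400)
            expected = vp * population_aif([t])[0] + kt * integ
            assert ct[i] == pytest.approx(expected, rel=1e-3)

    def test_ve_zero_with_flux_rejected(self):
        with pytest.raises(ValueError, match="k_ep"):
            simulate_dce(0.2, 0.0, 0.05, population_aif(self.times), self.times)

    def test_noiseless_when_sd_zero(self):
        aif = population_aif(self.times)
        a = simulate_dce(0.1, 0.3, 0.02, aif, self.times, noise_sd=0.0)
        b = simulate_dce(0.1, 0.3, 0.02, aif, self.times, noise_sd=0.0)
        assert np.array_equal(a, b)


class TestSurvival:
    def test_exponential_mean_when_beta_zero(self):
        h0 = 0.05
        t, e = generate_survival(np.zeros((1000, 1)), h0, [0.0], censor_rate=0.0, seed=1)
        assert e.sum() == 1000
        se = (1 / h0) / np.sqrt(1000)
        assert abs(t.mean() - 1 / h0) < 3 * se

    def test_no_censoring_all_events(self):
        _, e = generate_survival(np.zeros((50, 1)), 0.1, [0.0], censor_rate=0.0, seed=2)
        assert (e == 1).all()

    def test_censored_fraction_calibrated(self):
        rng = np.random.default_rng(5)
        z = rng.standard_normal((400, 2))
        _, e = generate_survival(z, 0.02, [1.0, 0.5], censor_rate=0.4, seed=7)
        assert abs((1 - e.mean()) - 0.4) < 0.05

    def test_higher_linear_predictor_shortens_survival(self):
        medians_base, medians_up = [], []
        for seed in range(20):
            z = np.zeros((200, 1))
            t0, _ = generate_survival(z, 0.05, [1.0], seed=seed)
            t1, _ = generate_survival(z + 1.0, 0.05, [1.0], seed=seed)
            medians_base.append(np.median(t0))
            medians_up.append(np.median(t1))
        assert np.mean(medians_up) < np.mean(medians_base)

    def test_invalid_h0(self):
        with pytest.raises(ValueError):
            generate_survival(np.zeros((10, 1)), 0.0, [0.0])


class TestCohortIO:
    def test_write_read_round_trip(self, tmp_path, small_cohort_config):
        cfg = dataclasses.replace(small_cohort_config, n_subjects=3)
        cohort = generate_cohort(cfg)
        manifest = write_cohort(cohort, tmp_path, config=cfg)
        assert len(manifest["subjects"]) == 3
        assert all("roi" in files for files in manifest["subjects"].values())
        back = read_cohort(tmp_path)
        assert len(back) == 3
        for a, b in zip(cohort, back):
            assert np.allclose(a.volumes["PD"].data, b.volumes["PD"].data)
            assert np.allclose(a.dce.data, b.dce.data)
            assert a.survival == pytest.approx(b.survival)

    def test_survival_csv_row_count(self, tmp_path, small_cohort_config):
        import pandas as pd

        cfg = dataclasses.replace(small_cohort_config, n_subjects=4)
        cohort = generate_cohort(cfg)
        write_cohort(cohort, tmp_path, config=cfg)
        df = pd.read_csv(tmp_path / "survival.csv")
        assert len(df) == 4

    def test_empty_cohort_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_cohort([], tmp_path)
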