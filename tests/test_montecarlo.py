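"""Monte Carlo flat-field simulator: determinism, conservation, ablations."""

import numpy as np
import pytest

from pcdnoise.covariance import DetectorGeometry
from pcdnoise.montecarlo import (SimulationConfig, simulate_flat_field,
                                 simulate_sxd_pair, spectral_image)
from pcdnoise.response import EnergyBins


@pytest.fixture(scope="module")
def geom():
    return DetectorGeometry(pitch_um=(100.0, 100.0), thickness_um=732.0)


def _cfg(**kw):
    base = dict(mode="full", grid_shape=(32, 32), photons_per_image=20000,
                n_images=3, energy_kev=63.0, bins=EnergyBins.single(10.0),
                seed=11)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self, cdte, geom, kernel_63_cri):
        a = simulate_flat_field(_cfg(), cdte, geom, kernel_63_cri)
        b = simulate_flat_field(_cfg(), cdte, geom, kernel_63_cri)
        for ia, ib in zip(a, b):
            np.testing.assert_array_equal(ia.counts[0], ib.counts[0])

    def test_different_seed_differs(self, cdte, geom, kernel_63_cri):
        a = simulate_flat_field(_cfg(n_images=1), cdte, geom, kernel_63_cri)
        b = simulate_flat_field(_cfg(n_images=1, seed=12), cdte, geom,
                                kernel_63_cri)
        assert not np.array_equal(a[0].counts[0], b[0].counts[0])


class TestIdealSettings:
    def test_every_photoelectric_event_counts_once(self, cdte, geom):
        """Point deposition below the K edges with alpha = 1: every
        photoelectric photon yields exactly one count (Compton events,
        ~0.5% at 20 keV, deposit nothing when recoil sampling is off)."""
        from pcdnoise.materials import interaction_fractions
        cfg = _cfg(mode="fluorescence_only", energy_kev=20.0, n_images=2)
        imgs = simulate_flat_field(cfg, cdte, geom, kernel=None, alpha=1.0)
        frac = interaction_fractions(cdte, 20.0)
        xi = sum(frac.nu[s] * frac.xi_pe[s] for s in frac.nu)
        n = cfg.photons_per_image
        for im in imgs:
            total = im.counts[0].sum()
            assert total <= n
            assert abs(total - n * xi) < 4 * np.sqrt(n * xi * (1 - xi)) + 1

    def test_fluorescence_bounds_counts_per_photon(self, cdte, geom):
        """Point deposition with fluorescence: at most two counts per
        photon (primary site + reabsorption site)."""
        cfg = _cfg(mode="fluorescence_only", energy_kev=63.0, n_images=1,
                   photons_per_image=50000)
        imgs = simulate_flat_field(cfg, cdte, geom, kernel=None, alpha=1.0)
        total = imgs[0].counts[0].sum()
        assert cfg.photons_per_image * 0.9 <= total <= 2 * cfg.photons_per_image


class TestPoissonStatistics:
    def test_variance_equals_mean(self, cdte, geom, kernel_63_cri):
        """Counts stay Poisson despite charge sharing."""
        cfg = _cfg(n_images=30, photons_per_image=30000, grid_shape=(48, 48))
        imgs = simulate_flat_field(cfg, cdte, geom, kernel_63_cri)
        interior = np.array([im.interior()[0] for im in imgs], dtype=float)
        mu = interior.mean()
        var = interior.var(ddof=1)
        # var/mean ~ 1 with sampling error ~ sqrt(2/N)
        n_eff = interior.size
        assert var / mu == pytest.approx(1.0, abs=5 * np.sqrt(2.0 / n_eff) + 0.01)

    def test_mean_counts_match_analytic_gain(self, cdte, geom, kernel_63_cri):
        """MC mean counts per element agree with the analytic large-area
        gain chain within 3 sigma (Compton excluded on both sides)."""
        from pcdnoise.covariance import SpectrumNPSModel
        from pcdnoise.spectra import monoenergetic
        model = SpectrumNPSModel(cdte, geom, monoenergetic(63.0),
                                 include_compton=False)
        model._kernel_cache[63.0] = kernel_63_cri
        cov = model.covariance(EnergyBins.single(10.0))
        cfg = _cfg(n_images=10, photons_per_image=50000, grid_shape=(48, 48))
        imgs = simulate_flat_field(cfg, cdte, geom, kernel_63_cri)
        q0 = cfg.photons_per_image / (48 * 48 * geom.pitch_area_mm2)
        expected = q0 * cov.cbar[0]
        vals = [im.interior()[0].mean() for im in imgs]
        err = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * err + 0.01 * expected


class TestModeAblation:
    def test_delta_kernel_matches_point_deposition(self, cdte, geom,
                                                   point_kernel):
        """Full mode with a near-delta kernel is distributionally the same
        as the no-cloud mode (chi-squared on count histograms)."""
        from scipy.stats import chi2_contingency
        cfg_a = _cfg(mode="full", energy_kev=63.0, n_images=4,
                     photons_per_image=40000, seed=5)
        cfg_b = _cfg(mode="fluorescence_only", energy_kev=63.0, n_images=4,
                     photons_per_image=40000, seed=6)
        im_a = simulate_flat_field(cfg_a, cdte, geom, point_kernel)
        im_b = simulate_flat_field(cfg_b, cdte, geom, None)
        ca = np.concatenate([im.interior()[0].ravel() for im in im_a])
        cb = np.concatenate([im.interior()[0].ravel() for im in im_b])
        top = int(max(ca.max(), cb.max()))
        ha = np.bincount(ca, minlength=top + 1)
        hb = np.bincount(cb, minlength=top + 1)
        keep = (ha + hb) > 10
        _, p, _, _ = chi2_contingency(np.array([ha[keep], hb[keep]]))
        assert p > 0.01


class TestSpectralImages:
    def test_identical_bins_cancel_at_lambda_minus_one(self):
        rng = np.random.default_rng(0)
        img = rng.poisson(20.0, (16, 16)).astype(float)
        s, nbad = spectral_image(img, img, 20.0, 20.0, -1.0)
        np.testing.assert_allclose(s[~np.isnan(s)], 0.0, atol=1e-12)

    def test_lambda_zero_is_low_bin_log(self):
        rng = np.random.default_rng(1)
        low = rng.poisson(30.0, (16, 16)).astype(float)
        high = rng.poisson(30.0, (16, 16)).astype(float)
        s, _ = spectral_image(low, high, 30.0, 25.0, 0.0)
        np.testing.assert_allclose(s, -np.log(low / 30.0), atol=1e-12)

    def test_sxd_pair_runs_and_reports_qc(self, cdte, geom, kernel_63_cri):
        cfg = _cfg(bins=EnergyBins.two_bin(10.0, 35.0), n_images=3)
        imgs, spectral, qc = simulate_sxd_pair(cfg, cdte, geom, kernel_63_cri,
                                               lam=1.4)
        assert len(spectral) == 3
        assert qc["c_low_ref"] > 0 and qc["c_high_ref"] > 0
        assert qc["zero_count_elements"] >= 0


class TestConfigValidation:
    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            _cfg(mode="nope")

    def test_cloud_mode_requires_kernel(self, cdte, geom):
        with pytest.raises(ValueError):
            simulate_flat_field(_cfg(), cdte, geom, kernel=None)
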