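"""Energy response, deposited-energy statistics, gains, and thresholds."""

import numpy as np
import pytest

from pcdnoise.response import (EnergyBins, deposited_energy_stats,
                               energy_response, equal_count_threshold,
                               klein_nishina_recoil_quadrature,
                               large_area_gain, mean_bin_counts, path_response)

FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestDepositedEnergyStats:
    def test_photopeak_fwhm_with_poisson_gain(self):
        """63-keV photopeak, sigma_e = 2 keV, w = 5 eV: F = 1 gives
        ~4.89 keV FWHM; the physical Fano factor 0.1 gives ~4.73 keV."""
        _, var1 = deposited_energy_stats(63.0, 1.0, 2.0, fano=1.0)
        _, var2 = deposited_energy_stats(63.0, 1.0, 2.0, fano=0.1)
        assert FWHM * np.sqrt(var1) == pytest.approx(4.89, abs=0.005)
        assert FWHM * np.sqrt(var2) == pytest.approx(4.73, abs=0.005)

    def test_no_collection_leaves_noise_only(self):
        mean, var = deposited_energy_stats(63.0, 0.0, 2.0)
        assert mean == 0.0
        assert var == pytest.approx(4.0)

    def test_mean_scales_with_collection_fraction(self):
        for pcs in (0.0, 0.3, 1.0):
            mean, _ = deposited_energy_stats(50.0, pcs, 2.0)
            assert mean == pytest.approx(50.0 * pcs)


class TestPathResponse:
    def test_point_kernel_low_noise_peaks_at_deposit_energy(self, point_kernel):
        grid = np.arange(-2.0, 70.0, 0.1)
        e, d = path_response(63.0, point_kernel, (500.0, 500.0),
                             sigma_e_kev=0.5, energy_grid_kev=grid)
        peak = e[np.argmax(d * (e > 5))]
        assert peak == pytest.approx(63.0, abs=0.2)

    def test_density_normalized(self, kernel_63_cri):
        e, d = path_response(63.0, kernel_63_cri, (100.0, 100.0))
        assert np.trapezoid(d, e) == pytest.approx(1.0, abs=5e-3)
        assert np.all(d >= 0)


@pytest.fixture(scope="module")
def resp_cri(cdte, kernel_63_cri):
    return energy_response(63.0, cdte, kernel_63_cri, 732.0, (100.0, 100.0))


class TestEnergyResponse:

    def test_density_integrates_to_one_per_interaction(self, resp_cri):
        assert np.trapezoid(resp_cri.density, resp_cri.energy_grid_kev) == \
            pytest.approx(1.0, abs=5e-3)

    def test_photopeak_and_escape_structure(self, cdte, kernel_63_cri):
        """With large elements the response shows the photopeak near the
        photon energy and K-escape structure ~E - EK."""
        resp = energy_response(63.0, cdte, kernel_63_cri, 732.0, (500.0, 500.0))
        e, d = resp.energy_grid_kev, resp.density
        win = (e > 55) & (e < 70)
        assert e[win][np.argmax(d[win])] == pytest.approx(63.0, abs=1.0)
        # escape peaks live between E - EK(te) = 35 and E - EK(cd) = 39.4:
        # the escape window must rise above the inter-peak valley
        esc = d[(e > 34) & (e < 41)].max()
        valley = d[(e > 46) & (e < 52)].min()
        assert esc > 2 * valley

    def test_below_edge_energy_is_pure_path_a(self, cdte, point_kernel):
        resp = energy_response(20.0, cdte, point_kernel, 732.0, (250.0, 250.0))
        assert np.allclose(resp.path_b, 0.0)
        assert np.allclose(resp.path_bc, 0.0)


class TestLargeAreaGain:
    def test_ideal_point_detector_gain_is_alpha(self, cdte, point_kernel):
        resp = energy_response(20.0, cdte, point_kernel, 30000.0, (250.0, 250.0))
        g = large_area_gain(resp, EnergyBins.single(10.0), alpha=1.0)
        assert g[0] == pytest.approx(1.0, abs=0.01)

    def test_charge_sharing_raises_multiplicity_above_alpha(self, cdte,
                                                            kernel_63_cri):
        resp = energy_response(63.0, cdte, kernel_63_cri, 732.0, (100.0, 100.0))
        g = large_area_gain(resp, EnergyBins.single(10.0), alpha=0.9)
        assert g[0] > 0.9

    def test_bin_additivity(self, cdte, kernel_63_cri):
        resp = energy_response(63.0, cdte, kernel_63_cri, 732.0, (100.0, 100.0))
        merged = large_area_gain(resp, EnergyBins(((10.0, 80.0),)))
        split = large_area_gain(resp, EnergyBins(((10.0, 35.0), (35.0, 80.0))))
        assert merged[0] == pytest.approx(split.sum(), rel=1e-6)


class TestCounts:
    def test_zero_fluence(self):
        assert mean_bin_counts(0.0, np.array([1.0]), 0.01)[0] == 0.0

    def test_ideal_detector_counts(self):
        assert mean_bin_counts(10000.0, np.array([1.0]), 0.01)[0] == \
            pytest.approx(100.0)

    def test_linearity_in_fluence(self):
        c1 = mean_bin_counts(5000.0, np.array([0.8]), 0.01)
        c2 = mean_bin_counts(10000.0, np.array([0.8]), 0.01)
        assert c2[0] == pytest.approx(2 * c1[0])


class TestEqualCountThreshold:
    def test_symmetric_uniform_response(self):
        """Uniform deposit density on [20, 60] keV splits at 40 keV."""
        def counts(split):
            lo = max(min(split, 60.0), 20.0)
            return lo - 20.0, 60.0 - lo
        assert equal_count_threshold(counts, low_threshold_kev=20.0,
                                     upper_kev=70.0) == pytest.approx(40.0, abs=0.1)

    def test_no_crossing_raises(self):
        with pytest.raises(ValueError):
            equal_count_threshold(lambda s: (1.0, 2.0))

    def test_returned_split_balances_by_construction(self, cdte, kernel_63_cri):
        from pcdnoise.response import energy_response, large_area_gain
        resp = energy_response(63.0, cdte, kernel_63_cri, 732.0, (100.0, 100.0))

        def counts(split):
            g = large_area_gain(resp, EnergyBins.two_bin(10.0, split))
            return g[0], g[1]

        split = equal_count_threshold(counts, upper_kev=70.0)
        c_l, c_h = counts(split)
        assert abs(c_l - c_h) / (c_l + c_h) < 0.005


class TestKleinNishina:
    def test_recoil_bounded_by_compton_edge(self):
        for e0 in (30.0, 63.0, 90.0, 120.0):
            recoil, w = klein_nishina_recoil_quadrature(e0)
            k = 2 * e0 / 510.99895
            edge = e0 * k / (1 + k)
            assert recoil.max() <= edge + 1e-9
            assert w.sum() == pytest.approx(1.0)

    def test_recoils_mostly_below_floor_at_63_kev(self):
        """At 63 keV most Compton recoils fall below a 10-keV threshold."""
        recoil, w = klein_nishina_recoil_quadrature(63.0)
        assert w[recoil < 10.0].sum() > 0.5
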