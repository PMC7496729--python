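"""Pair covariance, overlap interpolation, presampling/digital NPS."""

import numpy as np
import pytest

from pcdnoise.covariance import (alias_summed_nps, joint_energy_pdf,
                                 nps_from_covariance, overlap_interpolation,
                                 path_window_maps)
from pcdnoise.response import EnergyBins


@pytest.fixture(scope="module")
def ideal_cov(ideal_model):
    """Ideal photon counter: point kernel, no fluorescence, alpha ~ 1."""
    bins = EnergyBins.single(10.0)
    return overlap_interpolation(ideal_model.covariance(bins))


@pytest.fixture(scope="module")
def cri_cov(table3_results):
    return table3_results["chest_radiography_1"].cov


class TestIdealDetectorLimit:
    def test_gain_equals_alpha(self, ideal_cov):
        assert ideal_cov.alpha == pytest.approx(1.0, abs=1e-6)
        assert ideal_cov.gbar[0] == pytest.approx(1.0, abs=0.01)

    def test_covariance_is_aperture_triangle(self, ideal_cov):
        """Point deposition: K(tau) along the axis is the rect
        autocorrelation triangle, zero beyond one aperture."""
        g = ideal_cov.grid
        arr = ideal_cov.pair(0, 0)
        c = g.n_half
        prof = arr[c, c:] / arr[c, c]
        lags = np.arange(len(prof)) * g.h_um
        tri = np.clip(1.0 - lags / 100.0, 0.0, 1.0)
        assert np.max(np.abs(prof - tri)) < 0.03

    def test_digital_nps_flat_poisson(self, ideal_cov):
        """Aliased sinc^2 telescopes to a constant: W_dig = c * pitch^2,
        i.e. NNPS_dig * q0 * a = 1/alpha."""
        nps = nps_from_covariance(ideal_cov)
        w = nps.pair_digital(0, 0)
        expected = ideal_cov.cbar[0] * ideal_cov.geometry.pitch_area_mm2
        assert np.max(np.abs(w / expected - 1.0)) < 0.03

    def test_dqe_equals_alpha(self, ideal_cov):
        nps = nps_from_covariance(ideal_cov)
        i0 = len(nps.freq_digital_mm) // 2
        dqe = ideal_cov.cbar[0] ** 2 / nps.pair_digital(0, 0)[i0, i0]
        assert dqe == pytest.approx(1.0, abs=0.03)


class TestPoissonAnchor:
    def test_zero_lag_autocovariance_is_mean_counts(self, cri_cov):
        g = cri_cov.grid
        assert cri_cov.pair(0, 0)[g.n_half, g.n_half] == pytest.approx(
            cri_cov.cbar[0], rel=1e-9)

    def test_zero_lag_cross_covariance_vanishes(self, cri_sxd):
        cov = cri_sxd.cov
        g = cov.grid
        assert cov.pair(0, 1)[g.n_half, g.n_half] == 0.0

    def test_overlap_region_continuous_at_boundary(self, cri_cov):
        g = cri_cov.grid
        arr = cri_cov.pair(0, 0)
        c = g.n_half
        i_edge = c + g.m  # tau_x = aperture (unity fill)
        inner = arr[c, i_edge - 1]
        outer = arr[c, i_edge + 1]
        edge = arr[c, i_edge]
        assert min(inner, outer) - abs(inner - outer) <= edge <= \
            max(inner, outer) + abs(inner - outer)

    def test_symmetry(self, cri_cov):
        arr = cri_cov.pair(0, 0)
        np.testing.assert_allclose(arr, arr[::-1, ::-1], atol=1e-12)
        np.testing.assert_allclose(arr, arr.T, atol=1e-12)


class TestAliasing:
    def test_aliasing_adds_power_at_zero_frequency(self, table3_results):
        for res in table3_results.values():
            fr_p, prof_p = res.nnps_presampling
            fr_d, prof_d = res.nnps_digital
            assert prof_d[0] > prof_p[np.argmin(np.abs(fr_p))] * 1.01

    def test_lattice_dtft_matches_alias_summation(self, cri_cov):
        """Two independent digital-NPS routes: DTFT of the lattice-sampled
        covariance vs explicit alias-sum of the presampling NPS."""
        nps = nps_from_covariance(cri_cov)
        fr, alias = alias_summed_nps(cri_cov, n_freq=5, n_shifts=7)
        i0 = len(nps.freq_digital_mm) // 2
        direct0 = nps.pair_digital(0, 0)[i0, i0]
        alias0 = alias[(0, 0)][2, 2]
        assert alias0 == pytest.approx(direct0, rel=0.02)

    def test_alias_fraction_shrinks_for_small_kernel(self, ideal_model,
                                                     table3_results):
        """When kernel width / pitch -> 0 the alias-added power at zero
        frequency vanishes (ideal detector) but is substantial with
        charge sharing."""
        ideal = overlap_interpolation(ideal_model.covariance(EnergyBins.single(10.0)))
        nps_i = nps_from_covariance(ideal)
        i0 = len(nps_i.freq_digital_mm) // 2
        p0 = nps_i.pair_presampling(0, 0)[
            len(nps_i.freq_presampling_mm) // 2, len(nps_i.freq_presampling_mm) // 2]
        frac_ideal = nps_i.pair_digital(0, 0)[i0, i0] / p0 - 1.0
        res = table3_results["chest_radiography_1"]
        frac_cri = res.nnps_digital[1][0] / res.nnps_presampling[1][
            len(res.nnps_presampling[0]) // 2] - 1.0
        assert frac_ideal < 0.05 < frac_cri


class TestCrossNPS:
    def test_cross_nps_integrates_to_zero(self, cri_sxd):
        """The digital cross NPS of disjoint bins integrates to ~0 over the
        Nyquist region (zero-lag cross covariance vanishes)."""
        nps = cri_sxd.nps
        w = nps.pair_digital(0, 1)
        total = np.sum(w)
        assert abs(total) < 1e-3 * np.sum(np.abs(w))

    def test_cross_nps_negative_near_nyquist(self, cri_sxd):
        fr, p_x = cri_sxd.nnps_cross
        nyq = cri_sxd.cov.geometry.nyquist_mm
        assert np.interp(nyq, fr, p_x) < 0

    def test_cross_symmetric_in_bin_order(self, cri_sxd):
        nps = cri_sxd.nps
        np.testing.assert_allclose(nps.pair_digital(0, 1),
                                   nps.pair_digital(1, 0), atol=1e-15)


class TestWindowMaps:
    def test_limits_and_quadrature_oracle(self):
        bins = EnergyBins.two_bin(10.0, 35.0, top_kev=80.0)
        mean_map = np.array([[0.0, 20.0], [63.0, 40.0]])
        phis = path_window_maps(mean_map, bins, sigma_e_kev=2.0)
        # trapezoid integration of the normal density as the oracle
        for b, (lo, hi) in enumerate(bins.edges):
            e = np.linspace(lo, min(hi, 1e3), 400001)
            for idx in np.ndindex(2, 2):
                mu = mean_map[idx]
                var = 0.005 * mu + 4.0
                pdf = np.exp(-0.5 * (e - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
                ref = np.trapezoid(pdf, e)
                assert phis[b][idx] == pytest.approx(ref, abs=1e-6)

    def test_open_bin_saturates(self):
        bins = EnergyBins.single(10.0)
        phis = path_window_maps(np.array([[63.0]]), bins, 2.0)
        assert phis[0][0, 0] == pytest.approx(1.0, abs=1e-9)
        phis0 = path_window_maps(np.array([[0.0]]), bins, 2.0)
        assert phis0[0][0, 0] < 1e-6


class TestJointPdf:
    def test_zero_lag_concentrates_on_diagonal(self, point_kernel):
        from pcdnoise.covariance import DetectorGeometry
        geom = DetectorGeometry(pitch_um=(100.0, 100.0), thickness_um=732.0)
        e, pdf = joint_energy_pdf(40.0, point_kernel, geom, (0.0, 0.0),
                                  spacing_um=4.0)
        # at tau=0 both elements share the deposit: mass lies near eps=eps'
        on_diag = np.trace(pdf)
        total = pdf.sum()
        ii, jj = np.meshgrid(e, e, indexing="ij")
        off = pdf[np.abs(ii - jj) > 10.0].sum()
        assert off / total < 0.05
        assert on_diag > 0

    def test_bin_integrals_match_covariance_oracle(self, point_kernel):
        """Bin-rectangle integrals of the joint PDF reproduce the path-A
        covariance computed through the window-map route."""
        from pcdnoise.covariance import DetectorGeometry
        geom = DetectorGeometry(pitch_um=(100.0, 100.0), thickness_um=732.0)
        tau = (150.0, 0.0)
        e, pdf = joint_energy_pdf(40.0, point_kernel, geom, tau, spacing_um=4.0)
        de = e[1] - e[0]
        sel = e >= 10.0
        joint_prob = pdf[np.ix_(sel, sel)].sum() * de * de
        # oracle: product of window maps at the same lag, position-averaged
        from pcdnoise.transport import collection_probability_map
        coords, pcs = collection_probability_map(point_kernel, (100.0, 100.0),
                                                 spacing_um=4.0)
        from pcdnoise.covariance import _shift
        shifted = _shift(pcs, int(round(tau[0] / 4.0)), 0)
        bins = EnergyBins.single(10.0)
        phi1 = path_window_maps(40.0 * pcs, bins, 2.0)[0]
        phi2 = path_window_maps(40.0 * shifted, bins, 2.0)[0]
        ref = np.mean(phi1 * phi2)
        assert joint_prob == pytest.approx(ref, rel=0.05, abs=1e-6)
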