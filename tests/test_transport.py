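"""Charge-cloud PDE, kernel projection, calibration, collection map."""

import numpy as np
import pytest
from scipy.special import erf

from pcdnoise.transport import (TransportParams, calibrate_kernel,
                                calibration_sigma_um,
                                collection_probability_map, compute_kernel,
                                drift_time, evolve_cloud, initial_cloud_radius,
                                project_kernel)


@pytest.fixture(scope="module")
def cal_params():
    """Calibration-bench geometry: 2 mm CZT at 900 V."""
    return TransportParams(thickness_um=2000.0, bias_v=900.0)


class TestScalars:
    @pytest.mark.parametrize("energy,expected", [(60.0, 17.0), (480.0, 34.0),
                                                 (7.5, 8.5)])
    def test_initial_radius_cube_root_scaling(self, energy, expected):
        assert initial_cloud_radius(energy) == pytest.approx(expected)

    def test_drift_time_value(self, cal_params):
        # L^2/(mu V) = (0.2 cm)^2 / (1000 cm^2/Vs * 900 V)
        assert drift_time(cal_params) == pytest.approx(4.444e-8, rel=1e-3)

    def test_drift_time_linear_in_thickness_at_fixed_field(self):
        t1 = drift_time(TransportParams(thickness_um=500, field_v_cm=3333))
        t2 = drift_time(TransportParams(thickness_um=1000, field_v_cm=3333))
        assert t2 == pytest.approx(2 * t1)

    def test_bias_and_field_exclusive(self):
        with pytest.raises(ValueError):
            TransportParams(thickness_um=100, bias_v=900, field_v_cm=3333)
        with pytest.raises(ValueError):
            TransportParams(thickness_um=100)


class TestEvolution:
    def test_zero_time_returns_initial_sphere(self, cal_params):
        st = evolve_cloud(60.0, cal_params, 0.0)
        r0 = initial_cloud_radius(60.0)
        expected = np.minimum(1.0, (st.r_grid_um / r0) ** 3)
        np.testing.assert_allclose(st.enclosed_fraction, expected, atol=1e-12)

    def test_charge_conserved_and_monotone(self, cal_params):
        st = evolve_cloud(60.0, cal_params, 2e-8)
        assert st.enclosed_fraction[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(st.enclosed_fraction) >= -1e-12)
        assert st.enclosed_fraction[0] == 0.0

    def test_pure_repulsion_matches_ball_closed_form(self):
        """With diffusion off, a uniform ball stays uniform with
        r(t)^3 = r0^3 + 3 mu Q t/(4 pi eps)."""
        from pcdnoise.transport import _repulsion_coefficient
        p = TransportParams(thickness_um=200, field_v_cm=3333,
                            temperature_k=1e-6)
        st = evolve_cloud(52.0, p, 6e-9)
        r0 = initial_cloud_radius(52.0, p)
        coef = _repulsion_coefficient(52.0, p)
        r_edge = (r0**3 + 6.0 * coef * 6e-9) ** (1 / 3)
        r50 = np.interp(0.5, st.enclosed_fraction, st.r_grid_um)
        assert r50 == pytest.approx(r_edge * 0.5 ** (1 / 3), rel=0.01)

    def test_diffusion_limit_matches_gaussian_green_function(self):
        """Repulsion off, r0 -> 0: enclosed charge follows the 3D Gaussian
        with sigma = sqrt(2 D t)."""
        p = TransportParams(thickness_um=200, field_v_cm=3333)
        t = 6e-9
        st = evolve_cloud(0.05, p, t, repulsion=False)  # r0 = 1.6 um
        sig = np.sqrt(2 * p.diffusion_um2_s * t)
        x = st.r_grid_um / (np.sqrt(2) * sig)
        q_ana = erf(x) - 2 * x * np.exp(-(x**2)) / np.sqrt(np.pi)
        # compare radial densities via the enclosed-charge profiles
        assert np.max(np.abs(st.enclosed_fraction - q_ana)) < 0.01


class TestProjection:
    def test_uniform_ball_projection_hwhm(self, cal_params):
        """Projected uniform ball has HWHM (sqrt(3)/2) r0."""
        st = evolve_cloud(60.0, cal_params, 0.0)
        kern = project_kernel(st)
        assert kern.hwhm_um == pytest.approx(
            np.sqrt(3) / 2 * initial_cloud_radius(60.0), rel=0.02)

    def test_kernel_unit_integral_and_symmetry(self, kernel_63_cri):
        k = kernel_63_cri
        assert k.values.sum() * k.spacing_um**2 == pytest.approx(1.0, abs=1e-4)
        np.testing.assert_allclose(k.values, k.values.T, atol=1e-10)
        np.testing.assert_allclose(k.values, k.values[::-1, ::-1], atol=1e-10)

    def test_radially_nonincreasing(self, kernel_63_cri):
        _, prof = kernel_63_cri.radial_profile()
        assert np.all(np.diff(prof) <= 1e-9)

    @pytest.mark.parametrize("energy,hwhm_ref", [(59.0, 26.0), (136.0, 32.0)])
    def test_calibration_bench_radii(self, cal_params, energy, hwhm_ref):
        """Theoretical kernel radii for the 2-mm, 900-V bench geometry."""
        kern = compute_kernel(energy, cal_params)
        assert kern.hwhm_um == pytest.approx(hwhm_ref, abs=2.0)

    def test_hwhm_grows_with_drift_time(self):
        p = TransportParams(thickness_um=732, field_v_cm=3333)
        hwhms = [project_kernel(evolve_cloud(63.0, p, t)).hwhm_um
                 for t in (0.0, 1e-8, 2.2e-8, 5e-8)]
        assert np.all(np.diff(hwhms) > 0)


class TestCalibration:
    def test_sigma_zero_is_identity(self, kernel_63_cri):
        assert calibrate_kernel(kernel_63_cri, 0.0) is kernel_63_cri

    def test_sigma_from_radii(self):
        # (35 - 26)/sqrt(2 ln 2) ~ 7.64 um (adopted as ~8 um)
        assert calibration_sigma_um(35.0, 26.0) == pytest.approx(7.64, abs=0.01)
        with pytest.raises(ValueError):
            calibration_sigma_um(20.0, 26.0)

    def test_broadening_increases_hwhm(self, kernel_63_cri):
        wider = calibrate_kernel(kernel_63_cri, 8.0)
        assert wider.hwhm_um > kernel_63_cri.hwhm_um
        assert wider.values.sum() * wider.spacing_um**2 == pytest.approx(1.0, abs=1e-4)


class TestCollectionMap:
    def test_point_kernel_gives_aperture_indicator(self, point_kernel):
        coords, pcs = collection_probability_map(point_kernel, (100.0, 100.0),
                                                 spacing_um=2.0)
        c = len(coords) // 2
        assert pcs[c, c] == pytest.approx(1.0, abs=5e-3)
        far = np.argmin(np.abs(coords - 80.0))
        assert pcs[far, c] < 1e-6

    def test_lattice_partition_of_unity(self, kernel_63_cri):
        """Summing P_CS over the element lattice at any offset collects all
        charge (unity fill factor)."""
        pitch = 100.0
        coords, pcs = collection_probability_map(kernel_63_cri, (pitch, pitch),
                                                 spacing_um=pitch / 16,
                                                 extent_um=4 * pitch)
        h = coords[1] - coords[0]
        c = len(coords) // 2
        m = int(round(pitch / h))
        for off in (0, 3, 7):
            total = sum(pcs[c + off + i * m, c + j * m]
                        for i in range(-3, 4) for j in range(-3, 4))
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_center_collection_below_unity_with_sharing(self, kernel_63_cri):
        coords, pcs = collection_probability_map(kernel_63_cri, (100.0, 100.0))
        c = len(coords) // 2
        assert pcs[c, c] < 1.0
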