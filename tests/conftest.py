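"""Shared fixtures: materials, spectra, and the heavy analytic results.

The full-chain analytic results (four application configurations, two
two-bin spectroscopic analyses) are computed once per session and shared
between the unit tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcdnoise.covariance import DetectorGeometry, SpectrumNPSModel
from pcdnoise.materials import load_material
from pcdnoise.pipeline import build_preset, spcd_analysis, sxd_analysis
from pcdnoise.spectra import monoenergetic, rqa_spectrum
from pcdnoise.transport import ChargeSharingKernel, TransportParams, compute_kernel


@pytest.fixture(scope="session")
def cdte():
    return load_material()


@pytest.fixture(scope="session")
def rqa_spectra():
    return {name: rqa_spectrum(name) for name in ("RQA5", "RQA7", "RQA9")}


@pytest.fixture(scope="session")
def kernel_63_cri():
    """Calibrated charge-sharing kernel at 63 keV for the RQA7 L90 converter."""
    params = TransportParams(thickness_um=732.0, field_v_cm=3333.0)
    return compute_kernel(63.0, params, calibration_sigma_um=8.0)


def near_delta_kernel(sigma_um: float = 0.8, spacing_um: float = 0.4) -> ChargeSharingKernel:
    """Synthetic nearly-point kernel (narrow Gaussian) for analytic limits."""
    half = int(np.ceil(12 * sigma_um / spacing_um))
    c = np.arange(-half, half + 1) * spacing_um
    xx, yy = np.meshgrid(c, c, indexing="ij")
    vals = np.exp(-(xx**2 + yy**2) / (2 * sigma_um**2))
    vals /= vals.sum() * spacing_um**2
    return ChargeSharingKernel(spacing_um, vals)


@pytest.fixture(scope="session")
def point_kernel():
    return near_delta_kernel()


@pytest.fixture(scope="session")
def table3_results():
    """SPCD analyses of the four application configurations (QE 0.9)."""
    names = ["angiography", "chest_radiography_1", "chest_radiography_2",
             "computed_tomography"]
    return {name: spcd_analysis(build_preset(name)) for name in names}


@pytest.fixture(scope="session")
def cri_sxd():
    return sxd_analysis(build_preset("chest_radiography_1"))


@pytest.fixture(scope="session")
def ct_sxd():
    return sxd_analysis(build_preset("computed_tomography"))


@pytest.fixture(scope="session")
def ideal_model(cdte, point_kernel):
    """Monoenergetic sub-K-edge model with a point kernel: the ideal
    photon counter limit (no fluorescence, Compton off, alpha ~ 1)."""
    geom = DetectorGeometry(pitch_um=(100.0, 100.0), thickness_um=30000.0)
    model = SpectrumNPSModel(cdte, geom, monoenergetic(20.0),
                             include_compton=False, grid_target_h_um=1.6)
    model._kernel_cache[20.0] = point_kernel
    return model
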