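"""Scalar and spectral image-quality metrics.

All quantities are carried per unit incident fluence (q0 = 1/mm^2): mean
counts per element are c = a G, covariances/NPS are per-unit-q0, and every
metric below (pixel SNR ratio, DQE, multiplicity moments, GDQE) is
invariant to the actual fluence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import CovarianceMap, NPSSet
from .materials import load_attenuation

__all__ = [
    "MultiplicityMoments",
    "SpectralCombination",
    "pixel_snr_ratio",
    "dqe0",
    "dqe0_from_moments",
    "multiplicity_moments",
    "spectral_nps",
    "suppression_lambda",
    "gdqe0",
    "gdqe0_ideal",
]

BONE_DENSITY = 1.92  # g/cm^3 (ICRU-44 cortical bone)


@dataclass(frozen=True)
class MultiplicityMoments:
    """Mean and second moment of counts recorded per interacting photon."""

    m_bar: float
    m2_bar: float

    def __post_init__(self):
        if self.m_bar > 0 and self.m2_bar <= 0:
            raise ValueError("second moment must be positive when mean is")


@dataclass(frozen=True)
class SpectralCombination:
    """Log-subtraction weights for a two-bin spectral image."""

    lambda_suppression: float
    c_low: float
    c_high: float
    mu_low_bone_cm: float = float("nan")
    mu_high_bone_cm: float = float("nan")

    def __post_init__(self):
        if self.lambda_suppression < 0:
            raise ValueError("suppression parameter must be >= 0")


def pixel_snr_ratio(c_bar: float, q0a: float) -> float:
    """Pixel SNR^2 relative to an ideal counter: c / (q0 a) (Poisson counts)."""
    if q0a <= 0:
        raise ValueError("q0 a must be positive")
    return c_bar / q0a


def dqe0(c_bar: float, w_dig_0: float, q0: float = 1.0) -> float:
    """Zero-frequency DQE: c^2 / (q0 Wdig(0)).

    With per-unit-fluence bookkeeping (c in mm^2 = a G, Wdig in mm^2 per
    unit q0), pass q0 = 1; the ratio is dimensionless and fluence-free:
    equivalently DQE(0) = 1 / NNPS_dig(0) for NNPS_dig = q0 Wdig / c^2.
    """
    if w_dig_0 <= 0:
        raise ValueError("Wdig(0) must be positive")
    return c_bar**2 / (q0 * w_dig_0)


def dqe0_from_nps(cov: CovarianceMap, nps: NPSSet, bin_index: int = 0) -> float:
    i0 = len(nps.freq_digital_mm) // 2
    return dqe0(cov.cbar[bin_index], nps.pair_digital(bin_index, bin_index)[i0, i0])


def multiplicity_moments(cov: CovarianceMap, bin_index: int = 0) -> MultiplicityMoments:
    """Multiplicity moments from the lattice-sampled covariance.

    m_bar = G / alpha (counts per interaction); m2_bar is the lattice sum
    of pair covariances divided by (q0 a alpha).
    """
    if not cov.overlap_filled:
        raise ValueError("fill the covariance overlap region first")
    a = cov.geometry.aperture_area_mm2
    m_bar = cov.gbar[bin_index] / cov.alpha
    lattice = cov.lattice_sum(bin_index, bin_index)
    m2_bar = lattice / (a * cov.alpha)
    return MultiplicityMoments(m_bar=float(m_bar), m2_bar=float(m2_bar))


def dqe0_from_moments(moments: MultiplicityMoments, alpha: float) -> float:
    """DQE(0) = alpha m_bar^2 / m2_bar (multiplicity route)."""
    return alpha * moments.m_bar**2 / moments.m2_bar


def spectral_nps(w_low, w_high, w_cross, c_low: float, c_high: float,
                 lam: float):
    """Spectral NPS of the log-subtracted image.

    W_S = W_L/c_L^2 + lambda^2 W_H/c_H^2 + 2 lambda W_LH/(c_L c_H);
    accepts scalars or arrays for the three NPS terms.
    """
    if c_low <= 0 or c_high <= 0:
        raise ValueError("bin counts must be positive")
    return (np.asarray(w_low) / c_low**2
            + lam**2 * np.asarray(w_high) / c_high**2
            + 2.0 * lam * np.asarray(w_cross) / (c_low * c_high))


def suppression_lambda(spectrum, gain_low: np.ndarray, gain_high: np.ndarray,
                       energies_kev: np.ndarray | None = None) -> SpectralCombination:
    """Bone-suppression parameter lambda = mu_LB / mu_HB.

    ``gain_low/high`` are per-energy bin responses on the spectrum grid
    (or on ``energies_kev``); the bone linear attenuation coefficient is
    averaged over the spectrum weighted by fluence x bin response.
    """
    bone = load_attenuation("bone_cortical")
    e = energies_kev if energies_kev is not None else spectrum.energies_kev
    flu = np.interp(e, spectrum.energies_kev, spectrum.fluence)
    mu = bone.mu_total(e) * BONE_DENSITY  # 1/cm
    w_l = flu * np.asarray(gain_low)
    w_h = flu * np.asarray(gain_high)
    mu_l = float(np.sum(w_l * mu) / np.sum(w_l))
    mu_h = float(np.sum(w_h * mu) / np.sum(w_h))
    lam = mu_l / mu_h
    return SpectralCombination(lambda_suppression=lam, c_low=float(np.sum(w_l)),
                               c_high=float(np.sum(w_h)), mu_low_bone_cm=mu_l,
                               mu_high_bone_cm=mu_h)


def gdqe0(ws_dig_0: float, lam: float, q0: float = 1.0) -> float:
    """Zero-frequency generalized DQE: (1 + lambda^2)/(q0 W_S,dig(0))."""
    if ws_dig_0 <= 0:
        raise ValueError("spectral NPS at zero frequency must be positive")
    return (1.0 + lam**2) / (q0 * ws_dig_0)


def gdqe0_ideal() -> float:
    """GDQE(0) of an ideal two-bin detector with equal-count bins.

    Every photon is counted once in the correct bin; the bins are
    independent Poisson images with c = q0 a / 2, so
    W_S,dig(0) = 2 (1 + lambda^2)/q0 and GDQE(0) = 0.5 for any lambda.
    """
    lam = 1.0  # cancels exactly
    q0, a = 1.0, 1.0
    c = q0 * a / 2.0
    w_l = w_h = c * a  # white digital NPS of Poisson counts
    ws0 = float(spectral_nps(w_l, w_h, 0.0, c, c, lam))
    return gdqe0(ws0, lam, q0)
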