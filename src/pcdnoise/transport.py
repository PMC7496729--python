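"""Electron-cloud transport and the lateral charge-sharing kernel.

A photoelectric interaction liberates ``E / w`` electron-hole pairs.  Only
the electron cloud is tracked (electrons drift much farther than holes).
The cloud is spherically symmetric about a centroid drifting at constant
speed; its radial profile evolves under diffusion and Coulomb
self-repulsion.  In terms of the charge ``Q(r, t)`` enclosed within radius
``r`` of the centroid,

    dQ/dt = -(mu_e / (8 pi eps)) (1/r^2) d(Q^2)/dr
            + D [d^2Q/dr^2 - (2/r) dQ/dr],        D = mu_e k T / q,

which follows from the continuity equation, Gauss' law, and the Einstein
relation.  The initial cloud is a uniform sphere of radius
``r0(E) = r0_ref (E/E0)^(1/3)``.  Integrating the final spherical density
along the depth axis yields the 2D charge-sharing kernel whose radius is
quoted as a half width at half maximum (HWHM).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

K_BOLTZMANN = 1.380649e-23   # J/K
Q_ELEMENTARY = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12      # F/m

__all__ = [
    "TransportParams",
    "ChargeCloudState",
    "ChargeSharingKernel",
    "initial_cloud_radius",
    "drift_time",
    "evolve_cloud",
    "project_kernel",
    "compute_kernel",
    "calibrate_kernel",
    "calibration_sigma_um",
    "collection_probability_map",
]


@dataclass(frozen=True)
class TransportParams:
    """Electron transport configuration.

    Exactly one of ``bias_v`` / ``field_v_cm`` must be given; the other is
    derived from the thickness.
    """

    mu_e_cm2_vs: float = 1000.0
    temperature_k: float = 293.0
    rel_permittivity: float = 10.6
    thickness_um: float = 2000.0
    bias_v: float | None = None
    field_v_cm: float | None = None
    w_pair_kev: float = 0.005
    r0_ref_um: float = 17.0
    e0_ref_kev: float = 60.0

    def __post_init__(self):
        if (self.bias_v is None) == (self.field_v_cm is None):
            raise ValueError("give exactly one of bias_v or field_v_cm")
        if self.mu_e_cm2_vs <= 0 or self.thickness_um <= 0:
            raise ValueError("mobility and thickness must be positive")

    @property
    def voltage(self) -> float:
        if self.bias_v is not None:
            return self.bias_v
        return self.field_v_cm * self.thickness_um * 1e-4

    @property
    def diffusion_um2_s(self) -> float:
        """Einstein diffusion coefficient mu_e k T / q in um^2/s."""
        d_cm2 = self.mu_e_cm2_vs * K_BOLTZMANN * self.temperature_k / Q_ELEMENTARY
        return d_cm2 * 1e8


def initial_cloud_radius(energy_kev: float, params: TransportParams | None = None) -> float:
    """Initial uniform-sphere radius r0 (E/E0)^(1/3) [um]."""
    if energy_kev <= 0:
        raise ValueError("energy must be positive")
    p = params or TransportParams(field_v_cm=3333.0)
    return p.r0_ref_um * (energy_kev / p.e0_ref_kev) ** (1.0 / 3.0)


def drift_time(params: TransportParams) -> float:
    """Drift time L^2/(mu_e V) = L/(mu_e F) [s]."""
    length_cm = params.thickness_um * 1e-4
    return length_cm**2 / (params.mu_e_cm2_vs * params.voltage)


@dataclass(frozen=True)
class ChargeCloudState:
    r_grid_um: np.ndarray       # strictly increasing from 0
    enclosed_fraction: np.ndarray  # Q(r)/Q_total
    time_s: float
    energy_kev: float

    def __post_init__(self):
        q = self.enclosed_fraction
        if abs(q[-1] - 1.0) > 1e-6:
            raise ValueError("charge not conserved: Q(r_max) != 1")
        if np.any(np.diff(q) < -1e-9):
            raise ValueError("enclosed charge must be nondecreasing")

    def radial_density(self) -> np.ndarray:
        """rho(r) = dQ/dr / (4 pi r^2), unit total charge [um^-3]."""
        r = self.r_grid_um
        dq = np.gradient(self.enclosed_fraction, r)
        rho = np.zeros_like(r)
        rho[1:] = dq[1:] / (4.0 * np.pi * r[1:] ** 2)
        rho[0] = rho[1]
        return rho


def _repulsion_coefficient(energy_kev: float, params: TransportParams) -> float:
    """mu_e Q_tot / (8 pi eps) in um^3/s (Q_tot = (E/w) q)."""
    n_pairs = energy_kev / params.w_pair_kev
    q_tot = n_pairs * Q_ELEMENTARY
    mu_si = params.mu_e_cm2_vs * 1e-4  # m^2/Vs
    eps = params.rel_permittivity * EPS0
    coef_m3 = mu_si * q_tot / (8.0 * np.pi * eps)
    return coef_m3 * 1e18


def evolve_cloud(energy_kev: float, params: TransportParams, t_end: float,
                 dr_um: float = 0.25, r_max_um: float | None = None,
                 repulsion: bool = True) -> ChargeCloudState:
    """Integrate the enclosed-charge transport equation to ``t_end``.

    Explicit Heun stepping with a diffusion/advection CFL limit; first-order
    upwind differencing of the (outward) repulsion advection and central
    differencing of the diffusion term.  Total charge is conserved by
    construction of the Dirichlet boundaries Q(0)=0, Q(r_max)=1.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    r0 = initial_cloud_radius(energy_kev, params)
    d = params.diffusion_um2_s
    coef = _repulsion_coefficient(energy_kev, params) if repulsion else 0.0

    if r_max_um is None:
        # generous bound: pure-repulsion ball growth + 6 diffusion sigmas
        r_rep = (r0**3 + 6.0 * coef * t_end) ** (1.0 / 3.0)
        r_max_um = 1.5 * r_rep + 6.0 * np.sqrt(max(2.0 * d * t_end, 1e-30)) + 10.0
    n = int(np.ceil(r_max_um / dr_um)) + 1
    r = np.linspace(0.0, (n - 1) * dr_um, n)
    q = np.minimum(1.0, (np.maximum(r, 0.0) / r0) ** 3)

    if t_end == 0.0:
        return ChargeCloudState(r, q, 0.0, energy_kev)

    inner = slice(1, -1)
    ri = r[inner]
    dt_diff = 0.4 * dr_um**2 / d if d > 0 else np.inf
    # advection speed bound: v = coef * 2 Q / r^2 evaluated near the cloud edge
    v_max = 2.0 * coef / max(r0, dr_um) ** 2
    dt_adv = 0.5 * dr_um / v_max if v_max > 0 else np.inf
    dt = min(dt_diff, dt_adv, t_end)
    steps = int(np.ceil(t_end / dt))
    dt = t_end / steps

    def rhs(qv):
        dq_up = np.empty_like(ri)
        dq_up[:] = (qv[inner] - qv[:-2]) / dr_um          # upwind (flow outward)
        d2q = (qv[2:] - 2.0 * qv[inner] + qv[:-2]) / dr_um**2
        dq_c = (qv[2:] - qv[:-2]) / (2.0 * dr_um)
        adv = -(coef / ri**2) * 2.0 * qv[inner] * dq_up
        diff = d * (d2q - 2.0 * dq_c / ri)
        out = np.zeros_like(qv)
        out[inner] = adv + diff
        return out

    for _ in range(steps):
        k1 = rhs(q)
        q_mid = np.clip(q + dt * k1, 0.0, 1.0)
        k2 = rhs(q_mid)
        q = np.clip(q + 0.5 * dt * (k1 + k2), 0.0, 1.0)
        q = np.maximum.accumulate(q)   # enforce monotonicity against roundoff
        q[0], q[-1] = 0.0, 1.0
    if np.any(q < -1e-9):
        raise RuntimeError("solver instability (negative density); reduce dr_um")
    return ChargeCloudState(r, q, t_end, energy_kev)


@dataclass(frozen=True)
class ChargeSharingKernel:
    """Unit-normalized 2D lateral charge density on a square grid [um^-2]."""

    spacing_um: float
    values: np.ndarray  # centered, odd-sized square array

    def __post_init__(self):
        if np.any(self.values < -1e-12):
            raise ValueError("kernel values must be nonnegative")
        integral = self.values.sum() * self.spacing_um**2
        if abs(integral - 1.0) > 1e-4:
            raise ValueError(f"kernel integral {integral} != 1")

    @property
    def hwhm_um(self) -> float:
        """Half width at half maximum of the radial profile."""
        n = self.values.shape[0]
        c = n // 2
        profile = self.values[c, c:]
        half = 0.5 * self.values[c, c]
        idx = np.nonzero(profile < half)[0]
        if len(idx) == 0:
            raise ValueError("grid too small to resolve HWHM")
        i = idx[0]
        # linear interpolation between bracketing samples
        f = (profile[i - 1] - half) / (profile[i - 1] - profile[i])
        return (i - 1 + f) * self.spacing_um

    def radial_profile(self):
        n = self.values.shape[0]
        c = n // 2
        return np.arange(n - c) * self.spacing_um, self.values[c, c:]


def project_kernel(state: ChargeCloudState, spacing_um: float = 0.5,
                   extent_um: float | None = None) -> ChargeSharingKernel:
    """Project the spherical cloud density to the 2D image plane.

    The projection of a spherically symmetric density is the Abel-type
    integral p(s) = 2 ∫_s^∞ rho(r) r / sqrt(r^2 - s^2) dr; it is evaluated
    by direct quadrature on the radial grid and laid out on a centered
    square grid, renormalized to unit integral.
    """
    r = state.r_grid_um
    rho = state.radial_density()
    if extent_um is None:
        # radius enclosing 99.99% of charge, padded
        i = int(np.searchsorted(state.enclosed_fraction, 0.9999))
        extent_um = min(r[min(i, len(r) - 1)] * 1.3 + 2.0, r[-1])
    m = int(np.ceil(extent_um / spacing_um))
    s = np.arange(0, m + 1) * spacing_um

    # quadrature: for each s integrate over r > s with the Abel weight,
    # using the substitution u = sqrt(r^2 - s^2) to remove the singularity
    p = np.zeros_like(s)
    for k, sk in enumerate(s):
        rk = r[r > sk]
        if len(rk) < 2:
            continue
        u = np.concatenate([[0.0], np.sqrt(rk**2 - sk**2)])
        f = np.interp(np.sqrt(u**2 + sk**2), r, rho)
        p[k] = 2.0 * np.trapezoid(f, u)

    nhalf = m
    coords = np.arange(-nhalf, nhalf + 1) * spacing_um
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    rr = np.hypot(xx, yy)
    vals = np.interp(rr, s, p, right=0.0)
    integral = vals.sum() * spacing_um**2
    kern = ChargeSharingKernel(spacing_um, vals / integral)
    # resolution check: at least 8 samples inside the HWHM
    if kern.hwhm_um < 8 * spacing_um:
        raise ValueError("grid too coarse to resolve kernel HWHM; reduce spacing_um")
    return kern


def compute_kernel(energy_kev: float, params: TransportParams,
                   t_end: float | None = None, dr_um: float = 0.25,
                   spacing_um: float = 0.5,
                   calibration_sigma_um: float = 0.0) -> ChargeSharingKernel:
    """Convenience chain: evolve to drift time, project, optionally calibrate."""
    t = drift_time(params) if t_end is None else t_end
    state = evolve_cloud(energy_kev, params, t, dr_um=dr_um)
    kern = project_kernel(state, spacing_um=spacing_um)
    if calibration_sigma_um > 0:
        kern = calibrate_kernel(kern, calibration_sigma_um)
    return kern


def calibration_sigma_um(r_empirical_um: float, r_theory_um: float) -> float:
    """Gaussian sigma = (R_em - R_th)/sqrt(2 ln 2) matching empirical radii."""
    if r_empirical_um < r_theory_um:
        raise ValueError("empirical radius smaller than theoretical radius")
    return (r_empirical_um - r_theory_um) / np.sqrt(2.0 * np.log(2.0))


def calibrate_kernel(kernel: ChargeSharingKernel, broaden_sigma_um: float) -> ChargeSharingKernel:
    """Convolve with an isotropic zero-mean Gaussian of given sigma [um]."""
    if broaden_sigma_um < 0:
        raise ValueError("sigma must be >= 0")
    if broaden_sigma_um == 0:
        return kernel
    # pad so the broadened kernel is not truncated
    pad = int(np.ceil(4.0 * broaden_sigma_um / kernel.spacing_um))
    vals = np.pad(kernel.values, pad)
    vals = gaussian_filter(vals, sigma=broaden_sigma_um / kernel.spacing_um,
                           mode="constant")
    vals = np.maximum(vals, 0.0)
    vals /= vals.sum() * kernel.spacing_um**2
    return ChargeSharingKernel(kernel.spacing_um, vals)


def collection_probability_map(kernel: ChargeSharingKernel,
                               aperture_um: tuple[float, float],
                               spacing_um: float | None = None,
                               extent_um: float | None = None):
    """P_CS(r): rect aperture convolved with the charge-sharing kernel.

    Returns ``(coords_um, values)`` where ``values[i, j]`` is the fraction
    of the cloud charge collected by an aperture centered at
    ``(coords[i], coords[j])`` relative to the interaction point.
    """
    ax, ay = aperture_um
    if ax <= 0 or ay <= 0:
        raise ValueError("aperture must be positive")
    h = spacing_um or kernel.spacing_um
    if extent_um is None:
        kext = kernel.values.shape[0] // 2 * kernel.spacing_um
        extent_um = ax / 2 + kext + h
    n = int(np.ceil(extent_um / h))
    coords = np.arange(-n, n + 1) * h

    kern = _resample_kernel(kernel, h)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    # fractional-coverage rect indicator for accurate small-aperture limits
    cov_x = np.clip((ax / 2 - np.abs(xx)) / h + 0.5, 0.0, 1.0)
    cov_y = np.clip((ay / 2 - np.abs(yy)) / h + 0.5, 0.0, 1.0)
    rect = cov_x * cov_y
    pcs = fftconvolve(rect, kern * h * h, mode="same")
    return coords, np.clip(pcs, 0.0, 1.0)


def _resample_kernel(kernel: ChargeSharingKernel, h_um: float) -> np.ndarray:
    """Bilinear resample of the kernel density onto spacing ``h_um``.

    Conserves the unit integral to better than 1e-4 by renormalizing.
    """
    if abs(h_um - kernel.spacing_um) < 1e-12:
        return kernel.values
    half = kernel.values.shape[0] // 2 * kernel.spacing_um
    m = int(np.floor(half / h_um))
    coords = np.arange(-m, m + 1) * h_um
    src = np.arange(-(kernel.values.shape[0] // 2),
                    kernel.values.shape[0] // 2 + 1) * kernel.spacing_um
    from scipy.interpolate import RegularGridInterpolator
    interp = RegularGridInterpolator((src, src), kernel.values,
                                     bounds_error=False, fill_value=0.0)
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    vals = interp(np.stack([xx.ravel(), yy.ravel()], axis=1)).reshape(xx.shape)
    vals = np.maximum(vals, 0.0)
    total = vals.sum() * h_um**2
    return vals / total
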