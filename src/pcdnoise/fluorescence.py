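"""K-fluorescence reabsorption probability and lateral relocation kernel.

After a K-shell photoelectric interaction, the atom emits (with
probability ``omega_K``) a characteristic K x ray at the element's mean
K-emission energy.  The photon is emitted isotropically from the primary
interaction depth and either escapes the converter slab or is reabsorbed
after an exponential free path; reabsorbed photons are assumed to deposit
all their energy photoelectrically at one point.  This module computes the
reabsorption probability ``f_K`` and the 2D lateral probability density
``p_K(r)`` of the reabsorption site relative to the primary interaction,
by quadrature over primary interaction depth (Beer-Lambert weighted),
emission direction, and free path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import Material

__all__ = ["ReabsorptionKernel", "k_reabsorption", "reabsorption_transfer"]


@dataclass(frozen=True)
class ReabsorptionKernel:
    """Lateral relocation PDF of reabsorbed K photons.

    ``radii_um``/``radial_mass`` give the distribution of lateral
    displacement magnitude: ``radial_mass[i]`` is the probability that the
    displacement falls in the annulus ``[radii_um[i], radii_um[i+1])``,
    conditioned on reabsorption.  ``f_k`` is the reabsorption probability.
    """

    radii_um: np.ndarray
    radial_mass: np.ndarray
    f_k: float
    emission_energy_kev: float
    below_edge: bool = False

    def __post_init__(self):
        if not 0.0 <= self.f_k <= 1.0:
            raise ValueError("f_k must lie in [0, 1]")
        if np.any(self.radial_mass < -1e-12):
            raise ValueError("kernel mass must be nonnegative")
        if self.f_k > 0 and abs(self.radial_mass.sum() - 1.0) > 1e-3:
            raise ValueError("kernel mass must sum to 1")

    def density_2d(self, radii_um: np.ndarray) -> np.ndarray:
        """Isotropic 2D density p_K [um^-2] at given radii (unit integral)."""
        edges = self.radii_um
        centers = 0.5 * (edges[:-1] + edges[1:])
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        dens = self.radial_mass / areas
        return np.interp(radii_um, centers, dens, left=dens[0], right=0.0)

    def cell_masses(self, coords_um: np.ndarray) -> np.ndarray:
        """Distribute the radial mass over a square grid of cell centers.

        Conserves total mass exactly: each annulus' mass is split equally
        among the grid cells whose center radius falls inside it.
        """
        h = coords_um[1] - coords_um[0]
        xx, yy = np.meshgrid(coords_um, coords_um, indexing="ij")
        rr = np.hypot(xx, yy).ravel()
        edges = self.radii_um
        idx = np.clip(np.searchsorted(edges, rr, side="right") - 1, 0, len(edges) - 2)
        inside = rr < edges[-1]
        counts = np.bincount(idx[inside], minlength=len(edges) - 1).astype(float)
        # guard: annuli with no representative cell donate to the next one out
        mass = self.radial_mass.copy()
        for i in range(len(mass) - 1):
            if counts[i] == 0 and mass[i] > 0:
                mass[i + 1] += mass[i]
                mass[i] = 0.0
        out = np.zeros_like(rr)
        ok = inside & (counts[idx] > 0)
        out[ok] = mass[idx[ok]] / counts[idx[ok]]
        out = out.reshape(xx.shape)
        s = out.sum()
        if s > 0:
            out /= s
        return out


def k_reabsorption(material: Material, element: str, thickness_um: float,
                   primary_energy_kev: float, n_depth: int = 64,
                   n_mu: int = 256, n_radii: int = 200) -> ReabsorptionKernel:
    """Reabsorption probability and lateral kernel for one element's K x ray.

    Primary interaction depths are weighted by Beer-Lambert attenuation at
    the primary energy; emission is isotropic; the K photon free path is
    exponential with the material's interacting attenuation coefficient at
    the K-emission energy; paths are truncated at the slab faces.
    """
    el = material.element(element)
    e_k = el.mean_k_xray_kev
    if primary_energy_kev <= el.k_edge_kev:
        return ReabsorptionKernel(np.array([0.0, 1.0]), np.array([1.0]), 0.0,
                                  e_k, below_edge=True)
    if thickness_um <= 0:
        return ReabsorptionKernel(np.array([0.0, 1.0]), np.array([1.0]), 0.0, e_k)

    length_cm = thickness_um * 1e-4
    mu_p = material.mu_interacting(primary_energy_kev)  # 1/cm
    mu_k = material.mu_interacting(e_k)

    # depth quadrature (Gauss-Legendre on [0, L], Beer-Lambert weights)
    z_nodes, z_w = np.polynomial.legendre.leggauss(n_depth)
    z = 0.5 * length_cm * (z_nodes + 1.0)
    wz = z_w * 0.5 * length_cm * mu_p * np.exp(-mu_p * z)
    wz /= wz.sum()  # condition on interaction within the slab

    # direction quadrature: nu = cos(theta) uniform on [-1, 1]
    nu_nodes, nu_w = np.polynomial.legendre.leggauss(n_mu)
    wnu = nu_w / 2.0

    r_max = 6.0 / mu_k * 1e4  # um
    r_edges = np.linspace(0.0, r_max, n_radii + 1)
    mass = np.zeros(n_radii)
    f_k = 0.0

    for zi, wzi in zip(z, wz):
        # path length to the slab boundary for each direction
        with np.errstate(divide="ignore"):
            s_b = np.where(nu_nodes > 0, (length_cm - zi) / np.maximum(nu_nodes, 1e-12),
                           zi / np.maximum(-nu_nodes, 1e-12))
        p_abs = 1.0 - np.exp(-mu_k * s_b)
        f_k += float(wzi * np.sum(wnu * p_abs))
        # lateral displacement distribution: s ~ truncated exponential,
        # rho = s * sqrt(1 - nu^2); integrate s on per-direction grids
        sin_t = np.sqrt(np.maximum(1.0 - nu_nodes**2, 0.0))
        for nuk, wk, sb, st in zip(nu_nodes, wnu, s_b, sin_t):
            if st < 1e-9:
                mass[0] += wzi * wk * (1.0 - np.exp(-mu_k * sb))
                continue
            # absorbed mass per radial bin: rho bin [r0,r1] <-> s in [r0,r1]/st
            s_lo = np.minimum(r_edges[:-1] * 1e-4 / st, sb)
            s_hi = np.minimum(r_edges[1:] * 1e-4 / st, sb)
            dm = np.exp(-mu_k * s_lo) - np.exp(-mu_k * s_hi)
            mass += wzi * wk * dm

    total = mass.sum()
    if total > 0:
        mass /= total
    return ReabsorptionKernel(r_edges, mass, float(f_k), e_k)


def reabsorption_transfer(kernel: ReabsorptionKernel, frequency_mm: float) -> float:
    """Radial transfer function R(u): 2D Fourier transform of p_K.

    For an isotropic kernel this is the Hankel transform
    R(u) = sum_i m_i J0(2 pi u r_i); R(0) = 1.
    """
    from scipy.special import j0
    centers_mm = 0.5 * (kernel.radii_um[:-1] + kernel.radii_um[1:]) * 1e-3
    return float(np.sum(kernel.radial_mass * j0(2.0 * np.pi * frequency_mm * centers_mm)))
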