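"""Parallel-cascade energy response, large-area gain, and thresholds.

A photoelectric interaction at energy E follows one of three paths:

* path A -- no K x ray produced: all of E deposits locally;
* path B -- a K x ray is produced and escapes: E - E_K deposits locally;
* path B+C -- the K x ray is reabsorbed: E - E_K deposits locally and E_K
  deposits at a site displaced by a draw from the reabsorption kernel.

For an interaction at lateral position r relative to an element center,
the energy collected by the element is normal with mean E_X * P_CS(r) and
variance F w mean + sigma_e^2 (conversion-gain statistics plus electronic
noise).  Position-averaging those normals over the incidence position
yields the pulse-height spectrum; integrating over an energy bin yields
counting probabilities and the large-area gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .fluorescence import ReabsorptionKernel, k_reabsorption
from .materials import Material, interaction_fractions, quantum_efficiency
from .transport import ChargeSharingKernel, collection_probability_map

__all__ = [
    "EnergyBins",
    "EnergyResponse",
    "deposited_energy_stats",
    "bin_probability",
    "path_response",
    "energy_response",
    "klein_nishina_recoil_quadrature",
    "large_area_gain",
    "mean_bin_counts",
    "equal_count_threshold",
]


@dataclass(frozen=True)
class EnergyBins:
    """Ordered, non-overlapping counting bins [keV]."""

    edges: tuple[tuple[float, float], ...]

    def __post_init__(self):
        prev = -np.inf
        for lo, hi in self.edges:
            if lo >= hi:
                raise ValueError("bin lower edge must be below upper edge")
            if lo < prev:
                raise ValueError("bins must be ordered and non-overlapping")
            prev = hi

    @classmethod
    def single(cls, threshold_kev: float = 10.0, top_kev: float = 1e4) -> "EnergyBins":
        return cls(((threshold_kev, top_kev),))

    @classmethod
    def two_bin(cls, threshold_kev: float, split_kev: float,
                top_kev: float = 1e4) -> "EnergyBins":
        return cls(((threshold_kev, split_kev), (split_kev, top_kev)))

    @property
    def threshold_kev(self) -> float:
        return self.edges[0][0]

    def __len__(self):
        return len(self.edges)


def deposited_energy_stats(path_energy_kev: float, pcs: float, sigma_e_kev: float,
                           fano: float = 1.0, w_pair_kev: float = 0.005):
    """Mean and variance [keV, keV^2] of the collected-energy normal.

    mean = E_X * P_CS; variance = F * w * mean + sigma_e^2 (conversion-gain
    statistics expressed in energy units plus electronic noise).
    """
    mean = path_energy_kev * pcs
    var = fano * w_pair_kev * mean + sigma_e_kev**2
    return mean, var


def bin_probability(mean, var, lo: float, hi: float):
    """P(lo <= deposited energy < hi) for normal deposition statistics."""
    sd = np.sqrt(var)
    return ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd)


@dataclass(frozen=True)
class EnergyResponse:
    """Pulse-height spectrum per interaction [keV^-1] with path decomposition.

    Densities are normalized over the lateral incidence region of area
    ``region_area_um2`` (the large near-zero peak represents interactions
    far from the element); bin probabilities per interaction are
    ``(region_area / aperture_area) * integral`` (the kappa factors).
    """

    energy_grid_kev: np.ndarray
    density: np.ndarray        # weighted total (integrates to 1 per interaction)
    path_a: np.ndarray         # each path density integrates to 1
    path_b: np.ndarray
    path_bc: np.ndarray
    region_area_um2: float = float("nan")
    aperture_area_um2: float = float("nan")

    @property
    def area_ratio(self) -> float:
        return self.region_area_um2 / self.aperture_area_um2

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("energy_keV,density_per_keV,path_A,path_B,path_BC\n")
            for row in zip(self.energy_grid_kev, self.density, self.path_a,
                           self.path_b, self.path_bc):
                fh.write(",".join(f"{v:.8g}" for v in row) + "\n")


class _MeanMixture:
    """Position-averaged normal mixture, represented by a histogram of the
    position-dependent mean values (the variance is tied to the mean)."""

    def __init__(self, n_bins: int = 800):
        self.n_bins = n_bins

    def density(self, mean_map: np.ndarray, energy_grid: np.ndarray,
                sigma_e: float, fano: float, w_pair: float) -> np.ndarray:
        flat = mean_map.ravel()
        top = float(flat.max())
        if top <= 0:
            means = np.array([0.0])
            weights = np.array([1.0])
        else:
            hist, edges = np.histogram(flat, bins=self.n_bins, range=(0.0, top * (1 + 1e-9)))
            centers = 0.5 * (edges[:-1] + edges[1:])
            keep = hist > 0
            means, weights = centers[keep], hist[keep] / flat.size
        var = fano * w_pair * means + sigma_e**2
        sd = np.sqrt(var)
        z = (energy_grid[None, :] - means[:, None]) / sd[:, None]
        pdf = np.exp(-0.5 * z**2) / (np.sqrt(2 * np.pi) * sd[:, None])
        return weights @ pdf


def path_response(path_energy_kev: float, kernel: ChargeSharingKernel,
                  aperture_um: tuple[float, float], sigma_e_kev: float = 2.0,
                  fano: float = 1.0, w_pair_kev: float = 0.005,
                  energy_grid_kev: np.ndarray | None = None,
                  reabsorption: ReabsorptionKernel | None = None,
                  k_energy_kev: float = 0.0,
                  pcs: tuple[np.ndarray, np.ndarray] | None = None,
                  pcs_spacing_um: float | None = None):
    """Position-averaged normal mixture for one cascade path.

    Without ``reabsorption`` this is path A or B at deposit energy
    ``path_energy_kev``.  With it, the B+C mixture: the local deposit is
    ``path_energy_kev`` plus ``k_energy_kev`` deposited at a site displaced
    by a draw from the reabsorption kernel (radial/angular quadrature).

    Returns ``(energy_grid, density)`` with the density normalized per
    interaction.  ``pcs = (coords, values)`` may be supplied to reuse a
    precomputed collection-probability map.
    """
    if energy_grid_kev is None:
        top = path_energy_kev + k_energy_kev + 5.0 * sigma_e_kev
        energy_grid_kev = np.arange(-4.0 * sigma_e_kev, top + 0.25, 0.25)
    if pcs is None:
        h = pcs_spacing_um or max(1.0, kernel.hwhm_um / 10.0)
        pcs = collection_probability_map(kernel, aperture_um, spacing_um=h)
    coords, pmap = pcs
    h = coords[1] - coords[0]
    mix = _MeanMixture()

    def dens_of(mean_map):
        return mix.density(mean_map, energy_grid_kev, sigma_e_kev, fano, w_pair_kev)

    if reabsorption is None or reabsorption.f_k == 0.0 or k_energy_kev == 0.0:
        dens = dens_of(path_energy_kev * pmap)
    else:
        radii, masses = _radial_nodes(reabsorption, n_nodes=24)
        angles = np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False) + np.pi / 8
        dens = np.zeros_like(energy_grid_kev)
        for r, m in zip(radii, masses):
            for ang in angles:
                dx = int(round(r * np.cos(ang) / h))
                dy = int(round(r * np.sin(ang) / h))
                shifted = _shift2d(pmap, dx, dy)
                dens += (m / len(angles)) * dens_of(
                    path_energy_kev * pmap + k_energy_kev * shifted)
    norm = np.trapezoid(dens, energy_grid_kev)
    if abs(norm - 1.0) > 5e-3:
        raise ValueError(f"position quadrature too coarse: path density integral {norm}")
    return energy_grid_kev, dens / norm


def _radial_nodes(reabs: ReabsorptionKernel, n_nodes: int = 24):
    """Aggregate the radial relocation mass into ~n quantile nodes."""
    centers = 0.5 * (reabs.radii_um[:-1] + reabs.radii_um[1:])
    mass = reabs.radial_mass
    cum = np.cumsum(mass)
    qs = np.linspace(0, 1, n_nodes + 1)[1:-1]
    splits = np.searchsorted(cum, qs)
    groups = np.split(np.arange(len(mass)), np.unique(splits))
    radii, weights = [], []
    for g in groups:
        m = mass[g].sum()
        if m <= 0:
            continue
        radii.append(np.sum(centers[g] * mass[g]) / m)
        weights.append(m)
    w = np.array(weights)
    return np.array(radii), w / w.sum()


def _shift2d(arr: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Zero-filled integer shift."""
    out = np.roll(arr, (dx, dy), axis=(0, 1))
    if dx > 0:
        out[:dx, :] = 0.0
    elif dx < 0:
        out[dx:, :] = 0.0
    if dy > 0:
        out[:, :dy] = 0.0
    elif dy < 0:
        out[:, dy:] = 0.0
    return out


def energy_response(energy_kev: float, material: Material,
                    kernel: ChargeSharingKernel, thickness_um: float,
                    aperture_um: tuple[float, float], sigma_e_kev: float = 2.0,
                    energy_grid_kev: np.ndarray | None = None,
                    pcs_spacing_um: float | None = None) -> EnergyResponse:
    """Full per-interaction pulse-height spectrum with Cd/Te element mixing.

    The density is conditioned on an interaction; multiply by the quantum
    efficiency for a per-incident-photon response.  Compton interactions
    contribute through path A at Klein-Nishina-distributed recoil energies.
    """
    if energy_grid_kev is None:
        top = energy_kev + 5.0 * sigma_e_kev
        energy_grid_kev = np.arange(-4.0 * sigma_e_kev, top + 0.25, 0.25)
    frac = interaction_fractions(material, energy_kev)
    fano, w = material.fano, material.w_pair_kev
    h = pcs_spacing_um or max(1.0, kernel.hwhm_um / 10.0)
    pcs = collection_probability_map(kernel, aperture_um, spacing_um=h)
    hh = pcs[0][1] - pcs[0][0]
    region_area = (len(pcs[0]) * hh) ** 2

    def resp(dep, reabs=None, ek=0.0):
        _, d = path_response(dep, kernel, aperture_um, sigma_e_kev, fano, w,
                             energy_grid_kev, reabs, ek, pcs=pcs)
        return d

    total = np.zeros_like(energy_grid_kev)
    comp_a = np.zeros_like(energy_grid_kev)
    comp_b = np.zeros_like(energy_grid_kev)
    comp_bc = np.zeros_like(energy_grid_kev)

    for el in material.elements:
        nu = frac.nu[el.symbol]
        xi = frac.xi_pe[el.symbol]
        if energy_kev > el.k_edge_kev:
            pkwk = el.k_participation * el.fluorescence_yield
            reabs = k_reabsorption(material, el.symbol, thickness_um, energy_kev)
            f_k = reabs.f_k
        else:
            pkwk, f_k, reabs = 0.0, 0.0, None
        d_a = resp(energy_kev)
        comp_a += nu * xi * d_a
        total += nu * xi * (1.0 - pkwk) * d_a
        if pkwk > 0:
            e_k = el.mean_k_xray_kev
            d_b = resp(energy_kev - e_k)
            d_bc = resp(energy_kev - e_k, reabs, e_k)
            comp_b += nu * xi * d_b
            comp_bc += nu * xi * d_bc
            total += nu * xi * (pkwk * (1.0 - f_k) * d_b + pkwk * f_k * d_bc)
        if xi < 1.0:
            recoils, weights = klein_nishina_recoil_quadrature(energy_kev, 16)
            for t, wgt in zip(recoils, weights):
                if t < 0.05:
                    # sub-50-eV recoils: indistinguishable from zero deposit
                    t = 0.0
                total += nu * (1.0 - xi) * wgt * resp(t)
    return EnergyResponse(energy_grid_kev, total, comp_a, comp_b, comp_bc,
                          region_area_um2=region_area,
                          aperture_area_um2=aperture_um[0] * aperture_um[1])


def klein_nishina_recoil_quadrature(energy_kev: float, n_nodes: int = 64):
    """Recoil-energy nodes and weights from the Klein-Nishina cross section.

    Gauss-Legendre over the scattering-angle cosine; weights normalized.
    The recoil energy is bounded by the Compton edge E(2E/511)/(1+2E/511).
    """
    k = energy_kev / 510.99895
    mu, w = np.polynomial.legendre.leggauss(n_nodes)
    kp = 1.0 / (1.0 + k * (1.0 - mu))
    dsig = kp**2 * (kp + 1.0 / kp - (1.0 - mu**2))
    weights = w * dsig
    weights /= weights.sum()
    recoil = energy_kev * (1.0 - kp)
    return recoil, weights


def large_area_gain(response: EnergyResponse, bins: EnergyBins,
                    alpha: float = 1.0) -> np.ndarray:
    """Per-bin large-area gain: counts per incident photon.

    ``alpha`` is the quantum efficiency; the response is per interaction.
    Bin integrals are exact trapezoids restricted to [lo, hi).
    """
    e = response.energy_grid_kev
    ratio = response.area_ratio
    if not np.isfinite(ratio):
        ratio = 1.0
    # integrate via the cumulative trapezoid so bin edges off the grid (or
    # shared between bins) partition the integral exactly
    from scipy.integrate import cumulative_trapezoid
    cdf = np.concatenate([[0.0], cumulative_trapezoid(response.density, e)])

    def cdf_at(x):
        return np.interp(x, e, cdf)

    out = [alpha * ratio * (cdf_at(min(hi, e[-1])) - cdf_at(max(lo, e[0])))
           for lo, hi in bins.edges]
    return np.array(out)


def mean_bin_counts(q0_per_mm2: float, gain: np.ndarray, aperture_area_mm2: float):
    """Mean counts per element: c_j = q0 * a * G_j."""
    if q0_per_mm2 < 0:
        raise ValueError("fluence must be nonnegative")
    return q0_per_mm2 * aperture_area_mm2 * np.asarray(gain)


def equal_count_threshold(count_low, low_threshold_kev: float = 10.0,
                          upper_kev: float = 150.0, tol: float = 0.005) -> float:
    """Bisection for the bin split yielding equal counts in the two bins.

    ``count_low(split)`` must return ``(c_low, c_high)`` for a candidate
    split energy.  Terminates when |cL - cH|/(cL + cH) < ``tol``.
    """
    lo, hi = low_threshold_kev + 1e-3, upper_kev

    def imbalance(split):
        c_l, c_h = count_low(split)
        return (c_l - c_h) / (c_l + c_h)

    f_lo, f_hi = imbalance(lo), imbalance(hi)
    if f_lo * f_hi > 0:
        raise ValueError("no equal-count split within the search interval")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        f_mid = imbalance(mid)
        if abs(f_mid) < tol:
            return mid
        if f_lo * f_mid <= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    raise RuntimeError("equal-count bisection did not converge")


def spectrum_quantum_efficiency(material: Material, thickness_um: float, spectrum):
    """Convenience alias used by the pipeline."""
    return quantum_efficiency(material, thickness_um, spectrum)
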