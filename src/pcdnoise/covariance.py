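"""Presampling cross covariance and noise power spectra of counting bins.

The pair covariance of counts in energy bins i and j of two elements
separated by lag tau is assembled from windowed counting-probability maps

    Phi_{X,i}(x) = P(deposited energy in bin i | interaction at x),

one map per cascade path X (A, B, and the fluorescence path B+C at each
relocation displacement), as the position integral of Phi_i(x)
Phi_j(x + tau) -- a cross-correlation evaluated with FFTs.  The region of
strongly overlapping elements (|tau| inside half an aperture) cannot be
described by that product and is filled by interpolation anchored at the
tau = 0 value delta_ij c_j (counts in a single element are Poisson).

The presampling NPS is the continuous Fourier transform of the covariance;
the digital NPS adds noise aliasing, computed exactly as the discrete-time
Fourier transform of the covariance sampled on the element lattice.

All covariances are carried per unit incident fluence (q0 = 1/mm^2);
every reported metric (DQE, NNPS, multiplicity) is invariant to q0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy.signal import zoom_fft
from scipy.special import ndtr

from .fluorescence import ReabsorptionKernel, k_reabsorption
from .materials import Material, interaction_fractions, quantum_efficiency
from .response import EnergyBins, klein_nishina_recoil_quadrature
from .transport import ChargeSharingKernel, TransportParams, compute_kernel, _resample_kernel

__all__ = [
    "DetectorGeometry",
    "ChannelGrid",
    "CovarianceMap",
    "NPSSet",
    "SpectrumNPSModel",
    "path_window_maps",
    "joint_energy_pdf",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Element lattice: pitch, aperture (unity fill factor by default)."""

    pitch_um: tuple[float, float]
    aperture_um: tuple[float, float] | None = None
    thickness_um: float = 732.0

    def __post_init__(self):
        if self.aperture_um is None:
            object.__setattr__(self, "aperture_um", self.pitch_um)
        ax, ay = self.aperture_um
        px, py = self.pitch_um
        if not (0 < ax <= px and 0 < ay <= py):
            raise ValueError("aperture must be positive and no larger than pitch")

    @property
    def fill_factor(self) -> float:
        ax, ay = self.aperture_um
        px, py = self.pitch_um
        return (ax * ay) / (px * py)

    @property
    def aperture_area_mm2(self) -> float:
        ax, ay = self.aperture_um
        return ax * ay * 1e-6

    @property
    def pitch_area_mm2(self) -> float:
        px, py = self.pitch_um
        return px * py * 1e-6

    @property
    def nyquist_mm(self) -> float:
        return 1.0 / (2.0 * self.pitch_um[0] * 1e-3)


@dataclass(frozen=True)
class ChannelGrid:
    """Square lag/position grid aligned with the element lattice.

    ``h_um`` divides the pitch exactly (``m`` cells per pitch) so lattice
    lags fall on grid nodes.
    """

    h_um: float
    n_half: int      # cells on each side of zero; coords has 2 n_half + 1 nodes
    m: int           # cells per pitch

    @classmethod
    def for_geometry(cls, geometry: DetectorGeometry, extent_um: float,
                     target_h_um: float = 8.0) -> "ChannelGrid":
        pitch = geometry.pitch_um[0]
        m = 16
        while pitch / m > target_h_um:
            m *= 2
        h = pitch / m
        n_half = int(np.ceil(extent_um / (h * m))) * m
        return cls(h, n_half, m)

    @property
    def coords_um(self) -> np.ndarray:
        return np.arange(-self.n_half, self.n_half + 1) * self.h_um

    @property
    def n(self) -> int:
        return 2 * self.n_half + 1


def _pcs_on_grid(kernel: ChargeSharingKernel, aperture_um, grid: ChannelGrid):
    """Collection probability P_CS on the channel grid (rect * kernel)."""
    h = grid.h_um
    coords = grid.coords_um
    ax, ay = aperture_um
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    cov_x = np.clip((ax / 2 - np.abs(xx)) / h + 0.5, 0.0, 1.0)
    cov_y = np.clip((ay / 2 - np.abs(yy)) / h + 0.5, 0.0, 1.0)
    rect = cov_x * cov_y
    kern = _resample_kernel(kernel, h) * h * h
    from scipy.signal import fftconvolve
    return np.clip(fftconvolve(rect, kern, mode="same"), 0.0, 1.0)


def path_window_maps(mean_map: np.ndarray, bins: EnergyBins, sigma_e_kev: float,
                     fano: float = 1.0, w_pair_kev: float = 0.005) -> list[np.ndarray]:
    """Phi_{X,i}: per-bin counting probabilities for a deposited-mean map."""
    var = fano * w_pair_kev * np.maximum(mean_map, 0.0) + sigma_e_kev**2
    sd = np.sqrt(var)
    out = []
    for lo, hi in bins.edges:
        hi_term = ndtr((hi - mean_map) / sd) if np.isfinite(hi) else 1.0
        out.append(hi_term - ndtr((lo - mean_map) / sd))
    return out


@dataclass
class CovarianceMap:
    """Centered pair covariance K_{ij}(tau) per unit incident fluence [mm^2]."""

    grid: ChannelGrid
    geometry: DetectorGeometry
    bins: EnergyBins
    k: dict            # (i, j) i<=j -> (n, n) array, mm^2
    cbar: np.ndarray   # per-bin mean counts per element per unit fluence [mm^2]
    gbar: np.ndarray   # per-bin large-area gain (counts per incident photon)
    alpha: float       # spectrum-averaged quantum efficiency
    overlap_filled: bool = False

    def pair(self, i: int, j: int) -> np.ndarray:
        return self.k[(i, j)] if i <= j else self.k[(j, i)]

    def lattice_samples(self, i: int, j: int) -> np.ndarray:
        """K sampled at tau = (l px, n py) for all lattice lags on the grid."""
        g = self.grid
        sel = np.arange(0, g.n, g.m)
        return self.pair(i, j)[np.ix_(sel, sel)]

    def lattice_sum(self, i: int, j: int) -> float:
        return float(self.lattice_samples(i, j).sum())


def overlap_interpolation(cov: CovarianceMap) -> CovarianceMap:
    """Fill the region of strongly overlapping elements (|tau| < a/2).

    The product-of-window-maps construction treats the two elements'
    quanta as independently thinned, which breaks down as the elements
    approach complete overlap; inside the half-aperture box the
    covariance is interpolated linearly along each ray between the
    tau = 0 anchor delta_ij c_j (Poisson single-element covariance) and
    the computed value where the ray leaves the box.
    """
    g = cov.grid
    ax, ay = (0.5 * a for a in cov.geometry.aperture_um)
    coords = g.coords_um
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    s = np.maximum(np.abs(xx) / ax, np.abs(yy) / ay)
    inside = s < 1.0
    new_k = {}
    for (i, j), arr in cov.k.items():
        anchor = cov.cbar[i] if i == j else 0.0
        out = arr.copy()
        ss = s[inside]
        bx = np.where(ss > 0, xx[inside] / np.maximum(ss, 1e-12), 0.0)
        by = np.where(ss > 0, yy[inside] / np.maximum(ss, 1e-12), 0.0)
        # bilinear sample of the boundary value at tau / s
        fx = (bx + g.n_half * g.h_um) / g.h_um
        fy = (by + g.n_half * g.h_um) / g.h_um
        x0 = np.clip(np.floor(fx).astype(int), 0, g.n - 2)
        y0 = np.clip(np.floor(fy).astype(int), 0, g.n - 2)
        tx, ty = fx - x0, fy - y0
        bval = (arr[x0, y0] * (1 - tx) * (1 - ty) + arr[x0 + 1, y0] * tx * (1 - ty)
                + arr[x0, y0 + 1] * (1 - tx) * ty + arr[x0 + 1, y0 + 1] * tx * ty)
        out[inside] = (1.0 - ss) * anchor + ss * bval
        new_k[(i, j)] = out
    return CovarianceMap(g, cov.geometry, cov.bins, new_k, cov.cbar, cov.gbar,
                         cov.alpha, overlap_filled=True)


@dataclass
class NPSSet:
    """Presampling and digital (cross) NPS per unit incident fluence.

    ``presampling[(i,j)]``/``digital[(i,j)]`` are 2D arrays on the
    frequency grids ``freq_presampling_mm``/``freq_digital_mm`` (both
    fftshift-ordered, centered on zero frequency).  Units mm^2 x (per
    unit q0); multiply by q0 for absolute NPS.
    """

    freq_presampling_mm: np.ndarray
    presampling: dict
    freq_digital_mm: np.ndarray
    digital: dict
    cbar: np.ndarray
    geometry: DetectorGeometry

    def pair_digital(self, i, j):
        return self.digital[(i, j)] if i <= j else self.digital[(j, i)]

    def pair_presampling(self, i, j):
        return self.presampling[(i, j)] if i <= j else self.presampling[(j, i)]

    def nnps_digital(self, i: int, j: int | None = None) -> np.ndarray:
        j = i if j is None else j
        return self.pair_digital(i, j) / (self.cbar[i] * self.cbar[j])

    def radial_profile(self, arr: np.ndarray, freqs: np.ndarray,
                       n_rings: int | None = None):
        """Annulus average on rings of one frequency step, ring 0 = u = 0."""
        fx, fy = np.meshgrid(freqs, freqs, indexing="ij")
        rr = np.hypot(fx, fy)
        df = freqs[1] - freqs[0]
        n_rings = n_rings or int(np.ceil(freqs.max() / df)) + 1
        idx = np.minimum((rr / df + 0.5).astype(int), n_rings)
        prof = np.zeros(n_rings)
        for k in range(n_rings):
            mask = idx == k
            prof[k] = arr[mask].mean() if mask.any() else np.nan
        return np.arange(n_rings) * df, prof


def presampling_nps(cov: CovarianceMap, n_freq: int = 65,
                    max_freq_mm: float | None = None) -> tuple[np.ndarray, dict]:
    """Continuous-FT NPS on a zoomed frequency band via 2D zoom FFT."""
    g = cov.grid
    h_mm = g.h_um * 1e-3
    fmax = max_freq_mm if max_freq_mm is not None else cov.geometry.nyquist_mm
    freqs = np.linspace(-fmax, fmax, n_freq)
    out = {}
    for pair, arr in cov.k.items():
        w = _zoom_ft2(arr, h_mm, freqs)
        out[pair] = w
    return freqs, out


def _zoom_ft2(arr: np.ndarray, h_mm: float, freqs: np.ndarray) -> np.ndarray:
    """2D continuous FT of a centered array at the given frequencies [1/mm].

    ``freqs`` must be uniformly spaced (endpoints included); note
    scipy's zoom_fft excludes the upper endpoint, hence the band padding.
    """
    return _zoom_ft2_rect(arr, h_mm, freqs, freqs)


def digital_nps(cov: CovarianceMap, n_freq: int = 129) -> tuple[np.ndarray, dict]:
    """Digital (aliased) NPS as the lattice-sampled covariance DTFT.

    Mathematically identical to summing the presampling NPS over all
    reciprocal-lattice shifts (the aliasing sum); exact because sampling
    the covariance on the element lattice folds all replicas.
    """
    if not cov.overlap_filled:
        raise ValueError("fill the overlap region before computing the digital NPS")
    px, py = cov.geometry.pitch_um
    area_mm2 = cov.geometry.pitch_area_mm2
    out = {}
    for pair in cov.k:
        lat = cov.lattice_samples(*pair)
        nl = lat.shape[0]
        # place centered lattice array into wrap-around order
        c = nl // 2
        rolled = np.zeros((n_freq, n_freq))
        for a in range(nl):
            for b in range(nl):
                rolled[(a - c) % n_freq, (b - c) % n_freq] += lat[a, b]
        w = np.fft.fftshift(np.real(np.fft.fft2(rolled))) * area_mm2
        out[pair] = w
    freqs = np.fft.fftshift(np.fft.fftfreq(n_freq, d=px * 1e-3))
    return freqs, out


def alias_summed_nps(cov: CovarianceMap, n_freq: int = 33, n_shifts: int = 6):
    """Digital NPS via explicit alias summation of the presampling NPS.

    Independent route used for cross-validation: evaluates the presampling
    NPS on shifted bands u + (n/px, m/py) and sums them.  Shifts are
    clamped to the unambiguous band of the lag grid (|u| < 1/(2h)); beyond
    it the discrete transform repeats its own replicas.
    """
    g = cov.grid
    n_shifts = min(n_shifts, g.m // 2 - 1)
    h_mm = g.h_um * 1e-3
    px_mm = cov.geometry.pitch_um[0] * 1e-3
    py_mm = cov.geometry.pitch_um[1] * 1e-3
    nyq = cov.geometry.nyquist_mm
    base = np.linspace(-nyq, nyq, n_freq)
    out = {}
    for pair, arr in cov.k.items():
        total = np.zeros((n_freq, n_freq))
        for a in range(-n_shifts, n_shifts + 1):
            for b in range(-n_shifts, n_shifts + 1):
                fx = base + a / px_mm
                fy = base + b / py_mm
                w = _zoom_ft2_rect(arr, h_mm, fx, fy)
                total += w
        out[pair] = total
    return base, out


def _zoom_ft2_rect(arr, h_mm, fx, fy):
    """2D continuous FT at the uniformly spaced frequencies fx (x) fy."""
    n = arr.shape[0]
    fs = 1.0 / h_mm
    half = (n - 1) // 2

    def axis_transform(a, f, axis):
        if len(f) == 1:
            shape = [1] * a.ndim
            shape[axis] = -1
            k = np.arange(n).reshape(shape)
            return np.sum(a * np.exp(-2j * np.pi * f[0] * k / fs), axis=axis,
                          keepdims=True)
        df = f[1] - f[0]
        # zoom_fft computes m points with step (f2-f1)/m, excluding f2
        z = zoom_fft(a, [f[0], f[0] + len(f) * df], m=len(f), fs=fs, axis=axis)
        return z

    z1 = axis_transform(np.asarray(arr, dtype=complex), fx, 0)
    z1 *= np.exp(2j * np.pi * fx * (half / fs))[:, None]
    z2 = axis_transform(z1, fy, 1)
    z2 *= np.exp(2j * np.pi * fy * (half / fs))[None, :]
    return np.real(z2) * h_mm**2


class _PairAccumulator:
    """Accumulates weighted bin-pair cross-spectra over cascade paths."""

    def __init__(self, grid: ChannelGrid, n_bins: int):
        self.grid = grid
        self.nfft = sfft.next_fast_len(2 * grid.n)
        self.n_bins = n_bins
        self.spec = {(i, j): np.zeros((self.nfft, self.nfft // 2 + 1), dtype=complex)
                     for i in range(n_bins) for j in range(i, n_bins)}
        self.kappa = np.zeros(n_bins)

    def add(self, weight: float, phis: list[np.ndarray], cell_area_um2: float,
            aperture_area_um2: float):
        if weight <= 0:
            return
        ffts = [sfft.rfft2(p, s=(self.nfft, self.nfft)) for p in phis]
        for i in range(self.n_bins):
            self.kappa[i] += weight * phis[i].sum() * cell_area_um2 / aperture_area_um2
            for j in range(i, self.n_bins):
                self.spec[(i, j)] += weight * (ffts[i] * np.conj(ffts[j]))

    def finalize(self) -> dict:
        """Centered real-space covariance arrays [mm^2]."""
        g = self.grid
        out = {}
        scale = (g.h_um * 1e-3) ** 2  # cell area in mm^2
        for pair, spec in self.spec.items():
            c = sfft.irfft2(spec, s=(self.nfft, self.nfft))
            c = np.roll(c, (g.n_half, g.n_half), axis=(0, 1))[: g.n, : g.n]
            c *= scale
            # D4 symmetrization (square aperture, isotropic kernels)
            c = (c + c.T + c[::-1, :] + c[:, ::-1] + c[::-1, ::-1]
                 + c.T[::-1, :] + c.T[:, ::-1] + c.T[::-1, ::-1]) / 8.0
            out[pair] = c
        return out


@dataclass
class SpectrumNPSModel:
    """Full-chain analytic model for one detector configuration.

    Sums per-energy covariance contributions over the incident spectrum
    (stratified fluence-quantile nodes), Cd/Te element mixing, PE/Compton
    interaction types, and the three cascade paths.
    """

    material: Material
    geometry: DetectorGeometry
    spectrum: object                   # XraySpectrum (may be monoenergetic)
    field_v_cm: float = 3333.0
    sigma_e_kev: float = 2.0
    calibration_sigma_um: float = 8.0
    n_energy_nodes: int = 12
    n_fluor_radii: int = 12
    n_fluor_angles: int = 3            # per octant; D4 symmetrization completes
    n_compton_nodes: int = 16
    include_compton: bool = True
    kernel_dr_um: float = 0.25
    grid_target_h_um: float = 8.0
    _kernel_cache: dict = field(default_factory=dict)

    def energy_nodes(self):
        """Stratified fluence-quantile nodes (node energy, fluence weight)."""
        e = self.spectrum.energies_kev
        f = self.spectrum.fluence
        keep = f > 0
        e, f = e[keep], f[keep]
        if len(e) == 1 or self.n_energy_nodes >= len(e):
            return list(zip(e, f / f.sum()))
        cum = np.cumsum(f) / f.sum()
        edges = np.linspace(0, 1, self.n_energy_nodes + 1)
        nodes = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (cum > lo) & (cum <= hi)
            if not mask.any():
                continue
            w = f[mask].sum()
            nodes.append((float(np.sum(e[mask] * f[mask]) / w), float(w)))
        total = sum(w for _, w in nodes)
        return [(en, w / total) for en, w in nodes]

    def kernel_for(self, energy_kev: float) -> ChargeSharingKernel:
        key = round(energy_kev, 2)
        if key not in self._kernel_cache:
            params = TransportParams(thickness_um=self.geometry.thickness_um,
                                     field_v_cm=self.field_v_cm,
                                     w_pair_kev=self.material.w_pair_kev)
            self._kernel_cache[key] = compute_kernel(
                energy_kev, params, dr_um=self.kernel_dr_um,
                calibration_sigma_um=self.calibration_sigma_um)
        return self._kernel_cache[key]

    # ------------------------------------------------------------------
    def build_grid(self) -> ChannelGrid:
        nodes = self.energy_nodes()
        e_max = max(en for en, _ in nodes)
        kern = self.kernel_for(e_max)
        span = 6.0 * kern.hwhm_um
        pk_extent = 350.0
        ax, _ = self.geometry.aperture_um
        extent = ax + span + pk_extent
        return ChannelGrid.for_geometry(self.geometry, extent,
                                        target_h_um=self.grid_target_h_um)

    def _element_terms(self, energy_kev):
        """Per-element weights and reabsorption kernels at one energy."""
        frac = interaction_fractions(self.material, energy_kev)
        terms = []
        for el in self.material.elements:
            nu = frac.nu[el.symbol]
            xi = frac.xi_pe[el.symbol]
            if energy_kev > el.k_edge_kev:
                reabs = k_reabsorption(self.material, el.symbol,
                                       self.geometry.thickness_um, energy_kev)
                pkwk = el.k_participation * el.fluorescence_yield
            else:
                reabs, pkwk = None, 0.0
            terms.append((el, nu, xi, pkwk, reabs))
        return terms

    def _fluor_nodes(self, reabs: ReabsorptionKernel, grid: ChannelGrid):
        """(dx_cells, dy_cells, weight) quadrature of the relocation kernel."""
        centers = 0.5 * (reabs.radii_um[:-1] + reabs.radii_um[1:])
        mass = reabs.radial_mass
        cum = np.cumsum(mass)
        qs = np.linspace(0, 1, self.n_fluor_radii + 1)[1:-1]
        splits = np.unique(np.searchsorted(cum, qs))
        groups = np.split(np.arange(len(mass)), splits)
        radii, weights = [], []
        for gidx in groups:
            msum = mass[gidx].sum()
            if msum <= 0:
                continue
            radii.append(np.sum(centers[gidx] * mass[gidx]) / msum)
            weights.append(msum)
        weights = np.array(weights) / np.sum(weights)
        # octant angles; D4 symmetrization supplies the remaining directions
        na = self.n_fluor_angles
        angles = (np.arange(na) + 0.5) * (np.pi / 4) / na
        max_shift = 0.85 * grid.n_half * grid.h_um
        nodes = []
        for r, wr in zip(radii, weights):
            rc = min(r, max_shift)
            for ang in angles:
                dx = int(round(rc * np.cos(ang) / grid.h_um))
                dy = int(round(rc * np.sin(ang) / grid.h_um))
                nodes.append((dx, dy, wr / na))
        return nodes

    # ------------------------------------------------------------------
    def covariance(self, bins: EnergyBins,
                   grid: ChannelGrid | None = None) -> CovarianceMap:
        grid = grid or self.build_grid()
        acc = _PairAccumulator(grid, len(bins))
        cell = grid.h_um**2
        ap_area = self.geometry.aperture_um[0] * self.geometry.aperture_um[1]
        fano, w_pair = self.material.fano, self.material.w_pair_kev
        alpha_sum = 0.0

        def phis_of(mean_map):
            return path_window_maps(mean_map, bins, self.sigma_e_kev, fano, w_pair)

        for energy, weight in self.energy_nodes():
            alpha = quantum_efficiency(self.material, self.geometry.thickness_um,
                                       energy)
            alpha_sum += weight * alpha
            kern = self.kernel_for(energy)
            pcs = _pcs_on_grid(kern, self.geometry.aperture_um, grid)
            for el, nu, xi, pkwk, reabs in self._element_terms(energy):
                base = weight * alpha * nu
                f_k = reabs.f_k if reabs is not None else 0.0
                # path A
                acc.add(base * xi * (1.0 - pkwk), phis_of(energy * pcs), cell, ap_area)
                if pkwk > 0:
                    e_k = el.mean_k_xray_kev
                    # path B (K photon escapes)
                    acc.add(base * xi * pkwk * (1.0 - f_k),
                            phis_of((energy - e_k) * pcs), cell, ap_area)
                    # path B+C: local E-EK plus relocated EK deposit
                    w_bc = base * xi * pkwk * f_k
                    for dx, dy, wn in self._fluor_nodes(reabs, grid):
                        shifted = _shift(pcs, dx, dy)
                        acc.add(w_bc * wn,
                                phis_of((energy - e_k) * pcs + e_k * shifted),
                                cell, ap_area)
                # Compton: path A at Klein-Nishina recoil energies
                if xi < 1.0 and self.include_compton:
                    recoils, wgts = klein_nishina_recoil_quadrature(
                        energy, self.n_compton_nodes)
                    lo = bins.threshold_kev
                    for t, wt in zip(recoils, wgts):
                        if t + 5.0 * self.sigma_e_kev < lo:
                            continue  # cannot cross the counting threshold
                        acc.add(base * (1.0 - xi) * wt, phis_of(t * pcs),
                                cell, ap_area)

        k = acc.finalize()
        gbar = acc.kappa.copy()
        cbar = gbar * self.geometry.aperture_area_mm2
        return CovarianceMap(grid, self.geometry, bins, k, cbar, gbar, alpha_sum)

    # ------------------------------------------------------------------
    def gain_mixture(self, grid: ChannelGrid | None = None):
        """Histogram mixture of deposited-energy means for fast gain curves.

        Returns a list of (means, weights) whose bin probabilities times
        weights sum to the per-bin gain for arbitrary bins.
        """
        return [c for _, _, node in self.per_energy_gain_mixtures(grid)
                for c in node]

    def per_energy_gain_mixtures(self, grid: ChannelGrid | None = None):
        """Per-energy-node gain mixtures: list of (energy, weight, comps).

        Each node's comps carry the fluence weight already, so per-node
        gains from ``gains_for_bins(comps, bins)`` must be divided by the
        node weight for a per-photon-at-that-energy gain.
        """
        grid = grid or self.build_grid()
        cell = grid.h_um**2
        ap_area = self.geometry.aperture_um[0] * self.geometry.aperture_um[1]
        nodes_out = []
        comps = []

        def push(weight, mean_map):
            if weight <= 0:
                return
            flat = mean_map.ravel()
            top = float(flat.max())
            if top <= 0:
                comps.append((np.array([0.0]), np.array([weight * flat.size
                                                         * cell / ap_area])))
                return
            hist, edges = np.histogram(flat, bins=600, range=(0, top * (1 + 1e-9)))
            centers = 0.5 * (edges[:-1] + edges[1:])
            keep = hist > 0
            comps.append((centers[keep],
                          weight * hist[keep] * cell / ap_area))

        for energy, weight in self.energy_nodes():
            comps = []
            alpha = quantum_efficiency(self.material, self.geometry.thickness_um,
                                       energy)
            kern = self.kernel_for(energy)
            pcs = _pcs_on_grid(kern, self.geometry.aperture_um, grid)
            for el, nu, xi, pkwk, reabs in self._element_terms(energy):
                base = weight * alpha * nu
                f_k = reabs.f_k if reabs is not None else 0.0
                push(base * xi * (1.0 - pkwk), energy * pcs)
                if pkwk > 0:
                    e_k = el.mean_k_xray_kev
                    push(base * xi * pkwk * (1.0 - f_k), (energy - e_k) * pcs)
                    w_bc = base * xi * pkwk * f_k
                    for dx, dy, wn in self._fluor_nodes(reabs, grid):
                        shifted = _shift(pcs, dx, dy)
                        push(w_bc * wn, (energy - e_k) * pcs + e_k * shifted)
                if xi < 1.0 and self.include_compton:
                    recoils, wgts = klein_nishina_recoil_quadrature(
                        energy, self.n_compton_nodes)
                    for t, wt in zip(recoils, wgts):
                        push(base * (1.0 - xi) * wt, t * pcs)
            nodes_out.append((energy, weight, comps))
        return nodes_out

    def gains_for_bins(self, comps, bins: EnergyBins) -> np.ndarray:
        fano, w_pair = self.material.fano, self.material.w_pair_kev
        out = np.zeros(len(bins))
        for means, weights in comps:
            var = fano * w_pair * means + self.sigma_e_kev**2
            sd = np.sqrt(var)
            for i, (lo, hi) in enumerate(bins.edges):
                hi_t = ndtr((hi - means) / sd) if np.isfinite(hi) else 1.0
                out[i] += np.sum(weights * (hi_t - ndtr((lo - means) / sd)))
        return out


def _shift(arr: np.ndarray, dx: int, dy: int) -> np.ndarray:
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


def nps_from_covariance(cov: CovarianceMap, n_freq_presampling: int = 65,
                        n_freq_digital: int = 129) -> NPSSet:
    """Presampling + digital NPS from a (overlap-filled) covariance map."""
    if not cov.overlap_filled:
        cov = overlap_interpolation(cov)
    fp, wp = presampling_nps(cov, n_freq=n_freq_presampling)
    fd, wd = digital_nps(cov, n_freq=n_freq_digital)
    return NPSSet(fp, wp, fd, wd, cov.cbar, cov.geometry)


def joint_energy_pdf(energy_kev: float, kernel: ChargeSharingKernel,
                     geometry: DetectorGeometry, tau_um: tuple[float, float],
                     sigma_e_kev: float = 2.0, fano: float = 1.0,
                     w_pair_kev: float = 0.005,
                     energy_grid_kev: np.ndarray | None = None,
                     spacing_um: float = 4.0):
    """Path-A joint PDF p(eps, eps'; tau) for two elements at lag tau.

    Diagnostic/validation quantity: integrating it over bin rectangles
    reproduces the path-A covariance entries.  Units keV^-2 per unit
    detector area (the position average is taken over the evaluation
    region; multiply by region area for the Eq.-normalized form).
    """
    if energy_grid_kev is None:
        energy_grid_kev = np.arange(-8.0, energy_kev + 10.0, 0.5)
    from .transport import collection_probability_map
    coords, pcs = collection_probability_map(kernel, geometry.aperture_um,
                                             spacing_um=spacing_um)
    h = coords[1] - coords[0]
    dx, dy = int(round(tau_um[0] / h)), int(round(tau_um[1] / h))
    shifted = _shift(pcs, dx, dy)
    m1 = energy_kev * pcs
    m2 = energy_kev * shifted
    v1 = fano * w_pair_kev * m1 + sigma_e_kev**2
    v2 = fano * w_pair_kev * m2 + sigma_e_kev**2
    e = energy_grid_kev
    pdf = np.zeros((len(e), len(e)))
    norm1 = 1.0 / np.sqrt(2 * np.pi * v1)
    norm2 = 1.0 / np.sqrt(2 * np.pi * v2)
    for a in range(len(e)):
        g1 = norm1 * np.exp(-0.5 * (e[a] - m1) ** 2 / v1)
        for b in range(len(e)):
            g2 = norm2 * np.exp(-0.5 * (e[b] - m2) ** 2 / v2)
            pdf[a, b] = np.mean(g1 * g2)
    return energy_grid_kev, pdf
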