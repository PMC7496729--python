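"""Estimators for simulated (or measured) photon-counting images.

* ensemble NPS: averaged periodogram of mean-subtracted flat-field ROIs,
  |DFT|^2 * pitch_x * pitch_y / (Nx Ny), radially averaged in annuli of
  one frequency step;
* pixel-SNR power-law fit SNR = eta * mu^gamma (Poisson counts predict
  eta = 1, gamma = 1/2);
* energy-response calibration: nonlinear least squares of the local-
  deposition (path A) response model to a pulse-height spectrum, fitting
  electron mobility, electronic noise, and drift time, with a synthetic-
  spectrum generator standing in for bench measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .covariance import DetectorGeometry
from .response import path_response
from .transport import TransportParams, compute_kernel

__all__ = [
    "NPSEstimate",
    "SNRFit",
    "estimate_nps",
    "fit_pixel_snr",
    "EnergyResponseFit",
    "fit_energy_response",
    "synthetic_pulse_height_spectrum",
]


@dataclass
class NPSEstimate:
    freq_x_mm: np.ndarray          # fftshifted axes
    nps_2d: np.ndarray             # ensemble-averaged periodogram [mm^2]
    radial_freq_mm: np.ndarray
    radial_profile: np.ndarray
    n_images: int
    pitch_mm: tuple[float, float]


def estimate_nps(images: list[np.ndarray], geometry: DetectorGeometry,
                 edge_exclude: int = 3) -> NPSEstimate:
    """Ensemble NPS of flat-field count images.

    Each image is cropped by ``edge_exclude`` elements, mean-subtracted,
    and periodogram-averaged.  The zero-frequency bin is the (excluded)
    DC sample and reports 0 by construction of mean subtraction; it is
    kept as ring 0 of the radial profile.
    """
    if len(images) < 2:
        raise ValueError("need at least two images")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("images must share a common shape")
    px_mm = geometry.pitch_um[0] * 1e-3
    py_mm = geometry.pitch_um[1] * 1e-3
    acc = None
    for im in images:
        roi = im[edge_exclude:im.shape[0] - edge_exclude,
                 edge_exclude:im.shape[1] - edge_exclude].astype(float)
        roi -= roi.mean()
        per = np.abs(np.fft.fft2(roi)) ** 2 * px_mm * py_mm / roi.size
        acc = per if acc is None else acc + per
    nps2d = np.fft.fftshift(acc / len(images))
    n0, n1 = nps2d.shape
    fx = np.fft.fftshift(np.fft.fftfreq(n0, d=px_mm))
    fy = np.fft.fftshift(np.fft.fftfreq(n1, d=py_mm))
    xx, yy = np.meshgrid(fx, fy, indexing="ij")
    rr = np.hypot(xx, yy)
    df = fx[1] - fx[0]
    n_rings = int(np.ceil(rr.max() / df)) + 1
    idx = np.minimum((rr / df + 0.5).astype(int), n_rings - 1)
    prof = np.full(n_rings, np.nan)
    for k in range(n_rings):
        mask = idx == k
        if mask.any():
            prof[k] = nps2d[mask].mean()
    return NPSEstimate(fx, nps2d, np.arange(n_rings) * df, prof,
                       len(images), (px_mm, py_mm))


@dataclass
class SNRFit:
    eta: float
    gamma: float
    eta_err: float
    gamma_err: float
    chi2_reduced: float


def fit_pixel_snr(images_by_exposure: dict, edge_exclude: int = 3) -> SNRFit:
    """Fit SNR = eta mu^gamma across exposure groups.

    ``images_by_exposure`` maps an exposure label to a list of 2D count
    images.  For each group the pixel mean, pixel SNR (mean/std over the
    interior), and the standard error of the SNR are estimated; the
    power law is then fit by weighted nonlinear least squares.
    """
    if len(images_by_exposure) < 3:
        raise ValueError("need at least three exposure levels")
    mus, snrs, errs = [], [], []
    for _, imgs in sorted(images_by_exposure.items()):
        vals = []
        for im in imgs:
            roi = im[edge_exclude:im.shape[0] - edge_exclude,
                     edge_exclude:im.shape[1] - edge_exclude].astype(float)
            sd = roi.std(ddof=1)
            if sd == 0:
                raise ValueError("zero-variance image: cannot form an SNR")
            vals.append(roi.mean() / sd)
        mus.append(np.mean([im[edge_exclude:-edge_exclude,
                               edge_exclude:-edge_exclude].mean()
                            for im in imgs]))
        snrs.append(np.mean(vals))
        errs.append(np.std(vals, ddof=1) / np.sqrt(len(vals)) if len(vals) > 1
                    else 0.05 * np.mean(vals))
    mus, snrs, errs = map(np.asarray, (mus, snrs, errs))
    errs = np.where(errs <= 0, 0.05 * snrs, errs)

    def model(mu, eta, gamma):
        return eta * mu**gamma

    popt, pcov = curve_fit(model, mus, snrs, p0=(1.0, 0.5), sigma=errs,
                           absolute_sigma=True)
    resid = (snrs - model(mus, *popt)) / errs
    dof = max(len(mus) - 2, 1)
    return SNRFit(eta=float(popt[0]), gamma=float(popt[1]),
                  eta_err=float(np.sqrt(pcov[0, 0])),
                  gamma_err=float(np.sqrt(pcov[1, 1])),
                  chi2_reduced=float(np.sum(resid**2) / dof))


@dataclass
class EnergyResponseFit:
    mu_e_cm2_vs: float
    sigma_e_kev: float
    t_drift_s: float
    errors: tuple[float, float, float]
    chi2_reduced: float


def _path_a_model(energy_bins_kev, photon_energy_kev, mu_e, sigma_e, t_drift,
                  geometry: DetectorGeometry, dr_um=1.0, spacing_um=1.0):
    """Path-A pulse-height model evaluated at bin centers (unit area)."""
    params = TransportParams(mu_e_cm2_vs=mu_e,
                             thickness_um=geometry.thickness_um,
                             bias_v=900.0)
    kern = compute_kernel(photon_energy_kev, params, t_end=t_drift,
                          dr_um=dr_um, spacing_um=spacing_um)
    # evaluate on a full-support grid (normalization is global), then
    # sample at the requested bin centers
    grid = np.arange(-8.0, photon_energy_kev + 4.0 * max(sigma_e, 1.0), 0.5)
    _, dens = path_response(photon_energy_kev, kern, geometry.aperture_um,
                            sigma_e_kev=sigma_e, energy_grid_kev=grid)
    return np.interp(energy_bins_kev, grid, dens)


def fit_energy_response(energy_kev: np.ndarray, counts: np.ndarray,
                        photon_energy_kev: float, geometry: DetectorGeometry,
                        fit_window_kev: tuple[float, float] = (40.0, np.inf),
                        p0=(1000.0, 1.0, 5e-8)) -> EnergyResponseFit:
    """Calibrate (mu_e, sigma_e, t_drift) against a measured spectrum.

    The amplitude is profiled out linearly at each parameter set; drift
    time is a free parameter (not constrained to L^2/(mu V)).  Parameter
    errors come from the curve_fit covariance.

    Note an exact degeneracy: the transport equation is invariant under
    (mu_e, t) -> (c mu_e, t/c), so a single pulse-height spectrum
    identifies only the product mu_e * t_drift (the diffusion/repulsion
    "budget") together with sigma_e; the individual factors returned lie
    on that ridge.  Constrain one of the two externally when absolute
    values are needed.
    """
    if np.any(np.diff(energy_kev) <= 0):
        raise ValueError("energy grid must be strictly increasing")
    lo, hi = fit_window_kev
    sel = (energy_kev >= lo) & (energy_kev <= hi) & (counts > 0)
    if sel.sum() < 5:
        raise ValueError("fit window contains too few populated bins")
    e_fit, c_fit = energy_kev[sel], counts[sel].astype(float)
    sigma = np.sqrt(np.maximum(c_fit, 1.0))

    def model(e, mu_e, sigma_e, t_drift_ns):
        shape = _path_a_model(e, photon_energy_kev, abs(mu_e), abs(sigma_e),
                              abs(t_drift_ns) * 1e-9, geometry)
        amp = np.sum(c_fit * shape / sigma**2) / np.sum(shape**2 / sigma**2)
        return amp * shape

    p0_ns = (p0[0], p0[1], p0[2] * 1e9)
    popt, pcov = curve_fit(model, e_fit, c_fit, p0=p0_ns, sigma=sigma,
                           absolute_sigma=True, method="trf",
                           diff_step=(0.05, 0.05, 0.05), max_nfev=60)
    resid = (c_fit - model(e_fit, *popt)) / sigma
    dof = max(len(e_fit) - 3, 1)
    errs = np.sqrt(np.diag(pcov))
    return EnergyResponseFit(mu_e_cm2_vs=float(abs(popt[0])),
                             sigma_e_kev=float(abs(popt[1])),
                             t_drift_s=float(abs(popt[2]) * 1e-9),
                             errors=(float(errs[0]), float(errs[1]),
                                     float(errs[2] * 1e-9)),
                             chi2_reduced=float(np.sum(resid**2) / dof))


def synthetic_pulse_height_spectrum(photon_energy_kev: float,
                                    geometry: DetectorGeometry,
                                    mu_e_cm2_vs: float = 1000.0,
                                    sigma_e_kev: float = 0.6,
                                    t_drift_s: float = 1e-7,
                                    total_counts: int = 200_000,
                                    bin_width_kev: float = 0.5,
                                    seed: int = 0):
    """Synthetic stand-in for a bench pulse-height measurement.

    Draws Poisson counts in fixed-width energy bins from the path-A
    response model at the given transport parameters.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(5.0, photon_energy_kev + 6.0, bin_width_kev)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shape = _path_a_model(centers, photon_energy_kev, mu_e_cm2_vs,
                          sigma_e_kev, t_drift_s, geometry)
    shape = np.maximum(shape, 0.0)
    expect = total_counts * shape / shape.sum()
    return centers, rng.poisson(expect)
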