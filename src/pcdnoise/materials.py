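"""Converter materials: attenuation, quantum efficiency, interaction mixing.

The converter model is a two-element compound semiconductor (CdTe at CZT
bulk density by default).  Mass attenuation coefficients are read from the
plain-text tables shipped under :mod:`pcdnoise.data` and interpolated
log-log.  "Interacting" cross section means photoelectric + incoherent:
coherent scatter deposits no energy and is excluded from the quantum
efficiency, while beam transmission through filters uses the full total.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.interpolate import interp1d
from scipy.optimize import brentq

__all__ = [
    "AttenuationTable",
    "ElementK",
    "Material",
    "InteractionFractions",
    "load_attenuation",
    "load_material",
    "quantum_efficiency",
    "thickness_for_qe",
    "interaction_fractions",
    "air_mu_en",
]


def _data_text(name: str) -> str:
    return resources.files("pcdnoise.data").joinpath(name).read_text()


@dataclass(frozen=True)
class AttenuationTable:
    """Log-log interpolated mass attenuation partials [cm^2/g]."""

    energy_kev: np.ndarray
    photo: np.ndarray
    incoherent: np.ndarray
    coherent: np.ndarray

    def __post_init__(self):
        loge = np.log(self.energy_kev)
        for name in ("photo", "incoherent", "coherent", "total", "interacting"):
            vals = getattr(self, name)
            object.__setattr__(
                self, f"_f_{name}",
                interp1d(loge, np.log(np.maximum(vals, 1e-300)),
                         kind="linear", bounds_error=True),
            )

    @property
    def total(self) -> np.ndarray:
        return self.photo + self.incoherent + self.coherent

    @property
    def interacting(self) -> np.ndarray:
        return self.photo + self.incoherent

    def _eval(self, which: str, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energy_kev[0] - 1e-9) or np.any(e > self.energy_kev[-1] + 1e-9):
            raise ValueError(
                f"energy {e} keV outside attenuation table range "
                f"[{self.energy_kev[0]}, {self.energy_kev[-1]}]")
        e = np.clip(e, self.energy_kev[0], self.energy_kev[-1])
        out = np.exp(getattr(self, f"_f_{which}")(np.log(e)))
        return float(out) if np.isscalar(energy_kev) else out

    def mu_total(self, energy_kev):
        """Total mass attenuation (with coherent) [cm^2/g]."""
        return self._eval("total", energy_kev)

    def mu_interacting(self, energy_kev):
        """Photoelectric + incoherent mass attenuation [cm^2/g]."""
        return self._eval("interacting", energy_kev)

    def mu_photo(self, energy_kev):
        return self._eval("photo", energy_kev)

    def mu_incoherent(self, energy_kev):
        return self._eval("incoherent", energy_kev)


@functools.lru_cache(maxsize=None)
def load_attenuation(name: str) -> AttenuationTable:
    """Load an attenuation table by short name (cd, te, zn, al, w, bone_cortical)."""
    fname = {"bone_cortical": "attenuation_bone_cortical.csv"}.get(
        name, f"attenuation_{name}.csv")
    rows = [
        [float(x) for x in line.split(",")]
        for line in _data_text(fname).splitlines()
        if line and not line.startswith("#") and not line.startswith("energy")
    ]
    arr = np.array(rows)
    return AttenuationTable(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


@dataclass(frozen=True)
class ElementK:
    """Per-element K-shell bookkeeping for the fluorescence cascade."""

    symbol: str
    mass_fraction: float
    k_edge_kev: float
    fluorescence_yield: float  # omega_K
    mean_k_xray_kev: float     # intensity-weighted Kalpha/Kbeta mean
    k_participation: float     # P_K: fraction of PE events involving the K shell

    @property
    def table(self) -> AttenuationTable:
        return load_attenuation(self.symbol)


@dataclass(frozen=True)
class Material:
    name: str
    density_g_cm3: float
    w_pair_kev: float
    fano: float
    elements: tuple[ElementK, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.elements:
            total = sum(e.mass_fraction for e in self.elements)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mass fractions sum to {total}, not 1")

    def mu_interacting(self, energy_kev):
        """Linear interacting attenuation coefficient [1/cm]."""
        mu = sum(e.mass_fraction * e.table.mu_interacting(energy_kev)
                 for e in self.elements)
        return mu * self.density_g_cm3

    def mu_total(self, energy_kev):
        """Linear total attenuation coefficient (with coherent) [1/cm]."""
        mu = sum(e.mass_fraction * e.table.mu_total(energy_kev)
                 for e in self.elements)
        return mu * self.density_g_cm3

    def element(self, symbol: str) -> ElementK:
        for e in self.elements:
            if e.symbol == symbol:
                return e
        raise KeyError(f"element {symbol!r} not in material {self.name}")


def _k_participation(table: AttenuationTable, edge_kev: float) -> float:
    """P_K from the photoelectric jump at the K edge."""
    below = table.mu_photo(edge_kev - 0.005)
    above = table.mu_photo(edge_kev + 0.005)
    return float(1.0 - below / above)


@functools.lru_cache(maxsize=None)
def load_material(name: str = "cdte", zn_mass_fraction: float = 0.0) -> Material:
    """Load a converter material.

    ``zn_mass_fraction`` > 0 folds a Zn admixture into the Cd channel
    (same attenuation bookkeeping element-wise, but Zn K x rays are
    neglected: their yield and energy are low).
    """
    cfg = yaml.safe_load(_data_text("materials.yaml"))[name]
    elements = []
    for el in cfg.get("elements", []):
        table = load_attenuation(el["symbol"])
        elements.append(ElementK(
            symbol=el["symbol"],
            mass_fraction=el["mass_fraction"],
            k_edge_kev=el["k_edge_kev"],
            fluorescence_yield=el["fluorescence_yield"],
            mean_k_xray_kev=el["mean_k_xray_kev"],
            k_participation=_k_participation(table, el["k_edge_kev"]),
        ))
    if zn_mass_fraction > 0.0 and elements:
        # renormalize Cd/Te and treat Zn as extra Cd-channel mass
        scale = 1.0 - zn_mass_fraction
        elements = [
            ElementK(e.symbol, e.mass_fraction * scale + (zn_mass_fraction if e.symbol == "cd" else 0.0),
                     e.k_edge_kev, e.fluorescence_yield, e.mean_k_xray_kev,
                     e.k_participation)
            for e in elements
        ]
    return Material(
        name=name,
        density_g_cm3=cfg["density_g_cm3"],
        w_pair_kev=cfg.get("w_pair_kev", 0.005),
        fano=cfg.get("fano", 1.0),
        elements=tuple(elements),
    )


@dataclass(frozen=True)
class InteractionFractions:
    """Probabilities conditioned on one interaction at one energy."""

    alpha: float      # quantum efficiency (context-dependent thickness)
    nu: dict          # element symbol -> P(interaction with element | interaction)
    xi_pe: dict       # element symbol -> P(photoelectric | interaction with element)

    def __post_init__(self):
        total = sum(self.nu.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("element interaction probabilities must sum to 1")


def quantum_efficiency(material: Material, thickness_um: float, spectrum_or_energy):
    """Interaction probability 1 - exp(-mu L), fluence-averaged for a spectrum.

    Follows the conventional narrow-beam definition using the total mass
    attenuation coefficient (including coherent scatter, which removes
    ~2% of photons from the beam in CdTe at diagnostic energies).
    """
    if thickness_um < 0:
        raise ValueError("thickness must be >= 0")
    length_cm = thickness_um * 1e-4
    if hasattr(spectrum_or_energy, "fluence"):
        sp = spectrum_or_energy
        if sp.fluence.sum() <= 0:
            raise ValueError("degenerate spectrum: all-zero fluence")
        qe = 1.0 - np.exp(-material.mu_total(sp.energies_kev) * length_cm)
        return float(np.sum(sp.fluence * qe) / np.sum(sp.fluence))
    return 1.0 - np.exp(-material.mu_total(spectrum_or_energy) * length_cm)


def thickness_for_qe(material: Material, spectrum, target_qe: float,
                     bracket_um: tuple[float, float] = (1.0, 20000.0)) -> float:
    """Thickness [um] whose spectrum-averaged QE equals ``target_qe``."""
    if not 0.0 < target_qe < 1.0:
        raise ValueError("target QE must lie strictly between 0 and 1")

    def f(length):
        return quantum_efficiency(material, length, spectrum) - target_qe

    lo, hi = bracket_um
    if f(lo) * f(hi) > 0:
        raise RuntimeError("target quantum efficiency unreachable within bracket")
    return float(brentq(f, lo, hi, xtol=0.1))


def interaction_fractions(material: Material, energy_kev: float) -> InteractionFractions:
    """Element and interaction-type mixing at one energy.

    nu_Z is proportional to the mass-fraction-weighted interacting cross
    section of element Z; xi_PE is the photoelectric fraction of that
    element's interacting cross section.
    """
    nu = {}
    xi = {}
    for e in material.elements:
        inter = e.mass_fraction * e.table.mu_interacting(energy_kev)
        nu[e.symbol] = inter
        xi[e.symbol] = (e.mass_fraction * e.table.mu_photo(energy_kev)) / inter
    total = sum(nu.values())
    nu = {k: v / total for k, v in nu.items()}
    return InteractionFractions(alpha=float("nan"), nu=nu, xi_pe=xi)


@functools.lru_cache(maxsize=1)
def air_mu_en() -> interp1d:
    """Log-log interpolator of the air mass energy-absorption coefficient."""
    rows = [
        [float(x) for x in line.split(",")]
        for line in _data_text("air_mass_energy_absorption.csv").splitlines()
        if line and not line.startswith("#") and not line.startswith("energy")
    ]
    arr = np.array(rows)
    f = interp1d(np.log(arr[:, 0]), np.log(arr[:, 1]), kind="linear",
                 bounds_error=False, fill_value="extrapolate")
    return lambda e: np.exp(f(np.log(np.asarray(e, dtype=float))))
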