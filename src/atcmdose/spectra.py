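"""X-ray spectra, beam quality (HVL) and the beam-shaping (bowtie) filter.

The tube spectrum is a filtered Kramers bremsstrahlung continuum: relative
fluence proportional to (kVp - E)/E on 1 keV bins, hardened by the stated
aluminium filtration. Characteristic lines are omitted; any smooth continuum
tuned to a measured half-value layer carries the same beam-quality
information at the accuracy this simulation needs, and ``tune_filtration_to_hvl``
performs exactly that tuning.

Half-value layer is defined with air-kerma weighting, matching how an
ionisation chamber measures it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialTable

__all__ = [
    "Spectrum",
    "BowtieFilter",
    "build_spectrum",
    "compute_hvl",
    "tune_filtration_to_hvl",
    "bowtie_transmission",
]


class InvalidParameterError(ValueError):
    pass


class UnachievableTargetError(ValueError):
    pass


@dataclass
class Spectrum:
    """Relative photon fluence on 1 keV bins from 10 keV to the tube potential."""

    kvp: float
    energies_kev: np.ndarray
    fluence: np.ndarray  # unitless, sums to 1
    filtration_mm_al: float = 0.0

    def __post_init__(self):
        self.energies_kev = np.asarray(self.energies_kev, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if np.any(self.fluence < 0):
            raise InvalidParameterError("fluence must be non-negative")
        if np.any(self.fluence[self.energies_kev > self.kvp] > 0):
            raise InvalidParameterError("fluence above kVp must be zero")
        s = self.fluence.sum()
        if abs(s - 1.0) > 1e-9:
            raise InvalidParameterError("fluence must be normalised")

    @classmethod
    def monoenergetic(cls, energy_kev: float) -> "Spectrum":
        """Single-line pseudo-spectrum, used by analytic oracles."""
        return cls(kvp=energy_kev, energies_kev=np.array([energy_kev]),
                   fluence=np.array([1.0]))

    def mean_energy(self) -> float:
        return float(np.sum(self.energies_kev * self.fluence))

    def kerma_weights(self, materials: MaterialTable) -> np.ndarray:
        """Per-bin air-kerma contribution weights (unnormalised)."""
        muen = materials.coefficient("air", "mu_en", self.energies_kev)
        return self.fluence * self.energies_kev * np.atleast_1d(muen)

    def effective_energy_kev(self, materials: MaterialTable) -> float:
        """Kerma-weighted mean energy; the single energy used for ray marching."""
        w = self.kerma_weights(materials)
        return float(np.sum(self.energies_kev * w) / np.sum(w))

    def attenuated(self, material: str, thickness_mm: float,
                   materials: MaterialTable) -> "Spectrum":
        """Harden through a slab, renormalising the fluence."""
        mu = materials.mu_linear(material, "mu_total", self.energies_kev)
        f = self.fluence * np.exp(-np.atleast_1d(mu) * thickness_mm)
        return Spectrum(self.kvp, self.energies_kev, f / f.sum(),
                        self.filtration_mm_al)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"energy_keV": self.energies_kev, "value": self.fluence}
                     ).to_csv(path, index=False)


def build_spectrum(kvp: float, added_filtration_mm_al: float = 0.0,
                   materials: MaterialTable | None = None) -> Spectrum:
    """Kramers-form bremsstrahlung at `kvp`, filtered by aluminium.

    Parameters
    ----------
    kvp : tube potential in kV, 60-150.
    added_filtration_mm_al : aluminium filtration thickness, mm.
    materials : table providing aluminium attenuation (default packaged table).
    """
    if not (60.0 <= kvp <= 150.0):
        raise InvalidParameterError(f"kvp={kvp} outside [60, 150]")
    if added_filtration_mm_al < 0:
        raise InvalidParameterError("filtration must be >= 0")
    if materials is None:
        from .materials import load_default_materials

        materials = load_default_materials()
    energies = np.arange(10.0, np.floor(kvp) + 1.0)
    fluence = np.clip(kvp - energies, 0.0, None) / energies
    if added_filtration_mm_al > 0:
        mu = materials.mu_linear("aluminium", "mu_total", energies)
        fluence = fluence * np.exp(-np.atleast_1d(mu) * added_filtration_mm_al)
    total = fluence.sum()
    if total <= 0:
        raise InvalidParameterError("spectrum empty after filtration")
    return Spectrum(kvp, energies, fluence / total, added_filtration_mm_al)


def _kerma_transmission(spectrum: Spectrum, materials: MaterialTable,
                        x_mm: float) -> float:
    mu = np.atleast_1d(materials.mu_linear("aluminium", "mu_total",
                                           spectrum.energies_kev))
    w = spectrum.kerma_weights(materials)
    return float(np.sum(w * np.exp(-mu * x_mm)) / np.sum(w))


def compute_hvl(spectrum: Spectrum, materials: MaterialTable) -> float:
    """Aluminium half-value layer (mm) of a spectrum, kerma-weighted.

    Solves K(x)/K(0) = 1/2 by bisection to |K/K0 - 0.5| < 1e-6.
    """
    lo, hi = 0.0, 1.0
    it = 0
    while _kerma_transmission(spectrum, materials, hi) > 0.5:
        hi *= 2.0
        it += 1
        if it > 60:
            raise ArithmeticError("HVL bracket search failed")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        t = _kerma_transmission(spectrum, materials, mid)
        if abs(t - 0.5) < 1e-6:
            return mid
        if t > 0.5:
            lo = mid
        else:
            hi = mid
    raise ArithmeticError("HVL bisection did not converge in 200 iterations")


def tune_filtration_to_hvl(kvp: float, target_hvl_mm: float,
                           materials: MaterialTable | None = None,
                           max_filtration_mm: float = 20.0) -> Spectrum:
    """Find the aluminium filtration whose spectrum has the target HVL.

    HVL is strictly increasing in filtration, so bisection on [0, 20] mm Al
    converges; the returned spectrum satisfies |HVL - target| < 0.01 mm.
    """
    if materials is None:
        from .materials import load_default_materials

        materials = load_default_materials()
    lo, hi = 0.0, max_filtration_mm
    h_lo = compute_hvl(build_spectrum(kvp, lo, materials), materials)
    h_hi = compute_hvl(build_spectrum(kvp, hi, materials), materials)
    if not (h_lo <= target_hvl_mm <= h_hi):
        raise UnachievableTargetError(
            f"target HVL {target_hvl_mm} mm outside achievable "
            f"[{h_lo:.3f}, {h_hi:.3f}] mm for filtration in [0, {max_filtration_mm}] mm Al"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        h = compute_hvl(build_spectrum(kvp, mid, materials), materials)
        if abs(h - target_hvl_mm) < 0.005:
            break
        if h < target_hvl_mm:
            lo = mid
        else:
            hi = mid
    return build_spectrum(kvp, 0.5 * (lo + hi), materials)


@dataclass
class BowtieFilter:
    """Beam-shaping filter: thickness as a function of fan angle.

    Thickness is minimal on the central ray and non-decreasing towards the fan
    periphery, shaping the fluence to the patient's thickness profile.
    """

    gamma_max_rad: float
    t_max_mm: float
    material: str = "aluminium"
    t_min_mm: float = 0.0

    def thickness_mm(self, gamma_rad):
        g = np.asarray(gamma_rad, dtype=float)
        t = self.t_min_mm + self.t_max_mm * (g / self.gamma_max_rad) ** 2
        return t if t.ndim else float(t)


class OutOfFanError(ValueError):
    pass


def bowtie_transmission(bowtie: BowtieFilter, gamma_rad, energy_kev,
                        materials: MaterialTable):
    """Photon survival probability through the bowtie at fan angle gamma."""
    g = np.asarray(gamma_rad, dtype=float)
    if np.any(np.abs(g) > bowtie.gamma_max_rad * (1 + 1e-12)):
        raise OutOfFanError(f"|gamma| exceeds fan half-angle {bowtie.gamma_max_rad}")
    mu = materials.mu_linear(bowtie.material, "mu_total", energy_kev)
    out = np.exp(-np.asarray(mu) * bowtie.thickness_mm(g))
    return out if np.ndim(out) else float(out)
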