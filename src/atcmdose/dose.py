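"""Helical CT Monte Carlo dose engine.

Simulates a helical acquisition over a voxel phantom: the source follows a
helix whose table increment per rotation is the beam collimation multiplied
by the pitch, photon emission times are importance-sampled proportional to
the tube-current profile, the bowtie filter is applied as an emission
weight, and transport uses delta tracking with the kerma approximation (see
:mod:`atcmdose._transport`). Absolute dose is anchored to a free-in-air air
kerma calibration at the isocentre: the nominal scanner output in mGy per
100 mAs fixes how many real photons one simulated photon represents.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._transport import (KEV_PER_G_TO_MGY, N_EBINS, run_transport,
                         sample_kn_cosines)
from .atcm import TubeCurrentProfile
from .materials import MaterialTable, load_default_materials
from .phantoms import MATERIAL_NAMES, VoxelPhantom
from .scanner import ScannerModel
from .spectra import Spectrum, bowtie_transmission

__all__ = ["ScanProtocol", "DoseMap", "simulate_scan", "free_in_air_kerma",
           "calibrate_output", "save_dosemap", "load_dosemap",
           "sample_compton_cosines"]

DIRECTIONS = ("caudocranial", "craniocaudal")
_EGRID = np.arange(10.0, 10.0 + N_EBINS)  # 10..150 keV bin centres


class CoverageError(ValueError):
    pass


@dataclass
class ScanProtocol:
    """One helical acquisition: beam, trajectory and tube-current source."""

    kvp: float
    collimation_mm: float
    pitch: float
    rotation_time_s: float
    direction: str
    start_z_mm: float
    end_z_mm: float
    offset_mm: tuple[float, float] = (0.0, 0.0)
    profile: TubeCurrentProfile | None = None
    sid_mm: float = 600.0
    localiser_descriptor: str = ""

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown scan direction {self.direction!r}")
        if self.start_z_mm == self.end_z_mm:
            raise ValueError("scan range must be non-empty")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")
        if abs(self.offset_mm[0]) > 100 or abs(self.offset_mm[1]) > 100:
            raise ValueError("off-centring beyond the gantry bore (100 mm)")

    @property
    def table_increment_mm(self) -> float:
        return self.collimation_mm * self.pitch

    @classmethod
    def for_phantom(cls, phantom: VoxelPhantom, scanner: ScannerModel,
                    kvp: float, direction: str = "caudocranial",
                    offset_mm=(0.0, 0.0), profile=None) -> "ScanProtocol":
        """Scan from lung base to apex (or reversed) at the given kVp."""
        lo, hi = phantom.z_base_mm, phantom.z_apex_mm
        start, end = (lo, hi) if direction == "caudocranial" else (hi, lo)
        return cls(kvp=kvp, collimation_mm=scanner.collimation_mm,
                   pitch=scanner.pitch, rotation_time_s=scanner.rotation_time_s,
                   direction=direction, start_z_mm=start, end_z_mm=end,
                   offset_mm=tuple(offset_mm), profile=profile,
                   sid_mm=scanner.sid_mm)


@dataclass
class DoseMap:
    """3D absorbed dose in mGy on the phantom grid, with MC provenance."""

    dose_mgy: np.ndarray
    n_photons: int
    seed: int
    calibration_mgy_per_mas: float
    total_mas: float
    emitted_kev: float = 0.0
    deposited_kev: float = 0.0
    meta: dict = field(default_factory=dict)

    def scaled(self, factor: float) -> "DoseMap":
        out = DoseMap(self.dose_mgy * factor, self.n_photons, self.seed,
                      self.calibration_mgy_per_mas, self.total_mas * factor,
                      self.emitted_kev, self.deposited_kev, dict(self.meta))
        return out


def _mu_tables(materials: MaterialTable):
    """(n_mat, 141) photoelectric and incoherent mass coefficients."""
    mu_pe = materials.lookup_grid("mu_pe", _EGRID, MATERIAL_NAMES)
    mu_in = materials.lookup_grid("mu_incoh", _EGRID, MATERIAL_NAMES)
    return np.ascontiguousarray(mu_pe), np.ascontiguousarray(mu_in)


def _majorant(phantom: VoxelPhantom, mu_pe, mu_in) -> np.ndarray:
    maj = np.zeros(N_EBINS)
    for mid in np.unique(phantom.material_id):
        rho_max = phantom.density[phantom.material_id == mid].max()
        maj = np.maximum(maj, (mu_pe[mid] + mu_in[mid]) * rho_max * 0.1)
    return maj


def _spectrum_sampling(spectrum: Spectrum):
    e = np.ascontiguousarray(spectrum.energies_kev, dtype=np.float64)
    cdf = np.cumsum(spectrum.fluence)
    cdf /= cdf[-1]
    return e, np.ascontiguousarray(cdf)


def _bowtie_lookup(scanner: ScannerModel | None, materials: MaterialTable,
                   gamma_max: float, n_gamma: int = 64) -> np.ndarray:
    if scanner is None or scanner.bowtie is None:
        return np.ones((n_gamma, N_EBINS))
    gammas = np.linspace(0.0, min(gamma_max, scanner.bowtie.gamma_max_rad),
                         n_gamma)
    out = np.empty((n_gamma, N_EBINS))
    for i, g in enumerate(gammas):
        out[i] = bowtie_transmission(scanner.bowtie, g, _EGRID, materials)
    return out


def _helix_samples(protocol: ScanProtocol, n_t: int, centre_xy,
                   start_angle_rad: float = 0.0):
    """Discretised source trajectory with z-overscan of half a collimation."""
    z0, z1 = protocol.start_z_mm, protocol.end_z_mm
    direction = 1.0 if z1 > z0 else -1.0
    over = 0.5 * protocol.collimation_mm
    z_start = z0 - direction * over
    z_end = z1 + direction * over
    n_rot = abs(z_end - z_start) / protocol.table_increment_mm
    frac = (np.arange(n_t) + 0.5) / n_t
    z_t = z_start + (z_end - z_start) * frac
    # gantry angle 0 puts the source at the PA position (below the patient)
    theta = start_angle_rad + 2.0 * np.pi * n_rot * frac
    ax = centre_xy[0] - protocol.offset_mm[0]
    ay = centre_xy[1] - protocol.offset_mm[1]
    duration_s = n_rot * protocol.rotation_time_s
    return z_t, theta, ax, ay, duration_s


def simulate_scan(phantom: VoxelPhantom, protocol: ScanProtocol,
                  scanner: ScannerModel, n_photons: int, seed: int,
                  materials: MaterialTable | None = None,
                  scatter: bool = True, n_time_samples: int = 2048,
                  calibration: float | None = None) -> DoseMap:
    """Run the helical MC simulation and return an absolute dose map.

    Emission times are importance-sampled proportional to the tube-current
    profile, so the tallied per-photon dose already carries the modulation
    weighting; the absolute scale is (photons per mAs from the air-kerma
    calibration) x (total mAs of the scan).
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if materials is None:
        materials = load_default_materials()
    profile = protocol.profile
    if profile is None:
        raise CoverageError("protocol has no tube-current profile")
    # profiles are stored z-ascending; require coverage of the scan range
    lo = min(protocol.start_z_mm, protocol.end_z_mm)
    hi = max(protocol.start_z_mm, protocol.end_z_mm)
    if profile.z_mm[0] > lo or profile.z_mm[-1] < hi:
        raise CoverageError("tube-current profile does not cover the scan range")

    z_t, theta_t, ax, ay, duration_s = _helix_samples(
        protocol, n_time_samples, phantom.centre_xy_mm)
    ma_t = profile.interp(z_t)
    if np.any(ma_t <= 0):
        raise CoverageError("profile non-positive inside the scan range")
    cdf = np.cumsum(ma_t)
    total_mas = float(ma_t.mean()) * duration_s
    cdf /= cdf[-1]

    spectrum = scanner.spectrum(protocol.kvp, materials)
    spec_e, spec_cdf = _spectrum_sampling(spectrum)
    gamma_max = scanner.fan_half_angle_rad
    bowtie = _bowtie_lookup(scanner, materials, gamma_max)
    mu_pe, mu_in = _mu_tables(materials)
    majorant = np.maximum(_majorant(phantom, mu_pe, mu_in), 1e-12)

    dz, dy, dx = phantom.spacing_mm
    edep = np.zeros(phantom.shape)
    emitted, deposited = run_transport(
        int(seed) % (2**31), int(n_photons),
        phantom.density, phantom.material_id,
        dz, dy, dx,
        ax, ay, theta_t, z_t, cdf, True,
        gamma_max, 0.5 * protocol.collimation_mm, protocol.sid_mm,
        spec_e, spec_cdf, bowtie,
        mu_pe, mu_in, majorant, scatter, edep)

    if calibration is None:
        calibration = calibrate_output(scanner, protocol.kvp,
                                       materials=materials)
    mass_g = phantom.density * phantom.voxel_volume_cm3
    with np.errstate(divide="ignore", invalid="ignore"):
        dose_per_photon = np.where(
            mass_g > 0, edep * KEV_PER_G_TO_MGY / np.maximum(mass_g, 1e-300), 0.0)
    dose = dose_per_photon / n_photons * calibration * total_mas
    return DoseMap(dose_mgy=dose, n_photons=n_photons, seed=int(seed),
                   calibration_mgy_per_mas=float(calibration),
                   total_mas=total_mas, emitted_kev=float(emitted),
                   deposited_kev=float(deposited),
                   meta=dict(kvp=protocol.kvp, direction=protocol.direction,
                             offset_mm=list(protocol.offset_mm)))


# ---------------------------------------------------------------------------
# free-in-air kerma and output calibration


def free_in_air_kerma(scanner: ScannerModel, kvp: float,
                      distance_from_source_mm: float | None = None,
                      n_photons: int = 200_000, seed: int = 0,
                      materials: MaterialTable | None = None,
                      scoring_radius_mm: float = 10.0) -> float:
    """Air kerma per emitted photon (mGy) at a point on the central axis.

    No phantom is present; photons carry the bowtie transmission weight
    (the scoring point on the central axis sees the gamma ~ 0 part of the
    filter). Kerma is scored with a perpendicular disc fluence estimator.
    """
    if distance_from_source_mm is None:
        distance_from_source_mm = scanner.sid_mm
    if distance_from_source_mm <= 0:
        raise ValueError("distance must be > 0")
    if n_photons == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    materials = materials or load_default_materials()
    spectrum = scanner.spectrum(kvp, materials)
    spec_e, spec_cdf = _spectrum_sampling(spectrum)
    gamma_max = scanner.fan_half_angle_rad
    coll_half = 0.5 * scanner.collimation_mm
    # beam cross-section at the scoring distance must contain the disc
    l_ratio = distance_from_source_mm / scanner.sid_mm
    if (distance_from_source_mm * np.tan(gamma_max) < scoring_radius_mm
            or coll_half * l_ratio < scoring_radius_mm):
        raise ValueError("scoring volume outside the collimated beam")

    e = spec_e[np.searchsorted(spec_cdf, rng.random(n_photons)).clip(0, len(spec_e) - 1)]
    gamma = rng.uniform(-gamma_max, gamma_max, n_photons)
    zeta = rng.uniform(-coll_half, coll_half, n_photons)
    bowtie = _bowtie_lookup(scanner, materials, gamma_max)
    gi = np.abs(gamma) / gamma_max * (bowtie.shape[0] - 1)
    i0 = np.floor(gi).astype(int).clip(0, bowtie.shape[0] - 2)
    fr = gi - i0
    ie = (e - 10.0).astype(int).clip(0, N_EBINS - 1)
    w = bowtie[i0, ie] * (1 - fr) + bowtie[i0 + 1, ie] * fr

    # hit test on a disc perpendicular to the central axis
    r_fan = distance_from_source_mm * np.tan(np.abs(gamma))
    r_cone = np.abs(zeta) * l_ratio
    hits = (r_fan**2 + r_cone**2) <= scoring_radius_mm**2
    muen = materials.coefficient("air", "mu_en", e)  # cm^2/g
    area_cm2 = np.pi * (scoring_radius_mm / 10.0) ** 2
    kerma = np.sum(w[hits] * e[hits] * np.atleast_1d(muen)[hits]) \
        * KEV_PER_G_TO_MGY / area_cm2 / n_photons
    return float(kerma)


_CALIBRATION_CACHE: dict = {}


def calibrate_output(scanner: ScannerModel, kvp: float,
                     materials: MaterialTable | None = None,
                     n_photons: int = 400_000, seed: int = 12345) -> float:
    """Photons-per-mAs scale: nominal kerma per mAs / simulated kerma per photon.

    Multiplying a per-photon dose tally by this factor and by the scan's
    total mAs yields absolute dose anchored to the scanner's configured
    free-in-air output at the isocentre.
    """
    key = (scanner.name, scanner.sid_mm, scanner.collimation_mm,
           scanner.bowtie.t_max_mm, kvp, scanner.nominal_output(kvp),
           n_photons, seed)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    nominal_per_mas = scanner.nominal_output(kvp) / 100.0  # mGy/mAs
    k_per_photon = free_in_air_kerma(scanner, kvp, scanner.sid_mm,
                                     n_photons=n_photons, seed=seed,
                                     materials=materials)
    if k_per_photon <= 0:
        raise ArithmeticError("free-in-air kerma simulation returned zero")
    factor = nominal_per_mas / k_per_photon
    _CALIBRATION_CACHE[key] = factor
    return factor


def sample_compton_cosines(energy_kev: float, n: int, seed: int) -> np.ndarray:
    """Klein-Nishina scattering-angle cosines (thin wrapper over the kernel)."""
    return sample_kn_cosines(float(energy_kev), int(n), int(seed) % (2**31))


# ---------------------------------------------------------------------------
# fixed-beam oracle mode


def simulate_fixed_beam(phantom: VoxelPhantom, spectrum: Spectrum,
                        angle_rad: float, n_photons: int, seed: int,
                        sid_mm: float = 600.0, gamma_max_rad: float = 0.05,
                        coll_half_mm: float = 20.0, z_src_mm: float | None = None,
                        scatter: bool = False,
                        materials: MaterialTable | None = None):
    """Stationary narrow beam through the phantom (analytic-oracle mode).

    Returns the raw energy deposition grid in keV per emitted photon plus
    the (emitted, deposited) weighted totals. No bowtie, no calibration.
    """
    materials = materials or load_default_materials()
    cx, cy = phantom.centre_xy_mm
    if z_src_mm is None:
        z_src_mm = float(phantom.z_mm.mean())
    theta = np.array([angle_rad])
    sz = np.array([z_src_mm])
    cdf = np.array([1.0])
    spec_e, spec_cdf = _spectrum_sampling(spectrum)
    mu_pe, mu_in = _mu_tables(materials)
    majorant = np.maximum(_majorant(phantom, mu_pe, mu_in), 1e-12)
    bowtie = np.ones((2, N_EBINS))
    dz, dy, dx = phantom.spacing_mm
    edep = np.zeros(phantom.shape)
    emitted, deposited = run_transport(
        int(seed) % (2**31), int(n_photons),
        phantom.density, phantom.material_id,
        dz, dy, dx, cx, cy, theta, sz, cdf, False,
        gamma_max_rad, coll_half_mm, sid_mm,
        spec_e, spec_cdf, bowtie, mu_pe, mu_in, majorant,
        scatter, edep)
    return edep / n_photons, float(emitted), float(deposited)


# ---------------------------------------------------------------------------
# persistence


def save_dosemap(dosemap: DoseMap, path) -> None:
    import nibabel as nib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(dosemap.dose_mgy.transpose(2, 1, 0), np.eye(4))
    nib.save(img, str(path / "dose.nii.gz"))
    sidecar = dict(n_photons=dosemap.n_photons, seed=dosemap.seed,
                   calibration_mgy_per_mas=dosemap.calibration_mgy_per_mas,
                   total_mas=dosemap.total_mas, emitted_kev=dosemap.emitted_kev,
                   deposited_kev=dosemap.deposited_kev, meta=dosemap.meta)
    (path / "dose.json").write_text(json.dumps(sidecar, indent=2))


def load_dosemap(path) -> DoseMap:
    import nibabel as nib

    path = Path(path)
    sidecar = path / "dose.json"
    if not sidecar.exists():
        raise IOError(f"missing dose sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    vol = path / "dose.nii.gz"
    if not vol.exists():
        raise IOError(f"missing dose volume {vol}")
    arr = np.asanyarray(nib.load(str(vol)).dataobj)
    dose = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    return DoseMap(dose_mgy=dose, n_photons=meta["n_photons"],
                   seed=meta["seed"],
                   calibration_mgy_per_mas=meta["calibration_mgy_per_mas"],
                   total_mas=meta["total_mas"], emitted_kev=meta["emitted_kev"],
                   deposited_kev=meta["deposited_kev"], meta=meta["meta"])
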