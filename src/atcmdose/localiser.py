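"""Localiser (scout/topogram) acquisition as divergent fan-beam projection.

A CT localiser is a 2D radiograph acquired with a stationary tube; the ATCM
derives its per-slice patient-size estimate from it. Because the beam is
divergent, a patient displaced towards the tube appears magnified by
SID/(SID - d) and a patient displaced away appears minified - the geometric
mechanism by which off-centring corrupts the ATCM's size estimate.

The projection is modelled slice-by-slice with a 2D fan per z row (no cone
divergence along z, which is second order for per-z size estimates). Rays
are marched through the voxel grid at a single effective energy (the
kerma-weighted mean energy of the localiser spectrum), and the attenuation
profile is reduced to an apparent body width at isocentre scale plus a mean
water-equivalent path length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialTable
from .phantoms import VoxelPhantom
from .spectra import Spectrum

__all__ = [
    "ProjectionGeometry", "LocaliserImage", "magnification_factor",
    "project_localiser", "water_equivalent_diameter",
]

ANGLE_LABELS = ("PA", "AP", "LAT_left", "LAT_right")

#: rays with more water-equivalent path than this count as "body" (mm)
BODY_WEPL_THRESHOLD_MM = 5.0
DETECTOR_PITCH_MM = 1.0


class GeometryError(ValueError):
    pass


class EmptyProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class ProjectionGeometry:
    """Localiser acquisition geometry.

    ``offset_mm`` is the phantom displacement (dx, dy) relative to the
    rotation axis: dy < 0 means table lowered (patient below isocentre),
    dx > 0 means shifted to the patient's right.
    """

    angle: str
    sid_mm: float = 600.0
    offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.angle not in ANGLE_LABELS:
            raise GeometryError(f"unknown projection angle {self.angle!r}")
        if self.sid_mm <= 0:
            raise GeometryError("source-isocentre distance must be > 0")

    @property
    def displacement_towards_source_mm(self) -> float:
        dx, dy = self.offset_mm
        return {"PA": -dy, "AP": dy, "LAT_left": -dx, "LAT_right": dx}[self.angle]


@dataclass
class LocaliserImage:
    """Per-z size/attenuation estimates reconstructed from one projection."""

    z_mm: np.ndarray
    width_mm: np.ndarray      # apparent body width at isocentre scale
    wepl_mm: np.ndarray       # mean water-equivalent path of body rays
    geometry: ProjectionGeometry
    kvp: float

    def __post_init__(self):
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.width_mm = np.asarray(self.width_mm, dtype=float)
        self.wepl_mm = np.asarray(self.wepl_mm, dtype=float)
        if not (len(self.z_mm) == len(self.width_mm) == len(self.wepl_mm)):
            raise ValueError("z, width and wepl must have equal length")
        if np.any(np.diff(self.z_mm) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(self.width_mm < 0):
            raise ValueError("widths must be >= 0")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"z_mm": self.z_mm, "width_mm": self.width_mm,
                      "wepl_mm": self.wepl_mm}).to_csv(path, index=False)


def magnification_factor(geometry: ProjectionGeometry) -> float:
    """Apparent/true size ratio at isocentre scale: SID/(SID - d).

    d is the displacement of the object centre towards the source along the
    beam axis; a centred object has factor exactly 1.
    """
    d = geometry.displacement_towards_source_mm
    if abs(d) >= geometry.sid_mm:
        raise GeometryError("object displacement reaches the focal spot")
    return geometry.sid_mm / (geometry.sid_mm - d)


def _source_and_axes(geometry: ProjectionGeometry, centre_xy):
    """Source position, beam unit vector and detector unit vector (x, y)."""
    dx, dy = geometry.offset_mm
    ax_x, ax_y = centre_xy[0] - dx, centre_xy[1] - dy  # rotation axis position
    s = geometry.sid_mm
    if geometry.angle == "PA":
        src, beam, det = (ax_x, ax_y - s), (0.0, 1.0), (1.0, 0.0)
    elif geometry.angle == "AP":
        src, beam, det = (ax_x, ax_y + s), (0.0, -1.0), (-1.0, 0.0)
    elif geometry.angle == "LAT_left":
        src, beam, det = (ax_x - s, ax_y), (1.0, 0.0), (0.0, -1.0)
    else:  # LAT_right
        src, beam, det = (ax_x + s, ax_y), (-1.0, 0.0), (0.0, 1.0)
    return np.array(src), np.array(beam), np.array(det)


def project_localiser(phantom: VoxelPhantom, geometry: ProjectionGeometry,
                      spectrum: Spectrum, materials: MaterialTable,
                      fan_half_angle_rad: float = 0.5) -> LocaliserImage:
    """Acquire a localiser image of the phantom.

    For each z row, divergent rays are cast from the point source to a 1 mm
    pitch virtual detector at twice the source-isocentre distance; per-ray
    line integrals of mu(E_eff) are accumulated by ray marching with step at
    most half the minimum voxel spacing.
    """
    e_eff = spectrum.effective_energy_kev(materials)
    mu_water = materials.mu_linear("water", "mu_total", e_eff)  # 1/mm
    mass_mu = np.array([
        materials.coefficient(name, "mu_total", e_eff)
        for name in _material_names()])
    mu3d = mass_mu[phantom.material_id] * phantom.density / 10.0  # 1/mm

    dz, dy, dx = phantom.spacing_mm
    nz, ny, nx = phantom.shape
    src, beam, det = _source_and_axes(geometry, phantom.centre_xy_mm)
    sdd = 2.0 * geometry.sid_mm

    u_half = sdd * np.tan(fan_half_angle_rad)
    n_pix = int(2 * np.floor(u_half / DETECTOR_PITCH_MM) + 1)
    u = (np.arange(n_pix) - (n_pix - 1) / 2) * DETECTOR_PITCH_MM
    # detector points and ray directions (shared across slices)
    pts = src[None, :] + sdd * beam[None, :] + u[:, None] * det[None, :]
    vec = pts - src[None, :]
    t_len = np.linalg.norm(vec, axis=1)
    dirs = vec / t_len[:, None]

    # clip rays to the grid bounding box in (x, y)
    lo = np.array([0.0, 0.0])
    hi = np.array([nx * dx, ny * dy])
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo[None, :] - src[None, :]) / dirs
        t2 = (hi[None, :] - src[None, :]) / dirs
    tmin = np.nanmax(np.minimum(t1, t2), axis=1)
    tmax = np.nanmin(np.maximum(t1, t2), axis=1)
    hit = tmax > tmin
    if not np.any(hit):
        raise EmptyProjectionError("phantom entirely outside the fan")

    step = 0.5 * min(dy, dx)
    span = np.clip(tmax - tmin, 0.0, None)
    n_steps = max(int(np.ceil(span.max() / step)), 1)
    dt = span / n_steps                              # per-ray step <= `step`
    ts = tmin[:, None] + (np.arange(n_steps)[None, :] + 0.5) * dt[:, None]
    px = src[0] + ts * dirs[:, [0]]
    py = src[1] + ts * dirs[:, [1]]
    ix = np.floor(px / dx).astype(np.int64)
    iy = np.floor(py / dy).astype(np.int64)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix = np.clip(ix, 0, nx - 1)
    iy = np.clip(iy, 0, ny - 1)

    widths = np.zeros(nz)
    wepls = np.zeros(nz)
    for iz in range(nz):
        mu2d = mu3d[iz]
        line = np.sum(mu2d[iy, ix] * inside * dt[:, None], axis=1)
        wepl_ray = line / mu_water
        body = wepl_ray > BODY_WEPL_THRESHOLD_MM
        if np.any(body):
            idx = np.nonzero(body)[0]
            u_lo = (u[idx[0]] - DETECTOR_PITCH_MM / 2) * geometry.sid_mm / sdd
            u_hi = (u[idx[-1]] + DETECTOR_PITCH_MM / 2) * geometry.sid_mm / sdd
            # tangent-geometry correction (u -> SID*sin(atan(u/SID))): an
            # axis-centred cylinder then reconstructs to its true diameter
            # and an offset one scales by SID/(SID - d), mirroring how
            # scanners calibrate localiser width at isocentre scale
            s = geometry.sid_mm
            widths[iz] = (u_hi / np.sqrt(1 + (u_hi / s) ** 2)
                          - u_lo / np.sqrt(1 + (u_lo / s) ** 2))
            wepls[iz] = float(wepl_ray[body].mean())
    return LocaliserImage(z_mm=phantom.z_mm, width_mm=widths, wepl_mm=wepls,
                          geometry=geometry, kvp=spectrum.kvp)


def _material_names():
    from .phantoms import MATERIAL_NAMES

    return MATERIAL_NAMES


def water_equivalent_diameter(image: LocaliserImage,
                              assume_circular: bool = True) -> np.ndarray:
    """Per-z water-equivalent diameter estimate.

    Under the circular assumption the apparent width is used directly; the
    ellipse combination of two orthogonal localisers is done by the ATCM
    module, which consumes the raw series returned when the flag is off.
    """
    if len(image.z_mm) == 0:
        raise ValueError("empty localiser image")
    return image.width_mm.copy() if assume_circular else image.wepl_mm.copy()
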