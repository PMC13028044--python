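"""Automatic tube current modulation: prediction, feedback, translation.

The constant-noise theory of ATCM says the tube current needed to hold the
noise target grows exponentially with patient water-equivalent diameter
(WED): mA = mA_ref * exp(s * mu_w * (WED - WED_ref)), where mu_w is an
effective water attenuation coefficient and s in (0, 1] a vendor strength
that attenuates the full exponential. Vendors differ in how they obtain the
WED estimate (single or dual localiser, apparent width or attenuation
sizing) and in whether the prediction is corrected online during the scan -
those differences are captured by the archetypes in :mod:`atcmdose.scanner`.

This module also implements NRMSE-based profile translation: tube-current
deviations measured on a reference phantom (between a reference scan and a
deviating scan) are transferred onto a patient model's own reference
profile, run by run, by signed normalised root-mean-square-error factors
mapped proportionally along the scan range. Where the reference and
deviating profiles are identical, the patient's original tube currents are
retained unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .localiser import LocaliserImage

__all__ = [
    "TubeCurrentProfile", "ATCMModel", "predict_profile", "online_modulate",
    "extract_profile_dicom", "nrmse_translate", "read_profile_csv",
    "write_profile_csv",
]

PROVENANCES = ("computed", "dicom", "translated", "file")

FRONTAL_ANGLES = ("PA", "AP")
LATERAL_ANGLES = ("LAT_left", "LAT_right")

#: lateral off-centring beyond which the lateral-failure variant saturates (mm)
LATERAL_FAILURE_THRESHOLD_MM = 20.0


class InvalidCombinationError(ValueError):
    pass


class InvalidArchetypeError(ValueError):
    pass


class DegenerateFactorError(ValueError):
    pass


@dataclass
class TubeCurrentProfile:
    """Tube current as a function of table position (stored z-ascending)."""

    z_mm: np.ndarray
    ma: np.ndarray
    provenance: str = "computed"
    angular: bool = False

    def __post_init__(self):
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.ma = np.asarray(self.ma, dtype=float)
        if self.z_mm.ndim != 1 or self.z_mm.shape != self.ma.shape:
            raise ValueError("z and mA must be 1-D arrays of equal length")
        if len(self.z_mm) == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.z_mm) <= 0):
            raise ValueError("z must be strictly increasing")
        if np.any(self.ma <= 0):
            raise ValueError("tube current must be > 0 everywhere")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def interp(self, z_mm) -> np.ndarray:
        return np.interp(np.asarray(z_mm, dtype=float), self.z_mm, self.ma)

    def mean_ma(self) -> float:
        return float(self.ma.mean())

    def scaled(self, factor: float) -> "TubeCurrentProfile":
        return TubeCurrentProfile(self.z_mm.copy(), self.ma * factor,
                                  self.provenance, self.angular)


@dataclass
class ATCMModel:
    """Parameters of one ATCM archetype's modulation rule."""

    archetype: str = "prospective_magnification"
    wed_ref_mm: float = 250.0
    ma_ref: float = 120.0
    strength: float = 0.5
    mu_eff_per_mm: float = 0.02
    ma_limits: tuple[float, float] = (10.0, 800.0)
    dual_rule: str = "elliptical"
    lateral_failure: bool = False

    def __post_init__(self):
        if not (0.0 < self.strength <= 1.0):
            raise ValueError("modulation strength must be in (0, 1]")
        if self.wed_ref_mm <= 0 or self.ma_ref <= 0:
            raise ValueError("reference WED and mA must be > 0")
        if self.archetype == "size_compensated_lateral_failure":
            self.archetype = "size_compensated"
            self.lateral_failure = True

    def ma_for_wed(self, wed_mm) -> np.ndarray:
        """The exponential modulation rule, clamped to the tube's mA limits."""
        raw = self.ma_ref * np.exp(
            self.strength * self.mu_eff_per_mm
            * (np.asarray(wed_mm, dtype=float) - self.wed_ref_mm))
        return np.clip(raw, *self.ma_limits)


def _split_localisers(localisers):
    if isinstance(localisers, LocaliserImage):
        localisers = [localisers]
    frontal = [im for im in localisers if im.geometry.angle in FRONTAL_ANGLES]
    lateral = [im for im in localisers if im.geometry.angle in LATERAL_ANGLES]
    if len(localisers) == 1:
        if not frontal and not lateral:
            raise InvalidCombinationError("unknown localiser angle")
        return localisers[0], None
    if len(localisers) == 2:
        if len(frontal) != 1 or len(lateral) != 1:
            raise InvalidCombinationError(
                "dual localisers must combine one frontal (PA/AP) and one "
                "lateral view; two parallel views carry no extra information")
        return frontal[0], lateral[0]
    raise InvalidCombinationError("expected one or two localiser images")


def effective_wed(model: ATCMModel, localisers) -> tuple[np.ndarray, np.ndarray]:
    """Per-z effective water-equivalent diameter seen by the ATCM.

    Single localiser: circular assumption, WED = apparent width. Dual
    orthogonal localisers: elliptical combination, WED = sqrt(w_frontal *
    w_lateral). The size-compensated archetype instead sizes the patient
    from mean attenuation (4/pi * mean WEPL for a circular section), which
    is insensitive to geometric magnification.
    """
    primary, secondary = _split_localisers(localisers)
    z = primary.z_mm

    def width_of(im):
        if im is primary:
            return im.width_mm
        return np.interp(z, im.z_mm, im.width_mm)

    if model.archetype == "size_compensated":
        w = (4.0 / np.pi) * primary.wepl_mm
        if secondary is not None:
            w2 = (4.0 / np.pi) * np.interp(z, secondary.z_mm, secondary.wepl_mm)
            w = np.sqrt(np.clip(w * w2, 0.0, None))
        return z, w
    w1 = width_of(primary)
    if secondary is None:
        return z, w1
    w2 = width_of(secondary)
    return z, np.sqrt(np.clip(w1 * w2, 0.0, None))


def predict_profile(model: ATCMModel, localisers) -> TubeCurrentProfile:
    """Prospective tube-current profile from one or two localiser images.

    The lateral-failure variant (observed on some scanners as an apparent
    complete dysfunction of the modulation under lateral off-centring)
    returns the mA ceiling at every z once the lateral shift reaches
    20 mm.
    """
    primary, secondary = _split_localisers(localisers)
    if model.lateral_failure:
        dx = primary.geometry.offset_mm[0]
        if abs(dx) >= LATERAL_FAILURE_THRESHOLD_MM:
            z = primary.z_mm
            return TubeCurrentProfile(z, np.full(len(z), model.ma_limits[1]))
    z, wed = effective_wed(model, localisers)
    body = wed > 0
    ma = np.full(len(z), model.ma_limits[0])
    ma[body] = model.ma_for_wed(wed[body])
    # outside the body, hold the nearest in-body value (run-in/run-out)
    if body.any() and not body.all():
        idx = np.nonzero(body)[0]
        ma[: idx[0]] = ma[idx[0]]
        ma[idx[-1] + 1:] = ma[idx[-1]]
    return TubeCurrentProfile(z, ma)


def central_attenuation_wed(phantom, angle_rad: float, z_mm: float,
                            sid_mm: float, offset_mm, mu_water_per_mm: float,
                            mu3d=None) -> float:
    """Water-equivalent length of the central ray at one gantry angle.

    The source sits at `angle_rad` on the gantry circle (0 = PA position,
    below the patient, advancing clockwise seen from cranial); the ray is
    aimed at the rotation axis.
    """
    dz, dy, dx = phantom.spacing_mm
    nz, ny, nx = phantom.shape
    iz = int(np.clip(np.floor(z_mm / dz), 0, nz - 1))
    cx, cy = phantom.centre_xy_mm
    ax_x, ax_y = cx - offset_mm[0], cy - offset_mm[1]
    src = np.array([ax_x + sid_mm * np.sin(angle_rad),
                    ax_y - sid_mm * np.cos(angle_rad)])
    d = np.array([ax_x, ax_y]) - src
    d /= np.linalg.norm(d)
    step = 0.5 * min(dy, dx)
    n = int(np.ceil(2.2 * sid_mm / step))
    ts = (np.arange(n) + 0.5) * step
    px = src[0] + ts * d[0]
    py = src[1] + ts * d[1]
    ix = np.floor(px / dx).astype(np.int64)
    iy = np.floor(py / dy).astype(np.int64)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix = np.clip(ix, 0, nx - 1)
    iy = np.clip(iy, 0, ny - 1)
    if mu3d is None:
        from .materials import load_default_materials
        from .phantoms import MATERIAL_NAMES

        materials = load_default_materials()
        mass_mu = np.array([materials.coefficient(m, "mu_total", 60.0)
                            for m in MATERIAL_NAMES])
        mu3d = mass_mu[phantom.material_id] * phantom.density / 10.0
    line = float(np.sum(mu3d[iz][iy, ix] * ok) * step)
    return line / mu_water_per_mm


def online_modulate(model: ATCMModel, predicted: TubeCurrentProfile,
                    phantom, protocol, materials=None,
                    n_angles_per_rotation: int = 24) -> TubeCurrentProfile:
    """Real-time feedback modulation with a half-rotation lag.

    The first half rotation of the scan operates without real-time
    modulation (pure prediction). Thereafter the tube current at gantry
    angle theta is recomputed from the true attenuation observed at angle
    theta - pi, applied through the same exponential rule. The
    rotation-resolved currents are collapsed to a per-z mean profile.
    """
    if model.archetype != "online_lag":
        raise InvalidArchetypeError(
            f"online modulation requires the online_lag archetype, "
            f"got {model.archetype!r}")
    if materials is None:
        from .materials import load_default_materials

        materials = load_default_materials()
    from .phantoms import MATERIAL_NAMES

    e_eff = 60.0
    mu_water = materials.mu_linear("water", "mu_total", e_eff)
    mass_mu = np.array([materials.coefficient(m, "mu_total", e_eff)
                        for m in MATERIAL_NAMES])
    mu3d = mass_mu[phantom.material_id] * phantom.density / 10.0

    z0, z1 = protocol.start_z_mm, protocol.end_z_mm
    direction = np.sign(z1 - z0)
    increment = protocol.table_increment_mm
    n_rot = abs(z1 - z0) / increment
    n_t = max(int(np.ceil(n_rot * n_angles_per_rotation)), 2)
    frac = (np.arange(n_t) + 0.5) / n_t
    z_t = z0 + (z1 - z0) * frac
    theta_t = 2.0 * np.pi * n_rot * frac  # start angle 0 (PA position)

    half_lag_t = 0.5 / n_rot  # fraction of scan corresponding to half a turn
    ma_t = np.empty(n_t)
    for i in range(n_t):
        if frac[i] < half_lag_t:
            ma_t[i] = float(np.interp(z_t[i], predicted.z_mm, predicted.ma))
        else:
            z_obs = z_t[i] - direction * increment * 0.5
            wed_obs = central_attenuation_wed(
                phantom, theta_t[i] - np.pi, z_obs, protocol.sid_mm,
                protocol.offset_mm, mu_water, mu3d=mu3d)
            ma_t[i] = float(model.ma_for_wed(wed_obs))

    # collapse to a per-z mean over one full rotation's worth of samples,
    # averaging the angular variation of the feedback
    z_grid = predicted.z_mm
    ma_out = predicted.ma.copy()
    lo, hi = min(z0, z1), max(z0, z1)
    half_win = 0.5 * increment
    for j, zj in enumerate(z_grid):
        if zj < lo - half_win or zj > hi + half_win:
            continue
        sel = np.abs(z_t - zj) <= half_win
        if sel.any():
            ma_out[j] = ma_t[sel].mean()
    ma_out = np.clip(ma_out, *model.ma_limits)
    return TubeCurrentProfile(z_grid, ma_out)


# ---------------------------------------------------------------------------
# DICOM extraction


def extract_profile_dicom(series_dir) -> TubeCurrentProfile:
    """Read per-slice tube current from a directory of CT DICOM instances.

    Uses the slice location and X-ray tube current attributes; the profile
    is returned sorted by slice z ascending regardless of file order.
    """
    import pydicom

    series_dir = Path(series_dir)
    files = sorted(p for p in series_dir.iterdir() if p.is_file())
    zs, mas = [], []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f), force=True)
        except Exception:
            continue
        if "SliceLocation" not in ds and "ImagePositionPatient" not in ds:
            raise IOError(f"{f.name}: no slice location attribute")
        z = (float(ds.SliceLocation) if "SliceLocation" in ds
             else float(ds.ImagePositionPatient[2]))
        ma = None
        if "XRayTubeCurrentInmA" in ds:
            ma = float(ds.XRayTubeCurrentInmA)
        elif "XRayTubeCurrent" in ds:
            ma = float(ds.XRayTubeCurrent)
        if ma is None:
            raise IOError(f"{f.name}: no tube-current attribute")
        zs.append(z)
        mas.append(ma)
    if not zs:
        raise IOError(f"no readable DICOM instances in {series_dir}")
    zs = np.asarray(zs)
    mas = np.asarray(mas)
    order = np.argsort(zs, kind="stable")
    zs, mas = zs[order], mas[order]
    if np.any(np.diff(zs) == 0):
        raise IOError("duplicate slice locations in series")
    return TubeCurrentProfile(zs, mas, provenance="dicom")


# ---------------------------------------------------------------------------
# NRMSE translation


def nrmse_translate(ref: TubeCurrentProfile, dev: TubeCurrentProfile,
                    patient_ref: TubeCurrentProfile,
                    rel_tol: float = 0.01) -> TubeCurrentProfile:
    """Transfer phantom-measured ATCM deviations onto a patient profile.

    The reference-vs-deviating comparison on the phantom is partitioned into
    maximal runs where the deviating profile is consistently higher, lower,
    or equal (within ``rel_tol`` relative) to the reference. Each non-equal
    run P gets a signed factor f_P = 1 + sign * NRMSE_P, with NRMSE_P the
    RMS difference over the run normalised by the run-mean reference
    current; equal runs keep factor 1, so identical profiles leave the
    patient profile unchanged. Run extents are mapped proportionally from
    the phantom scan range onto the patient scan range, and the patient's
    reference currents are multiplied by the factor of the run they fall
    in.
    """
    dev_ma = dev.ma if np.array_equal(dev.z_mm, ref.z_mm) else dev.interp(ref.z_mm)
    r = ref.ma
    n = len(r)
    if n == 0 or len(patient_ref.ma) == 0:
        raise ValueError("empty profile")

    diff = dev_ma - r
    sign = np.sign(diff)
    sign[np.abs(diff) <= rel_tol * r] = 0.0

    # maximal constant-sign runs over the phantom profile
    boundaries = [0] + [i for i in range(1, n) if sign[i] != sign[i - 1]] + [n]
    factors = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        s = sign[a]
        if s == 0:
            f = 1.0
        else:
            # relative RMS over the run: dimensionless, and exactly |c - 1|
            # for a uniformly scaled deviation dev = c * ref
            nrmse = np.sqrt(np.mean((diff[a:b] / r[a:b]) ** 2))
            f = 1.0 + s * nrmse
        if f <= 0:
            raise DegenerateFactorError(
                f"translation factor {f:.3f} <= 0 on run [{a}, {b})")
        factors.append((a / n, b / n, f))

    m = len(patient_ref.ma)
    out = patient_ref.ma.copy()
    pos = (np.arange(m) + 0.5) / m  # fractional position along patient range
    for a, b, f in factors:
        sel = (pos >= a) & (pos < b)
        out[sel] *= f
    if np.any(out <= 0):
        raise DegenerateFactorError("translated profile has non-positive mA")
    return TubeCurrentProfile(patient_ref.z_mm.copy(), out,
                              provenance="translated")


# ---------------------------------------------------------------------------
# CSV round trip


def write_profile_csv(profile: TubeCurrentProfile, path) -> None:
    import pandas as pd

    pd.DataFrame({"z_mm": profile.z_mm, "mA": profile.ma}).to_csv(path,
                                                                  index=False)


def read_profile_csv(path) -> TubeCurrentProfile:
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("z_mm", "mA"):
        if col not in df.columns:
            raise IOError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise IOError(f"{path}: profile file contains no rows")
    if df[["z_mm", "mA"]].isna().any().any():
        raise IOError(f"{path}: malformed rows")
    if (df["mA"] <= 0).any():
        raise ValueError(f"{path}: tube current must be > 0")
    return TubeCurrentProfile(df["z_mm"].to_numpy(), df["mA"].to_numpy(),
                              provenance="file")
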