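"""Synthetic anthropomorphic voxel phantoms.

The cohort emulated here mirrors a 32-model study population: equal numbers
of male and female models with, per sex, an equal proportional distribution
of four BMI classes. Anatomy is parametric - stacked elliptical torso
cross-sections with embedded ellipsoidal lungs, heart, liver, thyroid, a
bony spine and (for female models) breasts - because the mechanisms under
study (z-varying attenuation, geometric magnification, organ position
relative to the scan range) survive this abstraction while keeping Monte
Carlo runs desk-scale.

Grid convention: axes ordered (z, y, x); z+ cranial, y+ anterior (supine
patient, towards the ceiling), x+ patient's right. Voxel indices are
0-based; world coordinates are voxel centres in mm. The thyroid sits at or
above the cranial scan edge and the liver extends caudal of the caudal
edge, so both organs probe dose outside or at the border of the scanned
range.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelPhantom", "CohortSpec", "generate_phantom", "generate_cohort",
    "reference_phantom", "save_phantom", "load_phantom",
    "MATERIAL_NAMES", "ORGANS",
]

MATERIAL_NAMES = ("air", "lung", "adipose", "soft_tissue", "water", "bone",
                  "aluminium", "pmma")
MATERIAL_ID = {name: i for i, name in enumerate(MATERIAL_NAMES)}

#: default material densities used when voxelising (g/cm^3)
DEFAULT_DENSITY = {"air": 1.205e-3, "lung": 0.26, "adipose": 0.95,
                   "soft_tissue": 1.06, "water": 1.00, "bone": 1.92,
                   "aluminium": 2.699, "pmma": 1.19}

ORGANS = ("lungs", "heart", "liver", "thyroid", "breasts")
SEXES = ("male", "female")
BMI_CLASSES = ("underweight", "normal", "overweight", "obese")

# torso half-axes (lateral a, anteroposterior b) in mm per BMI class
_BODY_AXES = {"underweight": (115.0, 80.0), "normal": (135.0, 95.0),
              "overweight": (150.0, 105.0), "obese": (165.0, 115.0)}


class ConfigurationError(ValueError):
    pass


@dataclass
class VoxelPhantom:
    """A voxelised patient: density and material grids plus organ masks."""

    density: np.ndarray          # (nz, ny, nx), g/cm^3
    material_id: np.ndarray      # (nz, ny, nx), uint8 into MATERIAL_NAMES
    masks: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float]   # (dz, dy, dx)
    sex: str
    bmi_class: str
    z_apex_mm: float             # cranial scan-range bound
    z_base_mm: float             # caudal scan-range bound
    origin_mm: tuple[float, float, float] = None  # world coord of voxel (0,0,0)
    model_id: str = "phantom"

    def __post_init__(self):
        if self.origin_mm is None:
            self.origin_mm = tuple(s / 2.0 for s in self.spacing_mm)
        self.validate()

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self):
        return self.density.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis (0=z,1=y,2=x)."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    @property
    def z_mm(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def centre_xy_mm(self) -> tuple[float, float]:
        """World (x, y) of the grid centre; the body axis for a centred phantom."""
        y = self.axis_coords(1)
        x = self.axis_coords(2)
        return (0.5 * (x[0] + x[-1]), 0.5 * (y[0] + y[-1]))

    @property
    def voxel_volume_cm3(self) -> float:
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx / 1000.0

    def body_mask(self) -> np.ndarray:
        return self.material_id != MATERIAL_ID["air"]

    def validate(self) -> None:
        if np.any(self.density < 0):
            raise ValueError("density must be >= 0")
        air = MATERIAL_ID["air"]
        names = list(self.masks)
        for i, a in enumerate(names):
            if np.any(self.masks[a] & (self.material_id == air)):
                raise ValueError(f"mask {a} covers air voxels")
            for b in names[i + 1:]:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"masks {a} and {b} overlap")
        if self.sex == "male" and self.masks.get("breasts", np.zeros(1)).any():
            raise ValueError("male phantom must not have a breast mask")


@dataclass
class CohortSpec:
    """Composition of a synthetic cohort; default 4 per (sex x BMI) cell = 32."""

    counts: dict[tuple[str, str], int] = field(default_factory=lambda: {
        (s, b): 4 for s in SEXES for b in BMI_CLASSES})
    master_seed: int = 0
    shape: tuple[int, int, int] = (96, 72, 72)
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    jitter: float = 0.04   # fractional jitter on ellipsoid axes

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("cohort counts must be >= 0")


def _derive_seed(master_seed: int, *parts) -> int:
    key = ":".join([str(master_seed), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


def _ellipsoid(zc, yc, xc, az, ay, ax, zz, yy, xx):
    return (((zz - zc) / az) ** 2 + ((yy - yc) / ay) ** 2
            + ((xx - xc) / ax) ** 2) <= 1.0


def generate_phantom(sex: str, bmi_class: str, seed: int,
                     shape=(96, 72, 72), spacing_mm=(5.0, 5.0, 5.0),
                     jitter: float = 0.04, model_id: str | None = None
                     ) -> VoxelPhantom:
    """Generate one deterministic torso phantom.

    The BMI class scales the elliptical torso cross-section; `seed` drives a
    small fractional jitter of body and organ axes so that models within a
    cell differ anatomically. Identical arguments give voxel-identical
    phantoms.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex label {sex!r}")
    if bmi_class not in BMI_CLASSES:
        raise ValueError(f"unknown BMI class {bmi_class!r}")
    if min(shape) < 32:
        raise ConfigurationError("resolution below 32^3 cannot contain the organs")

    rng = np.random.default_rng(seed)
    jit = lambda: 1.0 + rng.uniform(-jitter, jitter)  # noqa: E731

    nz, ny, nx = shape
    dz, dy, dx = spacing_mm
    z = dz / 2 + dz * np.arange(nz)
    y = dy / 2 + dy * np.arange(ny)
    x = dx / 2 + dx * np.arange(nx)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij", sparse=True)
    cx, cy = float(x.mean()), float(y.mean())
    z_extent = nz * dz
    zscale = z_extent / 480.0  # organ template is laid out on a 480 mm torso

    a0, b0 = _BODY_AXES[bmi_class]
    a = a0 * jit() * (1.03 if sex == "male" else 1.0)
    b = b0 * jit() * (1.03 if sex == "male" else 1.0)
    if a >= (nx * dx) / 2 or b >= (ny * dy) / 2:
        raise ConfigurationError("body does not fit inside the grid")

    z_lo, z_hi = 20.0 * zscale, 460.0 * zscale
    in_z = (zz >= z_lo) & (zz <= z_hi)
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    body = (r2 <= 1.0) & in_z
    shell = (r2 > 0.88**2) & body  # subcutaneous fat layer

    def organ(zc, yc_frac, xc_frac, az, ay_frac, ax_frac):
        return _ellipsoid(zc * zscale, cy + yc_frac * b, cx + xc_frac * a,
                          az * zscale, ay_frac * b, ax_frac * a, zz, yy, xx) & body

    jz = lambda lo=-5.0, hi=5.0: rng.uniform(lo, hi)  # noqa: E731

    lungs = (organ(255 + jz(), 0.05, -0.42 * jit(), 75 * jit(), 0.60, 0.30)
             | organ(255 + jz(), 0.05, 0.42 * jit(), 75 * jit(), 0.60, 0.30))
    heart = organ(230 + jz(), 0.15, -0.15, 45 * jit(), 0.38, 0.28) & ~lungs
    liver = organ(140 + jz(-3, 3), 0.0, 0.30, 55 * jit(), 0.52, 0.50) & ~lungs & ~heart
    thyroid = organ(352 + jz(-3, 3), 0.45, 0.0, 12 * jit(), 0.12, 0.18)
    thyroid &= ~(lungs | heart | liver)
    prior = lungs | heart | liver | thyroid
    if sex == "female":
        breasts = (organ(240 + jz(), 0.85, -0.45, 55 * jit(), 0.35, 0.30)
                   | organ(240 + jz(), 0.85, 0.45, 55 * jit(), 0.35, 0.30))
        breasts &= ~prior
    else:
        breasts = np.zeros(shape, dtype=bool)
    spine = (((xx - cx) / 16.0) ** 2 + ((yy - (cy - 0.60 * b)) / 16.0) ** 2 <= 1.0)
    spine = spine & body & ~(prior | breasts)

    material = np.zeros(shape, dtype=np.uint8)
    material[body] = MATERIAL_ID["soft_tissue"]
    material[shell] = MATERIAL_ID["adipose"]
    material[breasts] = MATERIAL_ID["adipose"]
    material[spine] = MATERIAL_ID["bone"]
    material[lungs] = MATERIAL_ID["lung"]

    density = np.empty(shape, dtype=np.float64)
    for name, mid in MATERIAL_ID.items():
        density[material == mid] = DEFAULT_DENSITY[name]

    masks = {"lungs": lungs, "heart": heart, "liver": liver, "thyroid": thyroid}
    if sex == "female":
        masks["breasts"] = breasts
    for name in ("lungs", "heart", "liver", "thyroid"):
        if not masks[name].any():
            raise ConfigurationError(f"grid too coarse: organ {name} empty")

    if model_id is None:
        model_id = f"{sex}_{bmi_class}_s{seed}"
    return VoxelPhantom(
        density=density, material_id=material, masks=masks,
        spacing_mm=tuple(spacing_mm), sex=sex, bmi_class=bmi_class,
        z_apex_mm=340.0 * zscale, z_base_mm=170.0 * zscale, model_id=model_id)


def generate_cohort(spec: CohortSpec) -> list[VoxelPhantom]:
    """Generate the full cohort described by `spec`, deterministically.

    Per-model seeds are derived by hashing (master seed, sex, BMI class,
    replicate index), so regenerating the same spec gives voxel-identical
    models and single cells can be regenerated in isolation.
    """
    out = []
    idx = 0
    for sex in SEXES:
        for bmi in BMI_CLASSES:
            n = spec.counts.get((sex, bmi), 0)
            for rep in range(n):
                seed = _derive_seed(spec.master_seed, sex, bmi, rep)
                out.append(generate_phantom(
                    sex, bmi, seed, shape=spec.shape, spacing_mm=spec.spacing_mm,
                    jitter=spec.jitter, model_id=f"M{idx:02d}_{sex}_{bmi}"))
                idx += 1
    return out


_REFERENCE_SEED = 714025


def reference_phantom(shape=(96, 72, 72), spacing_mm=(5.0, 5.0, 5.0)
                      ) -> VoxelPhantom:
    """The fixed adult-male phantom used to derive archetype ATCM profiles.

    Plays the role of the single physical anthropomorphic phantom from which
    reference and deviating tube-current profiles are measured before being
    translated onto the patient models.
    """
    return generate_phantom("male", "normal", _REFERENCE_SEED, shape=shape,
                            spacing_mm=spacing_mm, model_id="reference")


# ---------------------------------------------------------------------------
# persistence


def save_phantom(phantom: VoxelPhantom, path) -> None:
    """Write density/material/mask volumes as NIfTI plus a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = phantom.spacing_mm
    affine = np.diag([dx, dy, dz, 1.0])  # NIfTI is (x, y, z) ordered

    def write(name, arr, dtype):
        img = nib.Nifti1Image(np.asarray(arr, dtype=dtype).transpose(2, 1, 0),
                              affine)
        nib.save(img, str(path / f"{name}.nii.gz"))

    write("density", phantom.density, np.float64)
    write("material", phantom.material_id, np.uint8)
    for organ, mask in phantom.masks.items():
        write(f"mask_{organ}", mask, np.uint8)
    sidecar = dict(
        sex=phantom.sex, bmi_class=phantom.bmi_class, model_id=phantom.model_id,
        spacing_mm=list(phantom.spacing_mm), origin_mm=list(phantom.origin_mm),
        z_apex_mm=phantom.z_apex_mm, z_base_mm=phantom.z_base_mm,
        organs=list(phantom.masks), materials=list(MATERIAL_NAMES))
    (path / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path) -> VoxelPhantom:
    import nibabel as nib

    path = Path(path)
    sidecar_path = path / "phantom.json"
    if not sidecar_path.exists():
        raise IOError(f"missing phantom sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())

    def read(name, dtype):
        f = path / f"{name}.nii.gz"
        if not f.exists():
            raise IOError(f"missing phantom volume {f}")
        arr = np.asanyarray(nib.load(str(f)).dataobj)
        return np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(dtype)

    density = read("density", np.float64)
    material = read("material", np.uint8)
    masks = {o: read(f"mask_{o}", np.uint8).astype(bool) for o in meta["organs"]}
    return VoxelPhantom(
        density=density, material_id=material, masks=masks,
        spacing_mm=tuple(meta["spacing_mm"]), sex=meta["sex"],
        bmi_class=meta["bmi_class"], z_apex_mm=meta["z_apex_mm"],
        z_base_mm=meta["z_base_mm"], origin_mm=tuple(meta["origin_mm"]),
        model_id=meta["model_id"])
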