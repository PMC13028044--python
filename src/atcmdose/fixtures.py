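"""Deterministic generators of small test inputs.

These stand in for the non-public inputs of the original study design: a
DICOM CT series with known per-slice tube currents, reference/deviating
profile pairs with prescribed run structure, homogeneous water cylinders
for analytic transport oracles, and paired samples with known effect size
for the statistics. Fixture generators are independent of the modules they
exercise and fully reproducible from their parameters and seed.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .atcm import TubeCurrentProfile
from .phantoms import MATERIAL_ID, VoxelPhantom

__all__ = ["make_dicom_series", "make_profile_pair", "make_water_cylinder",
           "make_stats_pairs"]


def make_dicom_series(outdir, ma_values, z_start_mm: float = 0.0,
                      z_step_mm: float = 5.0, shuffle_seed: int | None = None
                      ) -> Path:
    """Write a minimal CT DICOM series with the given per-slice currents.

    Instances carry only the attributes a tube-current reader needs (slice
    location, tube current, minimal identity tags) - no pixel data. File
    names can be shuffled to verify order-invariant extraction.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ma_values = list(ma_values)
    if len(ma_values) < 1:
        raise ValueError("need at least one slice")
    if any(m <= 0 for m in ma_values):
        raise ValueError("tube currents must be positive")

    order = np.arange(len(ma_values))
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(order)

    series_uid = generate_uid(entropy_srcs=["atcmdose-fixture"])
    for file_idx, slice_idx in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[f"atcmdose-fixture-{slice_idx}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = int(file_idx + 1)
        ds.SliceLocation = float(z_start_mm + z_step_mm * slice_idx)
        ds.XRayTubeCurrent = float(ma_values[slice_idx])
        ds.save_as(str(outdir / f"ct_{file_idx:04d}.dcm"),
                   enforce_file_format=True)
    return outdir


def make_profile_pair(runs, z_start_mm: float = 0.0, z_step_mm: float = 5.0,
                      ref_ma: float = 100.0
                      ) -> tuple[TubeCurrentProfile, TubeCurrentProfile]:
    """Reference/deviating profile pair with prescribed run structure.

    ``runs`` is a list of (length, factor) pairs: the reference is constant
    at ``ref_ma`` and the deviating profile applies each factor over its
    run, so the expected NRMSE translation factor of a run is exactly the
    factor itself (NRMSE = |factor - 1| with the matching sign).
    """
    mas = []
    for length, factor in runs:
        if factor <= 0:
            raise ValueError("run factors must be positive")
        mas.extend([ref_ma * factor] * int(length))
    n = len(mas)
    if n == 0:
        raise ValueError("empty run structure")
    z = z_start_mm + z_step_mm * np.arange(n)
    ref = TubeCurrentProfile(z, np.full(n, ref_ma))
    dev = TubeCurrentProfile(z.copy(), np.array(mas, dtype=float))
    return ref, dev


def make_water_cylinder(diameter_mm: float = 300.0, height_mm: float = 200.0,
                        spacing_mm: float = 5.0, margin_mm: float = 80.0
                        ) -> VoxelPhantom:
    """Homogeneous water cylinder phantom for analytic transport oracles.

    The cylinder axis runs along z through the grid centre; the organ-mask
    machinery is bypassed (no organs), so the phantom only supports
    projection and dose-engine tests.
    """
    if diameter_mm <= 0 or height_mm <= 0:
        raise ValueError("cylinder dimensions must be positive")
    r = diameter_mm / 2.0
    half_xy = r + margin_mm
    nxy = int(np.ceil(2 * half_xy / spacing_mm))
    nz = int(np.ceil(height_mm / spacing_mm))
    d = spacing_mm
    xy = d / 2 + d * np.arange(nxy)
    c = float(xy.mean())
    yy, xx = np.meshgrid(xy, xy, indexing="ij")
    inside = ((xx - c) ** 2 + (yy - c) ** 2) <= r**2
    material = np.zeros((nz, nxy, nxy), dtype=np.uint8)
    material[:, inside] = MATERIAL_ID["water"]
    density = np.where(material == MATERIAL_ID["water"], 1.0, 1.205e-3)
    z_lo, z_hi = 0.25 * nz * d, 0.75 * nz * d
    return VoxelPhantom(
        density=density, material_id=material, masks={},
        spacing_mm=(d, d, d), sex="male", bmi_class="normal",
        z_apex_mm=z_hi, z_base_mm=z_lo, model_id="water_cylinder")


def make_stats_pairs(delta: float, sigma: float, n: int, seed: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Paired samples y = x + delta + Normal(0, sigma^2) noise, seeded."""
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if sigma <= 0:
        raise ValueError("noise SD must be positive")
    rng = np.random.default_rng(seed)
    x = rng.normal(10.0, 2.0, n)
    y = x + delta + rng.normal(0.0, sigma, n)
    return x, y
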