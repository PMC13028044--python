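"""Parametric scanner model and the vendor-archetype presets.

Exact vendor geometry, filtration and ATCM firmware are proprietary, so the
package works with archetypes: parameter sets that reproduce the *mechanism*
of each modulation family rather than any particular product.

* ``prospective_magnification`` - modulation fixed prospectively from the
  localiser; inherits its geometric magnification errors.
* ``online_lag`` - prospective prediction plus real-time feedback from the
  attenuation observed half a rotation earlier; the first half rotation runs
  without feedback.
* ``size_compensated`` - sizes the patient from localiser attenuation rather
  than apparent width, largely cancelling vertical-offset magnification; the
  ``lateral_failure`` variant saturates at the mA ceiling under lateral
  off-centring.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .materials import MaterialTable, load_default_materials
from .spectra import BowtieFilter, Spectrum, build_spectrum

__all__ = ["ScannerModel", "make_scanner", "ARCHETYPES", "kvp_for_bmi_class"]

#: tube potential selected per BMI class in the simulated screening protocol
KVP_BY_BMI = {"underweight": 100.0, "normal": 120.0, "overweight": 120.0,
              "obese": 140.0}


def kvp_for_bmi_class(bmi_class: str) -> float:
    try:
        return KVP_BY_BMI[bmi_class]
    except KeyError:
        raise ValueError(f"unknown BMI class {bmi_class!r}") from None


@dataclass
class ScannerModel:
    """Geometry, beam and output calibration of one scanner archetype."""

    name: str
    sid_mm: float = 600.0                # focus-isocentre distance
    fan_half_angle_rad: float = 0.45
    collimation_mm: float = 40.0         # at isocentre
    pitch: float = 1.4
    rotation_time_s: float = 0.5
    filtration_mm_al: dict[float, float] = field(
        default_factory=lambda: {100.0: 3.0, 120.0: 3.5, 140.0: 4.0})
    bowtie: BowtieFilter = None
    # nominal free-in-air kerma at isocentre, mGy per 100 mAs, per kVp
    output_mgy_per_100mas: dict[float, float] = field(
        default_factory=lambda: {100.0: 8.0, 120.0: 12.0, 140.0: 16.0})
    ma_limits: tuple[float, float] = (10.0, 800.0)
    atcm_archetype: str = "prospective_magnification"

    def __post_init__(self):
        if self.sid_mm <= 0:
            raise ValueError("focus-isocentre distance must be > 0")
        if not (0.5 <= self.pitch <= 2.0):
            raise ValueError(f"pitch {self.pitch} outside [0.5, 2.0]")
        if not (1.0 <= self.pitch <= 2.0):
            warnings.warn(f"pitch {self.pitch} outside the usual [1.0, 2.0]",
                          stacklevel=2)
        if self.bowtie is None:
            self.bowtie = BowtieFilter(gamma_max_rad=self.fan_half_angle_rad,
                                       t_max_mm=15.0)
        if any(v <= 0 for v in self.output_mgy_per_100mas.values()):
            raise ValueError("output calibration must be > 0")

    def spectrum(self, kvp: float, materials: MaterialTable | None = None
                 ) -> Spectrum:
        filt = self.filtration_mm_al.get(kvp, 3.5)
        return build_spectrum(kvp, filt, materials)

    def table_increment_mm(self) -> float:
        """Table travel per rotation: collimation multiplied by the pitch."""
        return self.collimation_mm * self.pitch

    def nominal_output(self, kvp: float) -> float:
        try:
            return self.output_mgy_per_100mas[kvp]
        except KeyError:
            raise KeyError(f"no nominal output calibration for {kvp} kVp") from None


ARCHETYPES: dict[str, dict] = {
    "prospective_magnification": dict(pitch=1.5, collimation_mm=40.0),
    "online_lag": dict(pitch=1.4, collimation_mm=40.0),
    "size_compensated": dict(pitch=1.4, collimation_mm=40.0),
    "size_compensated_lateral_failure": dict(pitch=1.35, collimation_mm=40.0),
}


def make_scanner(archetype: str, **overrides) -> ScannerModel:
    """Build a ScannerModel preset for a named ATCM archetype."""
    if archetype not in ARCHETYPES:
        raise ValueError(
            f"unknown archetype {archetype!r}; choose from {sorted(ARCHETYPES)}")
    kw = dict(ARCHETYPES[archetype])
    kw.update(overrides)
    return ScannerModel(name=archetype, atcm_archetype=archetype, **kw)


def scanner_from_config(cfg: dict, materials: MaterialTable | None = None
                        ) -> ScannerModel:
    """Build a scanner from a ``scanner:`` config mapping."""
    cfg = dict(cfg)
    archetype = cfg.pop("archetype", "prospective_magnification")
    bowtie_cfg = cfg.pop("bowtie", None)
    if bowtie_cfg:
        cfg["bowtie"] = BowtieFilter(**bowtie_cfg)
    known = {"sid_mm", "fan_half_angle_rad", "collimation_mm", "pitch",
             "rotation_time_s", "filtration_mm_al", "bowtie",
             "output_mgy_per_100mas", "ma_limits"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown scanner config keys: {sorted(unknown)}")
    if "ma_limits" in cfg:
        cfg["ma_limits"] = tuple(cfg["ma_limits"])
    for key in ("filtration_mm_al", "output_mgy_per_100mas"):
        if key in cfg:
            cfg[key] = {float(k): float(v) for k, v in cfg[key].items()}
    return make_scanner(archetype, **cfg)
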