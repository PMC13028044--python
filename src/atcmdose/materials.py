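"""Material interaction data for keV photon transport.

A compact compilation of mass attenuation coefficients (photoelectric,
incoherent, total) and mass energy-absorption coefficients on a 10-150 keV
grid, for the tissues and filter materials a chest-CT dose simulation needs.
Values between grid points are obtained by log-log interpolation, which is
accurate to a few percent for these smoothly varying cross sections.

Coefficients are in cm^2/g; energies in keV; densities in g/cm^3.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["MaterialTable", "load_default_materials", "klein_nishina_cross_section"]

_RE2_CM2 = 7.940787e-26  # classical electron radius squared
_NA = 6.02214076e23
ELECTRON_REST_KEV = 511.0


def klein_nishina_cross_section(energy_kev):
    """Total free-electron Compton cross section (cm^2) at the given energy."""
    k = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    a = 1.0 + 2.0 * k
    return 2 * np.pi * _RE2_CM2 * (
        (1 + k) / k**2 * (2 * (1 + k) / a - np.log(a) / k)
        + np.log(a) / (2 * k)
        - (1 + 3 * k) / a**2
    )


@dataclass
class MaterialTable:
    """Tabulated photon interaction coefficients for a set of materials."""

    energies_kev: np.ndarray
    coefficients: dict[str, dict[str, np.ndarray]]  # material -> column -> values
    densities: dict[str, float]
    z_over_a: dict[str, float] = field(default_factory=dict)

    COLUMNS = ("mu_pe", "mu_incoh", "mu_total", "mu_en")

    def __post_init__(self):
        e = np.asarray(self.energies_kev, dtype=float)
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if e[0] > 10.0 or e[-1] < 150.0:
            raise ValueError("energy grid must span [10, 150] keV")
        self.energies_kev = e
        self._log_e = np.log(e)
        for mat, cols in self.coefficients.items():
            for name in self.COLUMNS:
                v = np.asarray(cols[name], dtype=float)
                if v.shape != e.shape:
                    raise ValueError(f"{mat}/{name}: wrong length")
                if np.any(v <= 0):
                    raise ValueError(f"{mat}/{name}: coefficients must be > 0")
                cols[name] = v
            tot = cols["mu_total"]
            if np.any(cols["mu_pe"] > tot * (1 + 1e-9)) or np.any(
                cols["mu_incoh"] > tot * (1 + 1e-9)
            ):
                raise ValueError(f"{mat}: partial coefficient exceeds total")

    @property
    def materials(self) -> list[str]:
        return list(self.coefficients)

    def density(self, material: str) -> float:
        return self.densities[material]

    def coefficient(self, material, column, energy_kev):
        """Interpolate a mass coefficient (cm^2/g) at arbitrary energies.

        Log-log interpolation on the tabulated grid; energies are clipped to
        the grid support.
        """
        if column not in self.COLUMNS:
            raise KeyError(column)
        tab = self.coefficients[material][column]
        e = np.clip(np.asarray(energy_kev, dtype=float),
                    self.energies_kev[0], self.energies_kev[-1])
        out = np.exp(np.interp(np.log(e), self._log_e, np.log(tab)))
        return out if out.ndim else float(out)

    def mu_linear(self, material, column, energy_kev, density=None):
        """Linear coefficient in 1/mm at the material's (or given) density."""
        rho = self.density(material) if density is None else density
        return self.coefficient(material, column, energy_kev) * rho / 10.0

    def lookup_grid(self, column, energies_kev, materials=None):
        """(n_materials, n_energies) array of a mass coefficient column."""
        mats = self.materials if materials is None else list(materials)
        return np.stack(
            [np.atleast_1d(self.coefficient(m, column, energies_kev)) for m in mats]
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for mat, cols in self.coefficients.items():
            for i, e in enumerate(self.energies_kev):
                rows.append(
                    dict(material=mat, energy_keV=e,
                         mu_pe_cm2g=cols["mu_pe"][i],
                         mu_incoh_cm2g=cols["mu_incoh"][i],
                         mu_total_cm2g=cols["mu_total"][i],
                         mu_en_cm2g=cols["mu_en"][i])
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def load_default_materials() -> MaterialTable:
    """Load the packaged attenuation tables."""
    import pandas as pd

    pkg = resources.files("atcmdose") / "data"
    df = pd.read_csv(str(pkg / "attenuation.csv"))
    meta = json.loads((pkg / "materials.json").read_text())
    energies = np.sort(df["energy_keV"].unique()).astype(float)
    coeffs: dict[str, dict[str, np.ndarray]] = {}
    for mat, grp in df.groupby("material", sort=False):
        grp = grp.sort_values("energy_keV")
        coeffs[mat] = {
            "mu_pe": grp["mu_pe_cm2g"].to_numpy(),
            "mu_incoh": grp["mu_incoh_cm2g"].to_numpy(),
            "mu_total": grp["mu_total_cm2g"].to_numpy(),
            "mu_en": grp["mu_en_cm2g"].to_numpy(),
        }
    return MaterialTable(
        energies_kev=energies,
        coefficients=coeffs,
        densities={m: v["density_g_cm3"] for m, v in meta.items()},
        z_over_a={m: v["z_over_a"] for m, v in meta.items()},
    )
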