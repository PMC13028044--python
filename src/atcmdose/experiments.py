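"""End-to-end deviation-grid experiments.

Reproduces the structure of a phantom-anchored ATCM deviation study over a
synthetic cohort: a fixed reference phantom is "scanned" under a reference
setup (PA localiser, caudocranial, centred) and under deviating setups
(localiser angle, scan direction, vertical and lateral off-centring, each
with single-PA or dual PA+LAT localisers). Tube-current deviations measured
on the reference phantom are translated onto each cohort model's own
reference profile by signed NRMSE factors, the helical scan is simulated by
Monte Carlo at the BMI-mapped tube potential, and organ doses are compared
to the reference setup with symmetric relative differences plus the study's
statistics (RM-ANOVA with Dunnett, paired t, Bland-Altman).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import dataclasses

from .atcm import (ATCMModel, TubeCurrentProfile, central_attenuation_wed,
                   effective_wed, nrmse_translate, online_modulate,
                   predict_profile)
from .dose import ScanProtocol, calibrate_output, simulate_scan
from .localiser import LocaliserImage, ProjectionGeometry, project_localiser
from .materials import load_default_materials
from .organ_stats import (OrganDoseTable, RelDiffTable, bland_altman,
                          organ_dose, paired_t, relative_difference,
                          rm_anova_dunnett)
from .phantoms import (BMI_CLASSES, SEXES, CohortSpec, _derive_seed,
                       generate_cohort, reference_phantom)
from .scanner import kvp_for_bmi_class, make_scanner

__all__ = ["ExperimentConfig", "Setup", "ResultBundle", "run_reference",
           "run_grid", "summarize"]

LOCALISER_KVP = 120.0


@dataclass(frozen=True)
class Setup:
    """One acquisition condition of the deviation grid."""

    setup_id: str
    family: str  # reference | angle | direction | vertical | lateral
    angles: tuple[str, ...] = ("PA",)
    direction: str = "caudocranial"
    offset_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def dual(self) -> bool:
        return len(self.angles) == 2


@dataclass
class ExperimentConfig:
    """Declarative description of a deviation-grid experiment.

    The default grid is desk-scale: one model per (sex x BMI) cell, offsets
    {+-20, +-60} mm and 2e5 photons per scan; the full 32-model study grid
    is obtained with ``n_per_cell=4`` and ``offsets_mm=(20, 40, 60)`` at
    higher photon counts.
    """

    archetype: str = "prospective_magnification"
    n_per_cell: int = 1
    shape: tuple[int, int, int] = (96, 72, 72)
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 5.0)
    vertical_offsets_mm: tuple[float, ...] = (-60.0, -20.0, 20.0, 60.0)
    lateral_offsets_mm: tuple[float, ...] = (-60.0, -20.0, 20.0, 60.0)
    families: tuple[str, ...] = ("angle", "direction", "vertical", "lateral")
    n_photons: int = 200_000
    master_seed: int = 0
    output_dir: str | None = None
    ma_ref: float = 120.0
    wed_ref_mm: float = 270.0
    atcm_strength: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        cfg = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shape", "spacing_mm", "vertical_offsets_mm",
                    "lateral_offsets_mm", "families"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)


def build_setups(config: ExperimentConfig) -> list[Setup]:
    """The deviation grid; the reference setup is always first."""
    setups = [Setup("reference", "reference")]
    if "angle" in config.families:
        setups += [
            Setup("angle_AP", "angle", ("AP",)),
            Setup("angle_LAT", "angle", ("LAT_right",)),
            Setup("angle_PA_LAT", "angle", ("PA", "LAT_right")),
            Setup("angle_AP_LAT", "angle", ("AP", "LAT_right")),
        ]
    if "direction" in config.families:
        setups += [
            Setup("dir_craniocaudal_single", "direction", ("PA",),
                  direction="craniocaudal"),
            Setup("dir_craniocaudal_dual", "direction", ("PA", "LAT_right"),
                  direction="craniocaudal"),
        ]
    if "vertical" in config.families:
        for dy in config.vertical_offsets_mm:
            tag = f"y{int(dy):+d}"
            setups.append(Setup(f"vert_{tag}_single", "vertical", ("PA",),
                                offset_mm=(0.0, float(dy))))
            setups.append(Setup(f"vert_{tag}_dual", "vertical",
                                ("PA", "LAT_right"), offset_mm=(0.0, float(dy))))
    if "lateral" in config.families:
        for dx in config.lateral_offsets_mm:
            tag = f"x{int(dx):+d}"
            setups.append(Setup(f"lat_{tag}_single", "lateral", ("PA",),
                                offset_mm=(float(dx), 0.0)))
            setups.append(Setup(f"lat_{tag}_dual", "lateral",
                                ("PA", "LAT_right"), offset_mm=(float(dx), 0.0)))
    return setups


@dataclass
class ResultBundle:
    """All tables and metadata produced by one grid run."""

    config: ExperimentConfig
    organ_doses: OrganDoseTable
    rel_diffs: RelDiffTable
    stats: list[dict]
    setups: list[Setup]
    metadata: dict = field(default_factory=dict)
    complete: bool = True

    def manifest_hash(self) -> str:
        payload = (self.organ_doses.to_frame().to_csv(index=False)
                   + self.rel_diffs.to_frame().to_csv(index=False))
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        paths = {}
        od = outdir / "organ_doses.csv"
        self.organ_doses.to_frame().to_csv(od, index=False)
        paths["organ_doses"] = str(od)
        rd = outdir / "relative_differences.csv"
        self.rel_diffs.to_frame().to_csv(rd, index=False)
        paths["relative_differences"] = str(rd)
        st = outdir / "stats_summary.csv"
        pd.DataFrame(self.stats).to_csv(st, index=False)
        paths["stats_summary"] = str(st)
        manifest = dict(master_seed=self.config.master_seed,
                        archetype=self.config.archetype,
                        n_models=self.metadata.get("n_models"),
                        n_setups=len(self.setups),
                        n_photons=self.config.n_photons,
                        complete=self.complete,
                        hash=self.manifest_hash())
        mf = outdir / "manifest.json"
        mf.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = str(mf)
        return paths


class _Runner:
    """Shared state for one experiment run."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.materials = load_default_materials()
        self.scanner = make_scanner(config.archetype)
        self.atcm = ATCMModel(
            archetype=config.archetype, wed_ref_mm=config.wed_ref_mm,
            ma_ref=config.ma_ref, strength=config.atcm_strength,
            ma_limits=self.scanner.ma_limits)
        self.loc_spectrum = self.scanner.spectrum(LOCALISER_KVP, self.materials)
        self.ref_phantom = reference_phantom(shape=config.shape,
                                             spacing_mm=config.spacing_mm)
        spec = CohortSpec(
            counts={(s, b): config.n_per_cell for s in SEXES for b in BMI_CLASSES},
            master_seed=config.master_seed, shape=config.shape,
            spacing_mm=config.spacing_mm)
        self.models = generate_cohort(spec)
        self._profile_cache: dict[str, TubeCurrentProfile] = {}
        self._atcm_cache: dict[tuple, ATCMModel] = {}
        self._online_model: ATCMModel | None = None
        # warm the per-kVp calibrations once so every setup reuses them
        self.calibrations = {
            kvp: calibrate_output(self.scanner, kvp, materials=self.materials)
            for kvp in (100.0, 120.0, 140.0)}

    # -- localiser / profile machinery ------------------------------------
    def localisers(self, phantom, setup: Setup) -> list[LocaliserImage]:
        return [
            project_localiser(
                phantom,
                ProjectionGeometry(angle=a, sid_mm=self.scanner.sid_mm,
                                   offset_mm=setup.offset_mm),
                self.loc_spectrum, self.materials,
                fan_half_angle_rad=self.scanner.fan_half_angle_rad + 0.05)
            for a in setup.angles
        ]

    def atcm_for(self, setup: Setup) -> ATCMModel:
        """ATCM model with WED_ref anchored per localiser configuration.

        The modulation curve is calibrated so that the centred reference
        phantom yields the reference current under *any* scout
        configuration (single or dual, frontal or lateral, width- or
        attenuation-sized); only deviations from that anchored state then
        modulate the current, mirroring how vendors normalise their noise
        target across scout modes.
        """
        key = tuple(sorted(setup.angles))
        if key not in self._atcm_cache:
            centred = Setup("calibration", "reference", setup.angles)
            imgs = self.localisers(self.ref_phantom, centred)
            z, wed = effective_wed(self.atcm, imgs)
            sel = ((z >= self.ref_phantom.z_base_mm)
                   & (z <= self.ref_phantom.z_apex_mm) & (wed > 0))
            wed_ref = float(np.mean(wed[sel]))
            self._atcm_cache[key] = dataclasses.replace(self.atcm,
                                                        wed_ref_mm=wed_ref)
        return self._atcm_cache[key]

    def online_model(self) -> ATCMModel:
        """Feedback rule anchored to the centred phantom's central-ray WEPL."""
        if self._online_model is None:
            mats = self.materials
            mu_w = mats.mu_linear("water", "mu_total", 60.0)
            ph = self.ref_phantom
            zs = np.linspace(ph.z_base_mm, ph.z_apex_mm, 5)
            wepls = [central_attenuation_wed(ph, ang, z, self.scanner.sid_mm,
                                             (0.0, 0.0), mu_w)
                     for ang in (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
                     for z in zs]
            self._online_model = dataclasses.replace(
                self.atcm, wed_ref_mm=float(np.mean(wepls)))
        return self._online_model

    def _crop(self, profile: TubeCurrentProfile, phantom) -> TubeCurrentProfile:
        dz = phantom.spacing_mm[0]
        sel = ((profile.z_mm >= phantom.z_base_mm - dz)
               & (profile.z_mm <= phantom.z_apex_mm + dz))
        return TubeCurrentProfile(profile.z_mm[sel], profile.ma[sel],
                                  provenance=profile.provenance)

    def phantom_profile(self, setup: Setup) -> TubeCurrentProfile:
        """ATCM profile of the reference phantom under one setup."""
        if setup.setup_id in self._profile_cache:
            return self._profile_cache[setup.setup_id]
        predicted = predict_profile(self.atcm_for(setup),
                                    self.localisers(self.ref_phantom, setup))
        profile = self._crop(predicted, self.ref_phantom)
        if self.config.archetype == "online_lag":
            protocol = ScanProtocol.for_phantom(
                self.ref_phantom, self.scanner, LOCALISER_KVP,
                direction=setup.direction, offset_mm=setup.offset_mm,
                profile=profile)
            profile = online_modulate(self.online_model(), profile,
                                      self.ref_phantom, protocol,
                                      materials=self.materials)
        self._profile_cache[setup.setup_id] = profile
        return profile

    def model_reference_profile(self, model) -> TubeCurrentProfile:
        """The model's own ground-truth reference profile (reference setup)."""
        key = f"model:{model.model_id}"
        if key in self._profile_cache:
            return self._profile_cache[key]
        ref_setup = Setup("reference", "reference")
        predicted = predict_profile(self.atcm_for(ref_setup),
                                    self.localisers(model, ref_setup))
        profile = self._crop(predicted, model)
        if self.config.archetype == "online_lag":
            protocol = ScanProtocol.for_phantom(
                model, self.scanner, LOCALISER_KVP, profile=profile)
            profile = online_modulate(self.online_model(), profile, model,
                                      protocol, materials=self.materials)
        self._profile_cache[key] = profile
        return profile

    def model_profile(self, model, setup: Setup) -> TubeCurrentProfile:
        """Setup-specific profile for a model, by NRMSE translation."""
        model_ref = self.model_reference_profile(model)
        if setup.family == "reference":
            return model_ref
        return nrmse_translate(self.phantom_profile(Setup("reference", "reference")),
                               self.phantom_profile(setup), model_ref)

    # -- simulation ---------------------------------------------------------
    def simulate(self, model, setup: Setup, profile) -> "np.ndarray":
        kvp = kvp_for_bmi_class(model.bmi_class)
        protocol = ScanProtocol.for_phantom(
            model, self.scanner, kvp, direction=setup.direction,
            offset_mm=setup.offset_mm, profile=profile)
        seed = _derive_seed(self.config.master_seed, model.model_id,
                            setup.setup_id)
        return simulate_scan(model, protocol, self.scanner,
                             self.config.n_photons, seed,
                             materials=self.materials,
                             calibration=self.calibrations[kvp])


def run_reference(config: ExperimentConfig, runner: _Runner | None = None
                  ) -> dict:
    """Simulate the reference setup for every model.

    Returns per-model organ-dose rows keyed by model id; these establish
    Dose_ref for all later relative differences.
    """
    runner = runner or _Runner(config)
    ref_setup = Setup("reference", "reference")
    doses: dict[str, dict[str, float]] = {}
    table = OrganDoseTable()
    for model in runner.models:
        profile = runner.model_profile(model, ref_setup)
        dosemap = runner.simulate(model, ref_setup, profile)
        rows = organ_dose(dosemap, model, scanner=config.archetype,
                          setup_id="reference")
        table.extend(rows)
        doses[model.model_id] = {r.organ: r.mean_dose_mgy for r in rows}
    return dict(runner=runner, organ_doses=table, reference_doses=doses)


def _family_stats(config, setups, doses, models) -> list[dict]:
    """RM-ANOVA/Dunnett, paired t and Bland-Altman summaries per family."""
    stats_rows: list[dict] = []
    organs = sorted({o for m in doses.values() for o in m["reference"]})
    model_ids = [m.model_id for m in models]

    def matrix(setup_ids, organ):
        ids = [m for m in model_ids
               if all(organ in doses[m].get(s, {}) for s in setup_ids)]
        if len(ids) < 3:
            return None, ids
        return np.array([[doses[m][s][organ] for s in setup_ids]
                         for m in ids]), ids

    by_family: dict[str, list[Setup]] = {}
    for s in setups:
        by_family.setdefault(s.family, []).append(s)

    for family in ("angle", "vertical", "lateral"):
        fam = [s for s in by_family.get(family, [])
               if family == "angle" or not s.dual]
        if not fam:
            continue
        conds = ["reference"] + [s.setup_id for s in fam]
        for organ in organs:
            data, ids = matrix(conds, organ)
            if data is None:
                continue
            res = rm_anova_dunnett(data, conds, "reference")
            for comp in res["comparisons"]:
                stats_rows.append(dict(
                    test=f"rm_anova_dunnett_{family}", organ=organ,
                    comparison=f"{comp['condition']} vs reference",
                    statistic=comp["t"], df=res["df"][1],
                    p_adjusted=comp["p_adjusted"], F=res["F"],
                    p_anova=res["p_anova"], n=len(ids)))

    for s in by_family.get("direction", []):
        for organ in organs:
            pairs = [(doses[m]["reference"].get(organ),
                      doses[m].get(s.setup_id, {}).get(organ))
                     for m in model_ids]
            pairs = [(a, b) for a, b in pairs if a is not None and b is not None]
            if len(pairs) < 2:
                continue
            ref_v, dev_v = map(np.array, zip(*pairs))
            t, df, p = paired_t(dev_v, ref_v)
            stats_rows.append(dict(test="paired_t_direction", organ=organ,
                                   comparison=f"{s.setup_id} vs reference",
                                   statistic=t, df=df, p_adjusted=p,
                                   F=np.nan, p_anova=np.nan, n=len(pairs)))

    # Bland-Altman: single vs dual relative differences, per matched setup
    singles = {s.setup_id: s for s in setups if s.setup_id.endswith("_single")}
    for sid, s in singles.items():
        did = sid[: -len("_single")] + "_dual"
        for organ in organs:
            xs, xd = [], []
            for m in model_ids:
                ref = doses[m]["reference"].get(organ)
                a = doses[m].get(sid, {}).get(organ)
                b = doses[m].get(did, {}).get(organ)
                if None in (ref, a, b):
                    continue
                xs.append(relative_difference(a, ref))
                xd.append(relative_difference(b, ref))
            if len(xs) < 2:
                continue
            ba = bland_altman(np.array(xs), np.array(xd))
            stats_rows.append(dict(
                test="bland_altman_single_vs_dual", organ=organ,
                comparison=sid[: -len("_single")], statistic=ba.bias,
                df=ba.n - 1, p_adjusted=ba.p_bias, F=np.nan, p_anova=np.nan,
                n=ba.n, sd=ba.sd, loa_low=ba.loa_low, loa_high=ba.loa_high))
    return stats_rows


def run_grid(config: ExperimentConfig) -> ResultBundle:
    """Execute the full deviation grid and assemble the result bundle."""
    runner = _Runner(config)
    setups = build_setups(config)
    ref = run_reference(config, runner)
    organ_table: OrganDoseTable = ref["organ_doses"]
    rel_table = RelDiffTable()

    # doses[model][setup][organ]
    doses: dict[str, dict[str, dict[str, float]]] = {
        mid: {"reference": organs} for mid, organs in ref["reference_doses"].items()}

    complete = True
    status: dict[str, str] = {"reference": "ok"}
    for setup in setups:
        if setup.family == "reference":
            continue
        try:
            for model in runner.models:
                profile = runner.model_profile(model, setup)
                dosemap = runner.simulate(model, setup, profile)
                rows = organ_dose(dosemap, model, scanner=config.archetype,
                                  setup_id=setup.setup_id)
                organ_table.extend(rows)
                doses[model.model_id][setup.setup_id] = {
                    r.organ: r.mean_dose_mgy for r in rows}
            status[setup.setup_id] = "ok"
        except Exception as exc:  # partial failure: mark and continue
            complete = False
            status[setup.setup_id] = f"failed: {exc}"

    for model in runner.models:
        mid = model.model_id
        for setup in setups:
            per = doses[mid].get(setup.setup_id)
            if per is None:
                continue
            for organ, dev in per.items():
                rel_table.append(mid, config.archetype, setup.setup_id, organ,
                                 dev, doses[mid]["reference"][organ])

    stats_rows = _family_stats(config, setups, doses, runner.models)
    bundle = ResultBundle(
        config=config, organ_doses=organ_table, rel_diffs=rel_table,
        stats=stats_rows, setups=setups,
        metadata=dict(n_models=len(runner.models), setup_status=status),
        complete=complete)
    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle


def summarize(bundle: ResultBundle, outdir=None, allow_partial: bool = False,
              plots: bool = False):
    """Mean +- SD relative dose difference per (setup, organ), plus plots.

    Refuses an incomplete bundle unless ``allow_partial`` is set.
    """
    if not bundle.complete and not allow_partial:
        raise ValueError("bundle incomplete; pass allow_partial=True to "
                         "summarise anyway")
    import pandas as pd

    df = bundle.rel_diffs.to_frame()
    summary = (df.groupby(["scanner", "setup_id", "organ"])["rel_diff_pct"]
               .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
               .reset_index())
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "summary_rel_diff.csv", index=False)
        if plots:
            _summary_plots(summary, outdir)
    return summary


def _summary_plots(summary, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for scanner, grp in summary.groupby("scanner"):
        fig, ax = plt.subplots(figsize=(10, 4))
        setups = sorted(grp["setup_id"].unique())
        organs = sorted(grp["organ"].unique())
        width = 0.8 / max(len(organs), 1)
        xs = np.arange(len(setups))
        for i, organ in enumerate(organs):
            sub = grp[grp["organ"] == organ].set_index("setup_id")
            means = [sub["mean"].get(s, np.nan) for s in setups]
            sds = [sub["sd"].get(s, np.nan) for s in setups]
            ax.bar(xs + i * width, means, width, yerr=sds, label=organ,
                   capsize=2)
        ax.axhspan(-10, 10, color="0.9", zorder=0)
        ax.set_xticks(xs + 0.4)
        ax.set_xticklabels(setups, rotation=90, fontsize=7)
        ax.set_ylabel("relative dose difference (%)")
        ax.set_title(scanner)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / f"rel_diff_{scanner}.png", dpi=120)
        plt.close(fig)
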