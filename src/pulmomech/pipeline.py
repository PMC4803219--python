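"""Study orchestration: run every modality pipeline from one YAML config,
aggregate per-animal results, apply the comparison plan (two-group tests on
elastances and Lm, region x strain and frequency x strain ANOVAs), and write
a report with full provenance (config echo, seeds, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .afmmech import (ForceCurve, PowerLawFit, aggregate_E, compute_gstar,
                      fit_hertz, fit_two_powerlaw)
from .errors import ConfigurationError
from .morpho import MorphoConfig, compute_lm
from .stats import compare_two_groups, holm_sidak, two_way_anova
from .synthgen import (AlveolarImageSpec, CohortSpec, LungModelParams,
                       ManeuverSpec, generate_alveolar_image, generate_cohort,
                       params_for_ratio, simulate_force_curve,
                       simulate_multifreq)
from .ventmech import VentConfig, compute_elastances

_FLOAT_FMT = "%.10g"


@dataclass
class StudyConfig:
    """One structured configuration for a full synthetic study."""

    seed: int = 0
    n_per_group: int = 6
    out_dir: str = "study_out"
    # ventilation
    groups: dict = field(default_factory=lambda: {
        "WT": {"Est_true": 22.4, "Raw": 0.5, "PEEP": 0.0, "noise_sd": 0.02},
        "MFS": {"Est_true": 14.1, "Raw": 0.5, "PEEP": 0.0, "noise_sd": 0.02},
    })
    edyn_est_ratio: float = 1.15
    between_animal_cv: float = 0.05
    maneuver: dict = field(default_factory=lambda: {
        "VT": 0.30, "rate": 100.0, "fs": 100.0,
        "n_breaths_before_occlusion": 6, "n_occlusions": 2,
        "cannula_k1": 0.3, "cannula_k2": 0.02,
    })
    vent_thresholds: dict = field(default_factory=dict)
    # AFM
    powerlaw: dict = field(default_factory=lambda: {
        "WT": {"A": 9.40, "B": 0.016, "alpha": 0.084},
        "MFS": {"A": 10.34, "B": 0.036, "alpha": 0.089},
    })
    region_E_kpa: dict = field(default_factory=lambda: {
        "pleura": 5.0, "alveolar septum": 5.0,
        "vessel adventitia": 5.0, "vessel media": 15.0,
    })
    region_cv: float = 0.2
    afm_design: dict = field(default_factory=lambda: {
        "n_sites": 1, "n_points": 3, "n_curves": 2, "curve_samples": 150})
    multifreq: dict = field(default_factory=lambda: {
        "duration": 140.0, "fs": 50.0, "amplitude": 75.0,
        "b_h": 2e-6, "noise_sd": 0.01})
    # morphometry
    lm_pitch_um: dict = field(default_factory=lambda: {"WT": 43.2, "MFS": 69.9})
    lm_image: dict = field(default_factory=lambda: {
        "size_px": 600, "px_size": 1.0, "wall_um": 2.0, "noise_sd": 8.0})
    morpho_thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyReport:
    summary: dict
    tables: dict                 # name -> DataFrame
    errors: list
    provenance: dict

    @property
    def ok(self) -> bool:
        return not self.errors


def _config_hash(cfg: StudyConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _mean_se(x) -> dict:
    x = np.asarray(x, dtype=float)
    return {"mean": float(np.mean(x)),
            "se": float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0,
            "n": int(x.size)}


def _vent_stage(cfg: StudyConfig, seeds: np.random.SeedSequence):
    maneuver = ManeuverSpec(**cfg.maneuver)
    rng = np.random.default_rng(seeds.spawn(1)[0])
    means = {}
    for g, p in cfg.groups.items():
        base = LungModelParams(**p)
        tuned = params_for_ratio(base.Est_true, maneuver, ratio=cfg.edyn_est_ratio,
                                 Raw=base.Raw, PEEP=base.PEEP,
                                 noise_sd=base.noise_sd)
        means[g] = tuned
    cohort = CohortSpec(n_per_group=cfg.n_per_group, group_means=means,
                        between_animal_cv=cfg.between_animal_cv,
                        seed=int(rng.integers(2**31 - 1)))
    recordings, truth = generate_cohort(cohort, maneuver)
    vcfg = VentConfig(**cfg.vent_thresholds)
    rows = []
    for g, recs in recordings.items():
        for i, rec in enumerate(recs):
            res = compute_elastances(rec, vcfg)
            rows.append({"group": g, "animal": i, "Est": res.Est_mean,
                         "Edyn": res.Edyn_mean, "ratio": res.ratio_dyn_st})
    per_animal = pd.DataFrame(rows)
    return per_animal, truth


def _afm_stage(cfg: StudyConfig, seeds: np.random.SeedSequence):
    rng = np.random.default_rng(seeds.spawn(1)[0])
    d = cfg.afm_design
    sigma = float(np.sqrt(np.log1p(cfg.region_cv**2)))
    curve_rows = []
    for g in cfg.groups:
        for animal in range(cfg.n_per_group):
            for region, e_kpa in cfg.region_E_kpa.items():
                for site in range(d["n_sites"]):
                    for point in range(d["n_points"]):
                        e_true = e_kpa * 1e3 * float(
                            rng.lognormal(-0.5 * sigma**2, sigma))
                        for curve in range(d["n_curves"]):
                            fc = simulate_force_curve(
                                E_true=e_true, n_samples=d["curve_samples"],
                                noise_sd=0.3,
                                seed=int(rng.integers(2**31 - 1)))
                            fit = fit_hertz(fc)
                            curve_rows.append({
                                "group": g, "animal": animal, "region": region,
                                "site": site, "point": point, "curve": curve,
                                "E": fit.E, "converged": fit.converged})
    curves = pd.DataFrame(curve_rows)

    mf = cfg.multifreq
    pl_rows = []
    gstar_rows = []
    for g, p in cfg.powerlaw.items():
        for animal in range(cfg.n_per_group):
            jitter = float(rng.lognormal(-0.5 * sigma**2, sigma))
            truth = PowerLawFit(A=p["A"] * jitter, B=p["B"], alpha=p["alpha"])
            rec = simulate_multifreq(truth, duration=mf["duration"],
                                     fs=mf["fs"], amplitude=mf["amplitude"],
                                     b_h=mf["b_h"], noise_sd=mf["noise_sd"],
                                     seed=int(rng.integers(2**31 - 1)))
            gs = compute_gstar(rec)
            fit = fit_two_powerlaw(gs)
            pl_rows.append({"group": g, "animal": animal, "A": fit.A,
                            "B": fit.B, "alpha": fit.alpha})
            for f, gp, gl in zip(gs.freqs, gs.g_storage, gs.g_loss):
                gstar_rows.append({"group": g, "animal": animal,
                                   "freq_hz": f, "G_storage": gp, "G_loss": gl})
    return curves, pd.DataFrame(pl_rows), pd.DataFrame(gstar_rows)


def _morpho_stage(cfg: StudyConfig, seeds: np.random.SeedSequence):
    rng = np.random.default_rng(seeds.spawn(1)[0])
    im = cfg.lm_image
    mcfg = MorphoConfig(**cfg.morpho_thresholds)
    rows = []
    for g, pitch in cfg.lm_pitch_um.items():
        for animal in range(cfg.n_per_group):
            spec = AlveolarImageSpec(
                width_px=im["size_px"], height_px=im["size_px"],
                px_size=im["px_size"], cell_pitch=pitch,
                wall_thickness=im["wall_um"], noise_sd=im["noise_sd"],
                seed=int(rng.integers(2**31 - 1)))
            res = compute_lm(generate_alveolar_image(spec), mcfg)
            rows.append({"group": g, "animal": animal, "Lm": res.Lm,
                         "n_intercepts": res.n_intercepts})
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full study pattern and write report + per-sample CSVs.

    Stage failures are collected in ``report.errors``; completed stages are
    still reported.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = root.spawn(3)
    groups = list(config.groups)
    summary: dict = {"groups": {g: {} for g in groups}, "tests": {}}
    tables: dict = {}
    errors: list = []

    try:
        per_animal, truth = _vent_stage(config, stage_seeds[0])
        tables["elastance_per_animal"] = per_animal
        tables["cohort_truth"] = truth
        for g in groups:
            sub = per_animal[per_animal["group"] == g]
            summary["groups"][g]["Est"] = _mean_se(sub["Est"])
            summary["groups"][g]["Edyn"] = _mean_se(sub["Edyn"])
            summary["groups"][g]["Edyn_Est_ratio"] = _mean_se(sub["ratio"])
        if len(groups) >= 2:
            a, b = groups[:2]
            for var in ("Est", "Edyn"):
                res = compare_two_groups(
                    per_animal.loc[per_animal["group"] == a, var],
                    per_animal.loc[per_animal["group"] == b, var])
                summary["tests"][f"{var}_{a}_vs_{b}"] = dataclasses.asdict(res)
    except Exception as exc:  # noqa: BLE001 - partial report by contract
        errors.append({"stage": "ventilation", "error": repr(exc)})

    try:
        curves, powerlaw, gstar = _afm_stage(config, stage_seeds[1])
        tables["afm_curve_fits"] = curves
        tables["powerlaw_per_animal"] = powerlaw
        tables["gstar_per_animal"] = gstar
        hier = aggregate_E(curves)
        tables["afm_region_means"] = hier.region_means
        for g, p in powerlaw.groupby("group"):
            summary["groups"][g]["powerlaw"] = {
                k: _mean_se(p[k]) for k in ("A", "B", "alpha")}
        region_aov = two_way_anova(
            curves.groupby(["group", "animal", "region"], as_index=False)["E"].mean(),
            dv="E", factor_a="group", factor_b="region")
        summary["tests"]["region_by_strain_anova"] = {
            e: dict(zip(("F", "p"), region_aov.effect(e)))
            for e in region_aov.table.index}
        gstar_aov = two_way_anova(gstar, dv="G_storage", factor_a="group",
                                  factor_b="freq_hz")
        summary["tests"]["frequency_by_strain_anova"] = {
            e: dict(zip(("F", "p"), gstar_aov.effect(e)))
            for e in gstar_aov.table.index}
        raw_p = [summary["tests"]["region_by_strain_anova"][e]["p"]
                 for e in region_aov.table.index]
        hs = holm_sidak(raw_p)
        summary["tests"]["region_by_strain_holm_sidak"] = {
            e: {"p_adj": float(pa), "reject": bool(r)}
            for e, pa, r in zip(region_aov.table.index, hs.adjusted, hs.reject)}
    except Exception as exc:  # noqa: BLE001
        errors.append({"stage": "afm", "error": repr(exc)})

    try:
        lm = _morpho_stage(config, stage_seeds[2])
        tables["lm_per_animal"] = lm
        for g in groups:
            summary["groups"][g]["Lm"] = _mean_se(lm.loc[lm["group"] == g, "Lm"])
        if len(groups) >= 2:
            a, b = groups[:2]
            res = compare_two_groups(lm.loc[lm["group"] == a, "Lm"],
                                     lm.loc[lm["group"] == b, "Lm"])
            summary["tests"][f"Lm_{a}_vs_{b}"] = dataclasses.asdict(res)
    except Exception as exc:  # noqa: BLE001
        errors.append({"stage": "morphometry", "error": repr(exc)})

    provenance = {"package_version": __version__, "seed": config.seed,
                  "config_hash": _config_hash(config),
                  "config": config.to_dict()}
    report = StudyReport(summary=summary, tables=tables, errors=errors,
                         provenance=provenance)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
    (out / "report.json").write_text(json.dumps(
        {"summary": summary, "errors": errors, "provenance": provenance},
        indent=2, default=float))
    return report


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the canonical cross-module fixtures with a checksum manifest.

    Noiseless artifacts are seed-independent; stochastic ones derive their
    streams from ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    s_noise = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(3)]

    maneuver = ManeuverSpec(VT=0.30, n_breaths_before_occlusion=4,
                            cannula_k1=0.3, cannula_k2=0.02)
    params = params_for_ratio(22.4, maneuver)
    from .synthgen import simulate_ventilation
    rec = simulate_ventilation(params, maneuver)
    rec.to_tsv(out / "recording_noiseless.tsv")

    fc = simulate_force_curve(E_true=1e4)
    fc.to_tsv(out / "force_curve_noiseless.tsv")

    mf = simulate_multifreq(PowerLawFit(A=9.40, B=0.016, alpha=0.084),
                            duration=140.0, fs=50.0)
    mf.to_tsv(out / "multifreq_noiseless.tsv")

    img = generate_alveolar_image(AlveolarImageSpec(
        width_px=512, height_px=512, cell_pitch=40.0, wall_thickness=2.0,
        noise_sd=8.0, seed=s_noise[0]))
    img.save(out / "alveolar_lattice.png")

    cohort = CohortSpec(
        n_per_group=3,
        group_means={"WT": LungModelParams(Est_true=22.4),
                     "MFS": LungModelParams(Est_true=22.4 * 0.63)},
        between_animal_cv=0.05, seed=s_noise[1])
    _, truth = generate_cohort(cohort, maneuver)
    truth.to_csv(out / "cohort_truth.csv", index=False, float_format=_FLOAT_FMT)

    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json":
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
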