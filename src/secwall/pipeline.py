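"""End-to-end analysis pipeline and its configuration.

Orchestrates the full inference sequence — hard-disk Monte Carlo →
structure-factor table → SAXS radius scan → WAXS peak fit → 1D/2D NMR
quantitation → stoichiometric wall model — from a single validated
key-value configuration, writing one JSON master report (all physical
quantities carry explicit unit strings) plus per-stage CSV artefacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import harddisk, nmr, saxs, scattering, wallmodel, waxs

log = logging.getLogger("secwall")

_KNOWN_KEYS = {
    "seed",
    "output_dir",
    "saxs_profile",
    "waxs_profile",
    "nmr_spectrum",
    "crosspeak_table",
    "mc",
    "saxs_fit",
    "waxs_fit",
    "nmr_quant",
    "wall",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Unknown top-level keys are rejected; every stochastic stage draws its
    seed from the single top-level ``seed``.
    """

    seed: int = 0
    output_dir: str = "secwall_out"
    saxs_profile: Optional[str] = None
    waxs_profile: Optional[str] = None
    nmr_spectrum: Optional[str] = None
    crosspeak_table: Optional[str] = None
    mc: dict = field(default_factory=dict)
    saxs_fit: dict = field(default_factory=dict)
    waxs_fit: dict = field(default_factory=dict)
    nmr_quant: dict = field(default_factory=dict)
    wall: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _mc_stage(cfg: PipelineConfig) -> dict:
    p = cfg.mc
    radius = float(p.get("radius_phys", 13.5))
    sheath = float(p.get("sheath", 4.7))
    phi_phys = float(p.get("phi_phys", 0.29))
    n_disks = int(p.get("n_disks", 2000))
    distances = [float(d) for d in p.get("shell_distances", (6.0, 10.0))]
    r_eff = harddisk.effective_radius(radius, sheath)
    phi_eff = harddisk.effective_area_fraction(phi_phys, radius, r_eff)
    settings = harddisk.MCSettings(equil_sweeps=int(p.get("equil_sweeps", 2000)))
    config = harddisk.generate_configuration(
        n_disks, phi_eff, r_eff, radius, seed=cfg.seed, settings=settings
    )
    prox = harddisk.proximity_fractions(
        config,
        distances=distances,
        grid_spacing=float(p.get("grid_spacing", 1.0)),
    )
    return {
        "radius_phys": {"value": radius, "unit": "angstrom"},
        "radius_eff": {"value": r_eff, "unit": "angstrom"},
        "phi_phys": {"value": phi_phys, "unit": "1"},
        "phi_eff": {"value": phi_eff, "unit": "1"},
        "n_disks": config.n_disks,
        "shell_fractions": {
            f"{d:g}": {"value": float(f), "unit": "1"}
            for d, f in zip(prox.shell_distances, prox.matrix_fraction_within)
        },
        "_config": config,
    }


def _saxs_stage(cfg: PipelineConfig, mc_report: dict) -> dict:
    p = cfg.saxs_fit
    profile = scattering.read_profile(cfg.saxs_profile)
    radii = [float(r) for r in p.get("radii", np.arange(13.0, 15.51, 0.5))]
    sheath = float(p.get("sheath", 4.7))
    phi_eff = float(p.get("phi_eff", mc_report["phi_eff"]["value"]))
    q_window = tuple(p.get("q_window", saxs.DEFAULT_Q_WINDOW))
    table_path = p.get("sf_table")
    if table_path:
        table = harddisk.StructureFactorTable.load(table_path)
    else:
        r_eff_max = harddisk.effective_radius(max(radii), sheath)
        x_hi = min(q_window[1] * r_eff_max * 1.05, 20.0)
        table = harddisk.build_structure_factor_table(
            phi_grid=[phi_eff],
            x_grid=np.linspace(0.2, x_hi, 80),
            n_disks=int(p.get("table_disks", 1000)),
            seed=cfg.seed + 1,
        )
    scan = saxs.radius_scan(profile, radii, phi_eff, sheath, table, q_window=q_window)
    return {
        "best_radius": {"value": scan.best_radius, "unit": "angstrom"},
        "radii": list(scan.radii),
        "residuals": [float(r) for r in scan.residuals],
        "scale": {"value": float(scan.best_model.scale), "unit": "a.u."},
        "background": {"value": float(scan.best_model.background), "unit": "a.u."},
        "surface_coeff": {
            "value": float(scan.best_model.surface_coeff),
            "unit": "a.u.*angstrom^-3",
        },
    }


def _waxs_stage(cfg: PipelineConfig) -> dict:
    p = cfg.waxs_fit
    profile = scattering.read_profile(cfg.waxs_profile)
    init = p.get("init", [[1.13, 0.25, 0.5, 1.0], [1.55, 0.18, 0.5, 1.0]])
    peaks0 = [waxs.DiffractionPeak(*row) for row in init]
    window = tuple(p.get("fit_window", waxs.DEFAULT_FIT_WINDOW))
    peaks, diag = waxs.fit_equatorial_peaks(profile, len(peaks0), peaks0, window)
    d_ref = float(p.get("d200_reference", 3.86))
    out = {"peaks": [], "residual_norm": diag["residual_norm"]}
    for pk in peaks:
        d = waxs.d_spacing(pk.center)
        out["peaks"].append(
            {
                "center": {"value": pk.center, "unit": "angstrom^-1"},
                "fwhm": {"value": pk.fwhm, "unit": "angstrom^-1"},
                "eta": pk.eta,
                "d_spacing": {"value": d, "unit": "angstrom"},
                "scherrer_size": {"value": waxs.scherrer_size(pk.fwhm), "unit": "angstrom"},
            }
        )
    d200 = out["peaks"][-1]["d_spacing"]["value"]
    out["lattice_expansion_200"] = {
        "value": waxs.relative_expansion(d200, d_ref),
        "unit": "percent",
    }
    return out


def _nmr_stage(cfg: PipelineConfig) -> dict:
    spectrum = nmr.read_spectrum(cfg.nmr_spectrum)
    fractions = nmr.integrate_regions(spectrum)
    overall_2f = nmr.twofold_fraction(fractions["c1"], fractions["c4_twofold"])
    cellulose_share = float(cfg.nmr_quant.get("cellulose_share", 0.6))
    xylan_2f = nmr.xylan_twofold_share(overall_2f, cellulose_share)
    interior, surface = nmr.interior_surface_split(
        fractions["c4_interior"], fractions["c4_surface"]
    )
    xylan_residue_frac = float(
        cfg.nmr_quant.get(
            "xylan_residue_frac", fractions["c1"] * (1.0 - cellulose_share)
        )
    )
    acet = nmr.acetylation_degree(xylan_residue_frac, fractions["acetyl_co"])
    report = {
        "region_fractions": {k: {"value": v, "unit": "1"} for k, v in fractions.items()},
        "twofold_fraction": {"value": overall_2f, "unit": "1"},
        "xylan_twofold_share": {"value": xylan_2f, "unit": "1"},
        "interior_fraction": {"value": interior, "unit": "1"},
        "surface_fraction": {"value": surface, "unit": "1"},
        "acetylation_every_n_residues": {"value": acet, "unit": "residues"},
    }
    if cfg.crosspeak_table:
        table = nmr.CrossPeakTable.load(cfg.crosspeak_table)
        table = nmr.classify_cross_peaks(table)
        matrix = nmr.chord_weights(table)
        report["crosspeak_classes"] = {
            cls: sum(1 for p in table.peaks if p.peak_class == cls)
            for cls in ("strong", "medium", "weak")
        }
        report["_chord_matrix"] = matrix
    return report


def _wall_stage(cfg: PipelineConfig, nmr_report: Optional[dict]) -> dict:
    p = cfg.wall
    sugars = wallmodel.SugarComposition(*p.get("sugar_ratio", (53.0, 37.0, 4.0)))
    carb_lignin = tuple(p.get("carb_to_lignin", (65.0, 20.0)))
    moisture = float(p.get("moisture_dry_basis", 0.30))
    stoich = wallmodel.per_fibril_counts(sugars, carb_lignin, moisture)
    radius = wallmodel.fibril_radius_from_chains(
        rise_per_residue=float(p.get("rise_per_residue", 5.19)),
        density=float(p.get("cellulose_density", 1.6)),
    )
    if nmr_report is not None:
        share = nmr_report["xylan_twofold_share"]["value"]
    else:
        share = float(p.get("xylan_twofold_share", 0.583))
    n2, n3 = wallmodel.conformer_allocation(stoich.xylose, share)
    carb, lignin = carb_lignin
    glc_mass = sugars.glucose / (sugars.glucose + sugars.xylose + sugars.arabinose)
    masses = {
        "cellulose": carb * glc_mass,
        "hemicellulose": carb * (1.0 - glc_mass),
        "lignin": lignin,
    }
    fractions = wallmodel.volume_fractions(masses, moisture_dry_basis=moisture)
    return {
        "per_fibril_counts": {
            "exact": {
                "xylose": stoich.xylose,
                "arabinose": stoich.arabinose,
                "lignin": stoich.lignin,
                "water": stoich.water,
            },
            "rounded": stoich.rounded,
        },
        "fibril_radius": {"value": radius, "unit": "angstrom"},
        "water_molecular_volume": {
            "value": wallmodel.molecular_volume(),
            "unit": "angstrom^3",
        },
        "xylose_conformers": {"twofold": n2, "threefold": n3},
        "volume_fractions": {k: {"value": v, "unit": "1"} for k, v in fractions.items()},
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the JSON master report.

    Stages with no configured input are skipped.  Any stage failure is
    re-raised with the stage name; previously completed stage outputs
    are preserved in the report file.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema": "secwall-report/1", "seed": config.seed}
    stages = [("mc", lambda: _mc_stage(config))]
    if config.saxs_profile:
        stages.append(("saxs", lambda: _saxs_stage(config, report["mc"])))
    if config.waxs_profile:
        stages.append(("waxs", lambda: _waxs_stage(config)))
    if config.nmr_spectrum:
        stages.append(("nmr", lambda: _nmr_stage(config)))
    stages.append(("wall", lambda: _wall_stage(config, report.get("nmr"))))

    try:
        for name, fn in stages:
            log.info("running stage %s", name)
            result = fn()
            # side artefacts out, JSON-serialisable report in
            cfg_obj = result.pop("_config", None)
            if cfg_obj is not None:
                cfg_obj.save(out_dir / "disk_configuration.csv")
            chord = result.pop("_chord_matrix", None)
            if chord is not None:
                chord.to_frame().to_csv(out_dir / "chord_matrix.csv")
            report[name] = result
    except Exception as exc:
        _write_report(out_dir, report)
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    _write_report(out_dir, report)
    return report


def _write_report(out_dir: Path, report: dict) -> None:
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True, default=lambda o: float(o)) + "\n"
    )
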