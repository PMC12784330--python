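"""End-to-end pipeline driver: simulate -> thermo -> qha -> consensus ->
expansion -> packing, with per-stage CSV/JSON outputs and a reproducibility
log.  Identical (config, seed) re-runs are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calorimetry import consensus_pipeline, fit_cp, onset_range_variation, solubility_crossing
from .config import RunConfig
from .constants import CELSIUS_OFFSET
from .expansion import ExpansionModel, LatticeSeries, pdv_term, percent_change
from .harmonic import PhononSpectrum, pair_analysis
from .io import read_cif, read_table, write_cif, write_table
from .packing import build_cluster, overlay
from .quasiharmonic import QhaModel, VolumeGrid
from . import synthetic

log = logging.getLogger("crystherm")

STAGE_ORDER = ("simulate", "thermo", "qha", "consensus", "expansion", "packing")

#: inputs each stage needs on disk, produced by `simulate` (or the user)
STAGE_INPUTS = {
    "thermo": ["phonon_A.csv", "phonon_B.csv", "phonon_meta.json"],
    "qha": ["phonon_A.csv", "phonon_meta.json"],
    "consensus": ["cp.csv", "dsc.csv"],
    "expansion": ["lattice.csv"],
    "packing": ["polytype_A.cif", "polytype_B.cif"],
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def make_volume_grid(spec: PhononSpectrum, v0_a3: float | None = None,
                     bulk_scale: float = 2.0e3, gamma: float = 1.0,
                     gamma_cutoff_cm1: float = 300.0,
                     n_volumes: int = 7, span: float = 0.08) -> VolumeGrid:
    """Einstein-solid volume grid around ``v0_a3``: quadratic static energy
    and constant-Grueneisen frequency scaling nu(V) = nu0 (V0/V)^gamma.

    ``bulk_scale`` sets the E(V) curvature in kJ/mol of molecules per
    fractional strain squared; 2000 gives a bulk modulus near 10 GPa at a
    323 A^3 molecular volume, typical of an organic crystal (the default
    volume, per molecule).  Only lattice modes below ``gamma_cutoff_cm1``
    are volume-sensitive: intramolecular vibrations have near-zero
    Grueneisen parameters and scaling them too would swamp E(V) with
    zero-point pressure.
    """
    if v0_a3 is None:
        v0_a3 = 323.0 * spec.z
    volumes = v0_a3 * (1.0 + span * np.linspace(-1, 1, n_volumes))
    energies = bulk_scale * ((volumes - v0_a3) / v0_a3) ** 2 / 2.0 + spec.lattice_energy
    gammas = np.where(spec.frequencies < gamma_cutoff_cm1, gamma, 0.0)
    spectra = [
        PhononSpectrum(spec.frequencies * (v0_a3 / v) ** gammas,
                       spec.weights.copy(), z=spec.z,
                       lattice_energy=0.0, label=spec.label)
        for v in volumes
    ]
    return VolumeGrid(volumes, energies, spectra)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages in order; returns the report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in config.stages]
    for stage in stages:
        for fname in STAGE_INPUTS.get(stage, []):
            if "simulate" not in stages and not (out / fname).exists():
                raise ValueError(
                    f"stage {stage!r} needs {fname}, which neither exists in "
                    f"{out} nor is produced by a requested 'simulate' stage"
                )

    report: dict = {
        "config": config.to_dict(),
        "versions": {"crystherm": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    t_grid = np.arange(config.t_start_k, config.t_stop_k + 0.5 * config.t_step_k,
                       config.t_step_k)

    for stage in stages:
        params = config.stage_params.get(stage, {})
        inputs = {f: _sha256(out / f) for f in STAGE_INPUTS.get(stage, [])
                  if (out / f).exists()}
        log.info("stage %s: params=%s input checksums=%s", stage, params, inputs)
        handler = globals()[f"_stage_{stage}"]
        report["stages"][stage] = handler(config, params, out, t_grid)
        report["stages"][stage]["input_checksums"] = inputs

    _dump_json(report, out / "report.json")
    return report


def _stage_simulate(config: RunConfig, params: dict, out: Path, t_grid) -> dict:
    seed = config.seed
    spec_a, spec_b, crossing = synthetic.make_phonon_pair(
        synthetic.DEFAULT_ENANTIOTROPIC_SPEC, seed=seed)
    for name, spec in (("A", spec_a), ("B", spec_b)):
        write_table(pd.DataFrame({"freq_cm1": spec.frequencies,
                                  "weight": spec.weights}),
                    out / f"phonon_{name}.csv", schema="phonon")
    _dump_json({"e_latt_A_kJ_per_mol": spec_a.lattice_energy,
                "e_latt_B_kJ_per_mol": spec_b.lattice_energy,
                "z": spec_a.z, "true_crossing_K": crossing},
               out / "phonon_meta.json")

    write_table(synthetic.make_cp_dataset(seed=seed + 1), out / "cp.csv", schema="cp")
    write_table(synthetic.make_dsc_dataset(synthetic.DEFAULT_DSC_SPEC, seed=seed + 2),
                out / "dsc.csv", schema="dsc")
    write_table(synthetic.make_lattice_series((9.0, 10.0, 14.5), seed=seed + 3),
                out / "lattice.csv", schema="lattice")
    write_table(synthetic.make_solubility_dataset(seed=seed + 4),
                out / "solubility.csv", schema="solubility")
    st_a, st_b = synthetic.make_polytype_pair()
    write_cif(st_a, out / "polytype_A.cif")
    write_cif(st_b, out / "polytype_B.cif")
    return {"true_crossing_K": crossing}


def _load_spectra(out: Path) -> tuple[PhononSpectrum, PhononSpectrum]:
    meta = json.loads((out / "phonon_meta.json").read_text())
    specs = []
    for name, e_key in (("A", "e_latt_A_kJ_per_mol"), ("B", "e_latt_B_kJ_per_mol")):
        tab = read_table(out / f"phonon_{name}.csv", "phonon")
        specs.append(PhononSpectrum(tab["freq_cm1"].to_numpy(),
                                    tab["weight"].to_numpy(),
                                    z=meta["z"], lattice_energy=meta[e_key],
                                    label=name))
    return specs[0], specs[1]


def _stage_thermo(config: RunConfig, params: dict, out: Path, t_grid) -> dict:
    spec_a, spec_b = _load_spectra(out)
    pair = pair_analysis(spec_a, spec_b, t_grid)
    pair.curve_a.to_frame().to_csv(out / "thermo_A.csv", index=False)
    pair.curve_b.to_frame().to_csv(out / "thermo_B.csv", index=False)
    result = {
        "transition_temperatures_K": pair.transition_temperatures,
        "transition_temperatures_C": [t - CELSIUS_OFFSET
                                      for t in pair.transition_temperatures],
        "delta_zpe_kJ_per_mol": pair.delta_zpe / 1000.0,
    }
    _dump_json(result, out / "pair_result.json")
    return result


def _stage_qha(config: RunConfig, params: dict, out: Path, t_grid) -> dict:
    spec_a, _ = _load_spectra(out)
    grid = make_volume_grid(spec_a, **params)
    qha = QhaModel(grid, pressure_pa=config.pressure_pa).fit(t_grid)
    pd.DataFrame({
        "T_K": qha.temperatures, "V_eq_A3": qha.v_eq, "alpha_per_K": qha.alpha,
        "K_Pa": qha.bulk_modulus, "G_J_per_mol": qha.gibbs,
        "Cv_J_per_molK": qha.cv, "Cp_J_per_molK": qha.cp,
        "Cp_pointwise_J_per_molK": qha.cp_pointwise,
    }).to_csv(out / "qha.csv", index=False)
    i300 = int(np.argmin(np.abs(qha.temperatures - 300.0)))
    return {"alpha_300K_per_K": float(qha.alpha[i300]),
            "K_300K_GPa": float(qha.bulk_modulus[i300] / 1e9),
            "cp_minus_cv_300K": float(qha.cp[i300] - qha.cv[i300])}


def _stage_consensus(config: RunConfig, params: dict, out: Path, t_grid) -> dict:
    cp_tab = read_table(out / "cp.csv", "cp")
    dsc_tab = read_table(out / "dsc.csv", "dsc")
    fit_i = fit_cp(cp_tab, params.get("form_product", "I"))
    fit_ii = fit_cp(cp_tab, params.get("form_reactant", "II"))
    res = consensus_pipeline(dsc_tab, fit_i, fit_ii, config.tref_k,
                             unit=params.get("unit", "lab"))
    t_curve = np.arange(max(250.0, t_grid[0]), min(460.0, t_grid[-1]), 1.0)
    pd.DataFrame({"T_K": t_curve,
                  "dH_kJ_per_mol": res.curve(t_curve)}).to_csv(
        out / "enthalpy_curve.csv", index=False)
    variation = onset_range_variation(res.curve, 423.15, 443.15)
    sol = read_table(out / "solubility.csv", "solubility") \
        if (out / "solubility.csv").exists() else None
    result = {
        "dH_ref_kJ_per_mol": res.consensus.mean,
        "ci95_halfwidth_kJ_per_mol": res.consensus.ci_halfwidth,
        "tau2": res.consensus.tau2,
        "q": res.consensus.q,
        "dH_at_report_T_kJ_per_mol": float(res.curve(config.report_t_k)),
        "onset_range_variation_kJ_per_mol": variation,
    }
    if sol is not None:
        forms = sorted(sol["form"].unique())
        pts = [sol[sol["form"] == f][["T_C", "solubility_mg_per_g"]].to_numpy()
               for f in forms[:2]]
        result["solubility_crossing_C"] = solubility_crossing(*pts)
    _dump_json(result, out / "consensus.json")
    return result


def _stage_expansion(config: RunConfig, params: dict, out: Path, t_grid) -> dict:
    series = LatticeSeries(read_table(out / "lattice.csv", "lattice"),
                           z=params.get("z", 4),
                           molar_mass=params.get("molar_mass", 264.30))
    fit = ExpansionModel(series, degree=params.get("degree", 2)).fit()
    tmin = float(series.table["T_K"].min())
    tmax = float(series.table["T_K"].max())
    result = {
        "volume_percent_change": percent_change(fit, "V", tmin, tmax),
        "axial_percent_change": {q: percent_change(fit, q, tmin, tmax)
                                 for q in "abc"},
        "alpha_V_per_K_midrange": float(fit.alpha("V", 0.5 * (tmin + tmax))),
        "pdv_term_kJ_per_mol": pdv_term(params.get("v_molA_a3", 323.0),
                                        params.get("v_molB_a3", 300.0),
                                        config.pressure_pa),
    }
    _dump_json(result, out / "expansion.json")
    return result


def _stage_packing(config: RunConfig, params: dict, out: Path, t_grid) -> dict:
    n = params.get("n", 30)
    st_a = read_cif(out / "polytype_A.cif")
    st_b = read_cif(out / "polytype_B.cif")
    cl_a = build_cluster(st_a, n, central=params.get("central", 0))
    cl_b = build_cluster(st_b, n, central=params.get("central", 0))
    res = overlay(cl_a, cl_b,
                  dist_tol=params.get("dist_tol", 0.2),
                  ang_tol_deg=params.get("ang_tol", 25.0),
                  allow_inversion=params.get("allow_inversion", True))
    result = {"n_matched": res.n_matched, "n": res.n, "rmsd_A": res.rmsd,
              "inverted": res.inverted}
    _dump_json(result, out / "packing.json")
    return result
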