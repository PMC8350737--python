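"""Shared I/O, parameter-table merging and the pipeline driver.

Concentrations are mM at every interface; conversions to molar happen only
inside thermodynamic code. Parameter tables are TSV/CSV files with columns

    reaction_id, dg0_prime_kj_mol, kcat_s, km_mM, mw_g_mol

where ``km_mM`` holds ``"met:value"`` entries separated by ``;`` or ``,``.
Duplicate rows for a reaction are merged: geometric mean for the kinetic
quantities (the convention for multi-source database values), arithmetic
mean for ΔG°′. Missing entries are reported as a checklist, never a crash.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .uptake_kinetics import TransporterKinetics, fit_transporter
from .synthetic_data import SyntheticBatchSpec, generate_fermentation
from .pathway_thermo import PathwayModel, ThermoReaction, shipped_pathway, \
    optimize_mdf, net_yields
from .enzyme_cost import EnzymeKinetics, minimize_pathway_cost
from .core_dfba import build_core_network, simulate_batch, GasTransfer, \
    UptakeLimits, od_to_biomass, ExtracellularState
from .condition_scan import max_productivity

__all__ = ["RunConfig", "load_parameter_table", "merge_parameters",
           "run_pipeline"]

_REQUIRED_COLS = ("reaction_id",)
_VALUE_COLS = ("dg0_prime_kj_mol", "kcat_s", "km_mM", "mw_g_mol")
# stems used to catch unit-suffix mismatches like "kcat_min" or "km_M"
_STEMS = {"dg0_prime": "dg0_prime_kj_mol", "kcat": "kcat_s", "km": "km_mM",
          "mw": "mw_g_mol"}


def _parse_km_entries(text, reaction_id: str) -> dict:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return {}
    out = {}
    for entry in str(text).replace(";", ",").split(","):
        entry = entry.strip()
        if not entry:
            continue
        if ":" not in entry:
            raise ValueError(
                f"reaction {reaction_id}: malformed km entry {entry!r} "
                "(expected 'metabolite:value_mM')")
        met, val = entry.split(":", 1)
        try:
            out[met.strip()] = float(val)
        except ValueError:
            raise ValueError(
                f"reaction {reaction_id}: cannot parse km value in "
                f"{entry!r}") from None
    return out


def _check_columns(df: pd.DataFrame) -> None:
    for col in _REQUIRED_COLS:
        if col not in df.columns:
            raise ValueError(f"parameter table missing column {col!r}")
    for col in df.columns:
        for stem, expected in _STEMS.items():
            if col.startswith(stem) and col != expected:
                raise ValueError(
                    f"column {col!r} does not match the expected unit "
                    f"suffix ({expected!r}); convert units before loading")


def load_parameter_table(path) -> dict:
    """Load a kinetic/thermodynamic parameter table.

    Returns reaction_id → record dict with keys ``dg0_prime`` (kJ/mol),
    ``kcat`` (s⁻¹), ``km`` (mM per metabolite), ``mw`` (g/mol); any of them
    may be absent. Duplicate rows merge by geometric mean (kinetics) or
    arithmetic mean (ΔG°′) with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    _check_columns(df)
    merged: dict = {}
    for rid, group in df.groupby("reaction_id", sort=False):
        if len(group) > 1:
            warnings.warn(
                f"parameter table has {len(group)} rows for {rid}; "
                "merging (geometric mean for kinetics, mean for dG0)")
        rec: dict = {}
        if "dg0_prime_kj_mol" in group:
            vals = group["dg0_prime_kj_mol"].dropna()
            if len(vals):
                rec["dg0_prime"] = float(vals.mean())
        for col, key in (("kcat_s", "kcat"), ("mw_g_mol", "mw")):
            if col in group:
                vals = group[col].dropna()
                if len(vals):
                    if (vals <= 0).any():
                        raise ValueError(f"{rid}: {col} must be > 0")
                    rec[key] = float(np.exp(np.log(vals).mean()))
        if "km_mM" in group:
            km_maps = [_parse_km_entries(v, rid) for v in group["km_mM"]]
            km_all: dict = {}
            for m in {k for d in km_maps for k in d}:
                vs = [d[m] for d in km_maps if m in d]
                km_all[m] = float(np.exp(np.mean(np.log(vs))))
            if km_all:
                rec["km"] = km_all
        merged[rid] = rec
    return merged


def merge_parameters(pathway: PathwayModel, table: dict):
    """Merge a loaded parameter table onto a pathway.

    Returns ``(pathway, checklist)`` where ``checklist`` lists
    ``(reaction_id, missing_field)`` pairs for everything still absent after
    the merge. The input pathway is not modified.
    """
    new_reactions = []
    checklist = []
    for r in pathway.reactions:
        rec = table.get(r.id, {})
        dg0 = rec.get("dg0_prime", r.dg0_prime)
        kin = r.kinetics
        has_kin = {"kcat": None, "km": {}, "mw": None}
        if kin is not None:
            has_kin = {"kcat": kin.kcat_fwd, "km": dict(kin.km), "mw": kin.mw}
        kcat = rec.get("kcat", has_kin["kcat"])
        mw = rec.get("mw", has_kin["mw"])
        km = dict(has_kin["km"])
        km.update(rec.get("km", {}))
        if dg0 is None:
            checklist.append((r.id, "dg0_prime_kj_mol"))
        if kcat is None:
            checklist.append((r.id, "kcat_s"))
        if mw is None:
            checklist.append((r.id, "mw_g_mol"))
        needed = [m for m, nu in r.stoich.items()
                  if m not in ("h2o", "h") and (nu < 0 or r.reversible)]
        for m in needed:
            if m not in km:
                checklist.append((r.id, f"km_mM:{m}"))
        new_kin = None
        if kcat is not None and mw is not None:
            new_kin = EnzymeKinetics(kcat_fwd=kcat, km=km, mw=mw,
                                     irreversible=not r.reversible)
        new_reactions.append(ThermoReaction(
            id=r.id, stoich=dict(r.stoich), dg0_prime=dg0,
            reversible=r.reversible, kinetics=new_kin))
    merged = PathwayModel(
        reactions=new_reactions, rel_flux=dict(pathway.rel_flux),
        fixed_conc=dict(pathway.fixed_conc), conc_lb=pathway.conc_lb,
        conc_ub=pathway.conc_ub, temperature=pathway.temperature,
        boundary=set(pathway.boundary), product=pathway.product,
        carbon=dict(pathway.carbon), name=pathway.name)
    return merged, checklist


@dataclass
class RunConfig:
    """Configuration for the end-to-end pipeline."""

    outdir: str = "zymoflux_out"
    stages: tuple = ("synth", "fit", "yields", "mdf", "ecm", "dfba")
    seed: int = 0
    noise_cv: float = 0.02
    parameter_table: str | None = None  # required for mdf/ecm stages
    model_table: str | None = None  # core network TSV; None = shipped
    transporter: TransporterKinetics | None = None  # overrides the fit
    kla: float = 30.0
    o2_sat: float = 0.21
    od_factor: float = 0.33
    initial_od: float = 0.84
    initial_glc: float = 443.0
    initial_xyl: float = 245.0
    t_end: float = 65.0
    dt: float = 0.1
    fit_restarts: int = 8

    def __post_init__(self):
        for name in ("parameter_table", "model_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the requested stages in dependency order and write a manifest.

    Stages: ``synth`` (generate a course), ``fit`` (transporter fit),
    ``yields`` (pathway stoichiometric yields), ``mdf``/``ecm`` (require a
    parameter table), ``dfba`` (batch simulation + productivity). Outputs
    land in ``config.outdir``; a failed stage halts downstream stages and is
    recorded in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}
    for name in ("parameter_table", "model_table"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    course = None
    tk = config.transporter
    halted = False
    for stage in config.stages:
        if halted:
            manifest["stages"][stage] = {"status": "skipped (upstream failure)"}
            continue
        try:
            if stage == "synth":
                spec = SyntheticBatchSpec(
                    initial_glc=config.initial_glc,
                    initial_xyl=config.initial_xyl,
                    initial_biomass=od_to_biomass(config.initial_od,
                                                  config.od_factor),
                    t_end=config.t_end, noise_cv=config.noise_cv,
                    seed=config.seed)
                synth = generate_fermentation(spec)
                course = synth.noisy
                path = outdir / "course.tsv"
                course.to_tsv(path)
                manifest["stages"][stage] = {"status": "ok",
                                             "output": str(path)}
            elif stage == "fit":
                if course is None:
                    raise RuntimeError("fit requires the synth stage")
                fit = fit_transporter(course, n_restarts=config.fit_restarts,
                                      seed=config.seed)
                if tk is None:
                    tk = fit.params
                path = outdir / "fit.json"
                path.write_text(json.dumps(fit.to_dict(), indent=2))
                manifest["stages"][stage] = {"status": "ok",
                                             "output": str(path),
                                             "r_squared": fit.r_squared}
            elif stage == "yields":
                out = {}
                for name in ("glucose_bdo", "xylose_bdo"):
                    pw = shipped_pathway(name)
                    out[name] = net_yields(pw)
                path = outdir / "yields.json"
                path.write_text(json.dumps(out, indent=2))
                manifest["stages"][stage] = {"status": "ok",
                                             "output": str(path)}
            elif stage in ("mdf", "ecm"):
                if config.parameter_table is None:
                    raise RuntimeError(
                        f"{stage} requires a parameter table "
                        "(RunConfig.parameter_table)")
                table = load_parameter_table(config.parameter_table)
                out = {}
                for name in ("glucose_bdo", "xylose_bdo"):
                    pw, checklist = merge_parameters(shipped_pathway(name),
                                                     table)
                    if stage == "mdf":
                        if any(f == "dg0_prime_kj_mol" for _, f in checklist):
                            raise RuntimeError(
                                f"{name}: missing dG0 entries: "
                                f"{checklist}")
                        sol = optimize_mdf(pw)
                        out[name] = {"mdf_kj_mol": sol.mdf,
                                     "total_dg_kj_mol": sol.total_dg,
                                     "dg_prime": sol.dg_prime}
                    else:
                        if checklist:
                            raise RuntimeError(
                                f"{name}: missing parameters: {checklist}")
                        sol = minimize_pathway_cost(pw, seed=config.seed)
                        out[name] = {
                            "total_cost_g_per_mol_s": sol.total_cost,
                            "per_enzyme_share": sol.per_enzyme_share}
                path = outdir / f"{stage}.json"
                path.write_text(json.dumps(out, indent=2))
                manifest["stages"][stage] = {"status": "ok",
                                             "output": str(path)}
            elif stage == "dfba":
                if tk is None:
                    raise RuntimeError(
                        "dfba requires transporter parameters (run fit or "
                        "set RunConfig.transporter)")
                net = build_core_network(config.model_table)
                init = ExtracellularState(
                    glc=config.initial_glc, xyl=config.initial_xyl,
                    o2=config.o2_sat,
                    biomass=od_to_biomass(config.initial_od,
                                          config.od_factor))
                traj = simulate_batch(
                    net, tk, gas=GasTransfer(config.kla, config.o2_sat),
                    init=init, t_end=config.t_end, dt=config.dt)
                path = outdir / "trajectory.tsv"
                traj.to_frame().to_csv(path, sep="\t", index=False)
                p, t_at = max_productivity(traj)
                manifest["stages"][stage] = {
                    "status": "ok", "output": str(path),
                    "max_productivity_mmol_L_h": p, "t_at_max_h": t_at,
                    "final_bdo_mM": traj.states[-1].bdo}
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as err:  # halt downstream, record the failure
            manifest["stages"][stage] = {"status": f"failed: {err}"}
            halted = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
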