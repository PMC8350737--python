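"""Pathway-level thermodynamics: stoichiometric yields, reaction Gibbs
energies and max–min driving force (MDF) optimization.

A :class:`PathwayModel` is an ordered list of reactions, each carrying a
signed stoichiometry, a standard-transformed Gibbs energy ΔG°′ (kJ mol⁻¹)
and a relative flux per unit pathway flux (mol per mol 2,3-BDO). The MDF of
a pathway is the largest achievable value of the smallest −ΔG′ across its
(reversible) reactions, optimized over metabolite log-concentrations within
bounds — a linear program in x = ln c:

    maximize B  s.t.  −(ΔG°′_j + RT·S_jᵀ x) ≥ B  for every scored reaction j,
                      ln(lb) ≤ x ≤ ln(ub) for free metabolites,
                      x pinned for fixed concentrations.

Concentrations are mM at all interfaces and converted to molar internally
(standard state 1 M). Water and protons never appear in the concentration
vector; their contribution is absorbed in ΔG°′ (eQuilibrator convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import linprog

from ._equations import parse_equation, format_equation

__all__ = [
    "R_KJ_MOL_K", "DEFAULT_TEMPERATURE_K",
    "ThermoReaction", "PathwayModel", "MdfSolution",
    "load_pathway", "shipped_pathway", "net_yields", "reaction_dg",
    "optimize_mdf", "cumulative_profile", "standard_state_profile",
    "timecourse_mdf", "bottleneck_report", "cofactor_ratio_scan",
]

R_KJ_MOL_K = 8.314e-3  # kJ mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 298.15
MM_TO_M = 1e-3
#: species excluded from the concentration vector
EXCLUDED_SPECIES = frozenset({"h2o", "h"})
#: floor (mM) applied to pinned concentrations in time-course scans
CONC_FLOOR_MM = 1e-3


@dataclass
class ThermoReaction:
    """One pathway reaction: signed stoichiometry (substrates negative),
    ΔG°′ for the direction as written, and optional enzyme kinetics."""

    id: str
    stoich: dict
    dg0_prime: float | None = None
    reversible: bool = True
    kinetics: object | None = None  # EnzymeKinetics

    def __post_init__(self):
        if not self.stoich:
            raise ValueError(f"reaction {self.id} has empty stoichiometry")

    @property
    def substrates(self):
        return {m: c for m, c in self.stoich.items() if c < 0}

    @property
    def products(self):
        return {m: c for m, c in self.stoich.items() if c > 0}

    def carbon_imbalance(self, carbon: dict) -> float | None:
        """Signed carbon imbalance, or None if any carbon count is missing."""
        total = 0.0
        for m, c in self.stoich.items():
            if m in EXCLUDED_SPECIES:
                continue
            if m not in carbon:
                return None
            total += c * carbon[m]
        return total


@dataclass
class PathwayModel:
    reactions: list
    rel_flux: dict
    fixed_conc: dict = field(default_factory=dict)  # mM
    conc_lb: float = 1e-3  # mM  (1 uM)
    conc_ub: float = 10.0  # mM
    temperature: float = DEFAULT_TEMPERATURE_K
    boundary: set = field(default_factory=set)
    product: str | None = None
    carbon: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        self.boundary = set(self.boundary)
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reaction ids")
        for rid in ids:
            if self.rel_flux.get(rid, 0.0) <= 0:
                raise ValueError(f"rel_flux for {rid} must be > 0")
        if self.conc_lb <= 0 or self.conc_ub <= self.conc_lb:
            raise ValueError("concentration bounds must satisfy 0 < lb < ub")
        self.validate_steady_state()

    def metabolites(self) -> list:
        seen = []
        for r in self.reactions:
            for m in r.stoich:
                if m not in seen and m not in EXCLUDED_SPECIES:
                    seen.append(m)
        return seen

    def net_stoich(self) -> dict:
        """Σ_j rel_flux_j · stoich_ij over all reactions."""
        net: dict = {}
        for r in self.reactions:
            f = self.rel_flux[r.id]
            for m, c in r.stoich.items():
                net[m] = net.get(m, 0.0) + f * c
        return net

    def validate_steady_state(self, tol: float = 1e-9) -> None:
        """Every non-boundary intermediate must balance under rel_flux."""
        net = self.net_stoich()
        bad = [m for m, v in net.items()
               if m not in self.boundary and m not in EXCLUDED_SPECIES
               and abs(v) > tol]
        if bad:
            raise ValueError(
                f"pathway {self.name or '<unnamed>'} violates steady state "
                f"for intermediates: {sorted(bad)}")

    def get_reaction(self, rid: str) -> ThermoReaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction id {rid!r}")

    def with_fixed_conc(self, updates: dict) -> "PathwayModel":
        fixed = dict(self.fixed_conc)
        fixed.update(updates)
        return PathwayModel(reactions=self.reactions, rel_flux=self.rel_flux,
                            fixed_conc=fixed, conc_lb=self.conc_lb,
                            conc_ub=self.conc_ub, temperature=self.temperature,
                            boundary=self.boundary, product=self.product,
                            carbon=self.carbon, name=self.name)


@dataclass
class MdfSolution:
    mdf: float  # kJ mol^-1, maximized minimum of -dG'
    ln_conc: dict  # metabolite -> ln(concentration in M)
    dg_prime: dict  # reaction id -> kJ mol^-1
    cumulative_dg: list  # partial sums in pathway order
    status: str = "optimal"

    @property
    def total_dg(self) -> float:
        return self.cumulative_dg[-1] if self.cumulative_dg else 0.0


def net_yields(pathway: PathwayModel) -> dict:
    """Net production of boundary species per unit pathway flux, normalized
    so the designated product (2,3-BDO) has coefficient +1."""
    pathway.validate_steady_state()
    net = pathway.net_stoich()
    out = {m: v for m, v in net.items() if m in pathway.boundary}
    if pathway.product is not None and pathway.product in out:
        scale = out[pathway.product]
        if scale <= 0:
            raise ValueError(f"product {pathway.product} is not net produced")
        out = {m: v / scale for m, v in out.items()}
    return {m: (0.0 if abs(v) < 1e-12 else float(v)) for m, v in out.items()}


def reaction_dg(rxn: ThermoReaction, ln_conc: dict,
                temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """ΔG′ = ΔG°′ + RT·Σ ν_i ln c_i (c in M, standard state 1 M)."""
    if rxn.dg0_prime is None:
        raise ValueError(f"reaction {rxn.id} has no dg0_prime")
    rt = R_KJ_MOL_K * temperature
    total = rxn.dg0_prime
    for m, nu in rxn.stoich.items():
        if m in EXCLUDED_SPECIES:
            continue
        if m not in ln_conc:
            raise KeyError(f"no concentration supplied for metabolite {m!r}")
        total += rt * nu * ln_conc[m]
    return float(total)


def _require_dg0(pathway: PathwayModel):
    missing = [r.id for r in pathway.reactions if r.dg0_prime is None]
    if missing:
        raise ValueError(
            f"reactions missing dg0_prime: {missing}; merge a parameter "
            "table first (workbench.load_parameter_table)")


def optimize_mdf(pathway: PathwayModel,
                 extra_equalities: list | None = None) -> MdfSolution:
    """Solve the max–min driving force LP.

    Reactions flagged irreversible (``reversible=False``, e.g. the glf
    transport step) are excluded from the maximin objective but their ΔG′ at
    the optimal concentrations is still reported. ``extra_equalities`` is a
    list of ``(met_a, met_b, ln_ratio)`` constraints x_a − x_b = ln_ratio
    (used by the cofactor-ratio scan).
    """
    _require_dg0(pathway)
    mets = pathway.metabolites()
    idx = {m: i for i, m in enumerate(mets)}
    n = len(mets)
    rt = R_KJ_MOL_K * pathway.temperature

    lb = np.full(n, np.log(pathway.conc_lb * MM_TO_M))
    ub = np.full(n, np.log(pathway.conc_ub * MM_TO_M))
    for m, c_mM in pathway.fixed_conc.items():
        if m in idx:
            if c_mM <= 0:
                raise ValueError(f"fixed concentration for {m} must be > 0")
            lb[idx[m]] = ub[idx[m]] = np.log(c_mM * MM_TO_M)

    scored = [r for r in pathway.reactions if r.reversible]
    if not scored:
        raise ValueError("no reversible reactions to score in MDF")

    # variables: [x_0..x_{n-1}, B]; minimize -B
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.zeros((len(scored), n + 1))
    b_ub = np.zeros(len(scored))
    for k, r in enumerate(scored):
        for m, nu in r.stoich.items():
            if m in EXCLUDED_SPECIES:
                continue
            A_ub[k, idx[m]] += rt * nu
        A_ub[k, -1] = 1.0
        b_ub[k] = -r.dg0_prime
    A_eq = b_eq = None
    if extra_equalities:
        rows, rhs = [], []
        for (ma, mb, lnr) in extra_equalities:
            if ma not in idx or mb not in idx:
                raise KeyError(f"cofactor {ma if ma not in idx else mb!r} "
                               "not present in pathway")
            row = np.zeros(n + 1)
            row[idx[ma]] = 1.0
            row[idx[mb]] = -1.0
            rows.append(row)
            rhs.append(lnr)
        A_eq, b_eq = np.vstack(rows), np.array(rhs)

    bounds = [(lb[i], ub[i]) for i in range(n)] + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(
            f"MDF LP infeasible for pathway {pathway.name or '<unnamed>'} "
            f"(status {res.status}): {res.message}")
    x = res.x[:n]
    ln_conc = {m: float(x[idx[m]]) for m in mets}
    dg = {r.id: reaction_dg(r, ln_conc, pathway.temperature)
          for r in pathway.reactions}
    cum = np.cumsum([dg[r.id] for r in pathway.reactions]).tolist()
    return MdfSolution(mdf=float(res.x[-1]), ln_conc=ln_conc, dg_prime=dg,
                       cumulative_dg=cum)


def cumulative_profile(sol: MdfSolution, order: list) -> list:
    """Partial sums of per-reaction ΔG′ in the given pathway order."""
    missing = [rid for rid in order if rid not in sol.dg_prime]
    if missing:
        raise KeyError(f"unknown reaction ids in order: {missing}")
    return np.cumsum([sol.dg_prime[rid] for rid in order]).tolist()


def standard_state_profile(pathway: PathwayModel,
                           conc_mM: float = 1.0) -> list:
    """Cumulative ΔG′ with every metabolite at a reference concentration
    (default 1 mM) — the 'standard' curve of the MDF plots."""
    _require_dg0(pathway)
    ln_c = np.log(conc_mM * MM_TO_M)
    ln_conc = {m: ln_c for m in pathway.metabolites()}
    dgs = [reaction_dg(r, ln_conc, pathway.temperature)
           for r in pathway.reactions]
    return np.cumsum(dgs).tolist()


def timecourse_mdf(pathway: PathwayModel, substrate_series: dict):
    """Re-solve the MDF at each timepoint with extracellular substrates
    pinned at the supplied values (mM; clipped at a 10⁻³ mM floor).

    ``substrate_series`` maps metabolite id → array of concentrations, all of
    equal length. Returns ``(mdf, total_dg, dg_traces, solutions)`` where
    ``dg_traces`` maps reaction id → ΔG′ array.
    """
    names = list(substrate_series)
    arrays = [np.asarray(substrate_series[m], dtype=float) for m in names]
    n_t = arrays[0].size
    if any(a.size != n_t for a in arrays):
        raise ValueError("substrate series must have equal length")
    mdf = np.empty(n_t)
    total = np.empty(n_t)
    traces = {r.id: np.empty(n_t) for r in pathway.reactions}
    sols = []
    for t in range(n_t):
        pins = {m: max(float(a[t]), CONC_FLOOR_MM)
                for m, a in zip(names, arrays)}
        sol = optimize_mdf(pathway.with_fixed_conc(pins))
        mdf[t] = sol.mdf
        total[t] = sol.total_dg
        for rid, v in sol.dg_prime.items():
            traces[rid][t] = v
        sols.append(sol)
    return mdf, total, traces, sols


def bottleneck_report(pathway: PathwayModel, conc_mM: float = 1.0) -> list:
    """Reactions with ΔG′ > 0 when every metabolite sits at the reference
    concentration (default 1 mM), in pathway order."""
    _require_dg0(pathway)
    ln_c = np.log(conc_mM * MM_TO_M)
    ln_conc = {m: ln_c for m in pathway.metabolites()}
    return [r.id for r in pathway.reactions
            if reaction_dg(r, ln_conc, pathway.temperature) > 0]


_RATIO_NAMES = {
    "ATP/ADP": ("atp", "adp"),
    "NADH/NAD": ("nadh", "nad"),
    "NADPH/NADP": ("nadph", "nadp"),
}


def cofactor_ratio_scan(pathway: PathwayModel, ratio_name, ratios):
    """Total pathway ΔG′ as a function of a pinned cofactor ratio.

    ``ratio_name`` is one of ``"ATP/ADP"``, ``"NADH/NAD"``, ``"NADPH/NADP"``
    or an explicit ``(numerator, denominator)`` metabolite pair. Returns a
    list of ``(ratio, total_dg, mdf)``; infeasible ratios raise.
    """
    if isinstance(ratio_name, str):
        if ratio_name not in _RATIO_NAMES:
            raise KeyError(f"unknown ratio name {ratio_name!r}; "
                           f"expected one of {sorted(_RATIO_NAMES)}")
        num, den = _RATIO_NAMES[ratio_name]
    else:
        num, den = ratio_name
    mets = set(pathway.metabolites())
    for m in (num, den):
        if m not in mets:
            raise KeyError(f"cofactor {m!r} not present in pathway")
    out = []
    for r in ratios:
        if r <= 0:
            raise ValueError("ratios must be positive")
        sol = optimize_mdf(pathway, extra_equalities=[(num, den, np.log(r))])
        out.append((float(r), sol.total_dg, sol.mdf))
    return out


# ---------------------------------------------------------------------------
# pathway-definition files

def _reaction_from_record(rec: dict) -> tuple[ThermoReaction, float]:
    from .enzyme_cost import EnzymeKinetics  # deferred: avoids import cycle
    stoich, rev_from_eq = parse_equation(rec["equation"])
    reversible = not rec.get("irreversible", not rev_from_eq)
    kin = None
    if rec.get("kcat_s") is not None and rec.get("mw_g_mol") is not None:
        kin = EnzymeKinetics(kcat_fwd=rec["kcat_s"],
                             km={k: float(v) for k, v in
                                 (rec.get("km_mM") or {}).items()},
                             mw=rec["mw_g_mol"],
                             irreversible=not reversible)
    rxn = ThermoReaction(id=rec["id"], stoich=stoich,
                         dg0_prime=rec.get("dg0_prime_kj_mol"),
                         reversible=reversible, kinetics=kin)
    return rxn, float(rec.get("rel_flux", 1.0))


def pathway_from_dict(doc: dict) -> PathwayModel:
    reactions, rel_flux = [], {}
    for rec in doc["reactions"]:
        rxn, f = _reaction_from_record(rec)
        reactions.append(rxn)
        rel_flux[rxn.id] = f
    return PathwayModel(
        reactions=reactions, rel_flux=rel_flux,
        fixed_conc=doc.get("fixed_conc_mM", {}),
        conc_lb=doc.get("conc_lb_mM", 1e-3),
        conc_ub=doc.get("conc_ub_mM", 10.0),
        temperature=doc.get("temperature_K", DEFAULT_TEMPERATURE_K),
        boundary=set(doc.get("boundary", [])),
        product=doc.get("product"),
        carbon=doc.get("carbon", {}),
        name=doc.get("name", ""))


def load_pathway(path) -> PathwayModel:
    """Load a pathway-definition JSON file."""
    with open(path) as fh:
        return pathway_from_dict(json.load(fh))


def shipped_pathway(name: str) -> PathwayModel:
    """Load one of the curated pathway files: ``"glucose_bdo"`` (ED route)
    or ``"xylose_bdo"`` (PPP rearrangement feeding ED + lower glycolysis).

    ΔG°′ and kinetics fields are unset except where stated by construction
    (glf transport carries ΔG°′ = 0); merge a parameter table to fill them.
    """
    ref = resources.files("zymoflux.data").joinpath(f"{name}.json")
    with ref.open() as fh:
        return pathway_from_dict(json.load(fh))


def pathway_to_dict(pathway: PathwayModel) -> dict:
    recs = []
    for r in pathway.reactions:
        rec = {"id": r.id,
               "equation": format_equation(r.stoich, r.reversible),
               "dg0_prime_kj_mol": r.dg0_prime,
               "rel_flux": pathway.rel_flux[r.id],
               "irreversible": not r.reversible}
        if r.kinetics is not None:
            rec["kcat_s"] = r.kinetics.kcat_fwd
            rec["km_mM"] = dict(r.kinetics.km)
            rec["mw_g_mol"] = r.kinetics.mw
        recs.append(rec)
    return {"name": pathway.name, "reactions": recs,
            "fixed_conc_mM": dict(pathway.fixed_conc),
            "conc_lb_mM": pathway.conc_lb, "conc_ub_mM": pathway.conc_ub,
            "temperature_K": pathway.temperature,
            "boundary": sorted(pathway.boundary),
            "product": pathway.product, "carbon": dict(pathway.carbon)}
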