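"""Enzyme protein cost: the minimal total enzyme mass required to sustain a
unit pathway flux, in g (mol s⁻¹)⁻¹.

The demand of one reaction factorizes as

    E = MW · v / (kcat⁺ · η_rev · η_sat)

with the thermodynamic efficiency η_rev = 1 − exp(ΔG′/RT) (η_rev ≡ 1 for
irreversible steps) and the saturation efficiency of the common modular
rate law

    η_sat = Π_S (s/Km)^|ν| / ( Π_S (1+s/Km)^|ν| + Π_P (1+p/Km)^|ν| − 1 ).

For irreversible reactions the product terms are dropped. Total pathway cost
Σ_j E_j is minimized over metabolite log-concentrations within the same
bounds and pins as the MDF problem, subject to ΔG′_j ≤ −ε for every
reversible reaction. Reverse turnover numbers, when needed, follow the
Haldane relationship kcat⁻ = kcat⁺ · Π_P Km^|ν| / (K_eq · Π_S Km^|ν|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, LinearConstraint

from .pathway_thermo import (
    R_KJ_MOL_K, DEFAULT_TEMPERATURE_K, MM_TO_M, EXCLUDED_SPECIES,
    CONC_FLOOR_MM, ThermoReaction, PathwayModel, optimize_mdf, reaction_dg,
)

__all__ = [
    "EnzymeKinetics", "EnzymeCostSolution", "haldane_kcat_rev",
    "enzyme_demand", "minimize_pathway_cost", "timecourse_cost",
]

#: strict forward feasibility margin on ΔG′ (kJ mol^-1)
DG_EPSILON = 1e-3
_BIG = 1e30


@dataclass(frozen=True)
class EnzymeKinetics:
    """kcat⁺ (s⁻¹), Michaelis constants (mM, per metabolite), molecular
    weight (g mol⁻¹)."""

    kcat_fwd: float
    km: dict
    mw: float
    irreversible: bool = False

    def __post_init__(self):
        if self.kcat_fwd <= 0:
            raise ValueError("kcat_fwd must be > 0")
        if self.mw <= 0:
            raise ValueError("mw must be > 0")
        for m, v in self.km.items():
            if v <= 0:
                raise ValueError(f"Km for {m} must be > 0")


@dataclass
class EnzymeCostSolution:
    per_enzyme_cost: dict  # reaction id -> g (mol s^-1)^-1
    total_cost: float
    ln_conc: dict  # metabolite -> ln M
    per_enzyme_share: dict  # reaction id -> fraction of total
    converged: bool = True

    def dominant_enzyme(self) -> str:
        return max(self.per_enzyme_cost, key=self.per_enzyme_cost.get)


def _km_M(kin: EnzymeKinetics, met: str, rid: str) -> float:
    if met not in kin.km:
        raise KeyError(f"reaction {rid}: missing Km for metabolite {met!r}")
    return kin.km[met] * MM_TO_M


def haldane_kcat_rev(kin: EnzymeKinetics, dg0_prime: float, stoich: dict,
                     temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Reverse turnover number from the Haldane relationship (Km in M)."""
    if kin.irreversible:
        raise ValueError("reverse rate is undefined for an irreversible enzyme")
    rt = R_KJ_MOL_K * temperature
    keq = np.exp(-dg0_prime / rt)
    num = 1.0
    den = 1.0
    for m, nu in stoich.items():
        if m in EXCLUDED_SPECIES:
            continue
        km = _km_M(kin, m, "<haldane>")
        if nu > 0:
            num *= km ** nu
        else:
            den *= km ** (-nu)
    return float(kin.kcat_fwd * num / (keq * den))


def _efficiencies(rxn: ThermoReaction, ln_conc: dict,
                  temperature: float) -> tuple[float, float]:
    kin: EnzymeKinetics = rxn.kinetics
    rt = R_KJ_MOL_K * temperature
    irreversible = not rxn.reversible or kin.irreversible
    if irreversible:
        eta_rev = 1.0
    else:
        dg = reaction_dg(rxn, ln_conc, temperature)
        if dg >= 0:
            raise ValueError(
                f"reaction {rxn.id} is thermodynamically infeasible "
                f"(ΔG′ = {dg:.3f} kJ/mol ≥ 0) at the given concentrations")
        eta_rev = 1.0 - np.exp(dg / rt)
    num = 1.0
    den_s = 1.0
    den_p = 1.0
    for m, nu in rxn.stoich.items():
        if m in EXCLUDED_SPECIES:
            continue
        if nu < 0:
            ratio = np.exp(ln_conc[m]) / _km_M(kin, m, rxn.id)
            num *= ratio ** (-nu)
            den_s *= (1.0 + ratio) ** (-nu)
        elif not irreversible:
            ratio = np.exp(ln_conc[m]) / _km_M(kin, m, rxn.id)
            den_p *= (1.0 + ratio) ** nu
    eta_sat = num / (den_s + den_p - 1.0)
    return eta_rev, eta_sat


def enzyme_demand(rxn: ThermoReaction, ln_conc: dict, flux: float,
                  temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Enzyme mass (g) required to carry ``flux`` (mol s⁻¹) through ``rxn``
    at the given log-concentrations (ln M)."""
    if flux <= 0:
        raise ValueError("flux must be > 0")
    if rxn.kinetics is None:
        raise ValueError(f"reaction {rxn.id} carries no kinetics")
    eta_rev, eta_sat = _efficiencies(rxn, ln_conc, temperature)
    kin: EnzymeKinetics = rxn.kinetics
    return float(kin.mw * flux / (kin.kcat_fwd * eta_rev * eta_sat))


def _objective_factory(pathway: PathwayModel, mets: list, idx: dict):
    """Vector objective x (ln M) → total cost; returns +_BIG outside the
    thermodynamically feasible region (line searches may step there)."""
    rt = R_KJ_MOL_K * pathway.temperature

    def total_cost(x: np.ndarray) -> float:
        ln_conc = {m: x[idx[m]] for m in mets}
        total = 0.0
        for r in pathway.reactions:
            irrev = not r.reversible or r.kinetics.irreversible
            if not irrev:
                dg = reaction_dg(r, ln_conc, pathway.temperature)
                if dg >= -DG_EPSILON * 0.5:
                    return _BIG
                eta_rev = 1.0 - np.exp(dg / rt)
            else:
                eta_rev = 1.0
            kin = r.kinetics
            num = den_s = den_p = 1.0
            for m, nu in r.stoich.items():
                if m in EXCLUDED_SPECIES:
                    continue
                ratio = np.exp(x[idx[m]]) / (kin.km[m] * MM_TO_M) \
                    if m in kin.km else None
                if nu < 0:
                    if ratio is None:
                        raise KeyError(
                            f"reaction {r.id}: missing Km for {m!r}")
                    num *= ratio ** (-nu)
                    den_s *= (1.0 + ratio) ** (-nu)
                elif not irrev:
                    if ratio is None:
                        raise KeyError(
                            f"reaction {r.id}: missing Km for {m!r}")
                    den_p *= (1.0 + ratio) ** nu
            eta_sat = num / (den_s + den_p - 1.0)
            total += kin.mw * pathway.rel_flux[r.id] / (
                kin.kcat_fwd * eta_rev * eta_sat)
        return total

    return total_cost


def minimize_pathway_cost(pathway: PathwayModel, seed: int = 0,
                          n_restarts: int = 10,
                          x0: np.ndarray | None = None) -> EnzymeCostSolution:
    """Minimize total enzyme mass per unit pathway flux (1 mol BDO s⁻¹).

    Optimization runs in ln-concentration space with the same bounds and
    pins as the MDF problem and linear constraints ΔG′_j ≤ −ε on reversible
    reactions. One start is the MDF optimum (requires pathway MDF > 0);
    the rest are seeded jitters around it.
    """
    for r in pathway.reactions:
        if r.kinetics is None:
            raise ValueError(f"reaction {r.id} carries no kinetics")
    if any(r.reversible for r in pathway.reactions):
        mdf_sol = optimize_mdf(pathway)
        if mdf_sol.mdf <= 0:
            tight = min(mdf_sol.dg_prime, key=lambda k: -mdf_sol.dg_prime[k])
            raise ValueError(
                f"pathway MDF = {mdf_sol.mdf:.3f} kJ/mol <= 0: no feasible "
                f"interior (bottleneck reaction: {tight})")
    else:
        mdf_sol = None  # all steps irreversible: no thermodynamic precheck

    mets = pathway.metabolites()
    idx = {m: i for i, m in enumerate(mets)}
    n = len(mets)
    rt = R_KJ_MOL_K * pathway.temperature

    lb = np.full(n, np.log(pathway.conc_lb * MM_TO_M))
    ub = np.full(n, np.log(pathway.conc_ub * MM_TO_M))
    for m, c_mM in pathway.fixed_conc.items():
        if m in idx:
            lb[idx[m]] = ub[idx[m]] = np.log(c_mM * MM_TO_M)

    # linear thermodynamic constraints: RT S^T x <= -dg0 - eps
    rows, rhs = [], []
    for r in pathway.reactions:
        if not r.reversible or r.kinetics.irreversible:
            continue
        row = np.zeros(n)
        for m, nu in r.stoich.items():
            if m not in EXCLUDED_SPECIES:
                row[idx[m]] += rt * nu
        rows.append(row)
        rhs.append(-r.dg0_prime - DG_EPSILON)
    constraints = []
    if rows:
        constraints.append(LinearConstraint(np.vstack(rows),
                                            -np.inf, np.array(rhs)))

    objective = _objective_factory(pathway, mets, idx)

    def log_objective(x):  # spans many decades; optimize on log scale
        return np.log(objective(x))

    rng = np.random.default_rng(seed)
    if mdf_sol is not None:
        x_mdf = np.array([mdf_sol.ln_conc[m] for m in mets])
    else:
        x_mdf = (lb + ub) / 2.0
    starts = [x_mdf] if x0 is None else [np.asarray(x0, float), x_mdf]
    while len(starts) < n_restarts:
        jitter = rng.normal(0.0, 2.0, size=n)
        starts.append(np.clip(x_mdf + jitter, lb, ub))

    best_x, best_f, converged = None, np.inf, False
    for x_start in starts:
        res = minimize(log_objective, x_start, method="SLSQP",
                       bounds=list(zip(lb, ub)), constraints=constraints,
                       options={"maxiter": 400, "ftol": 1e-12})
        f = objective(res.x)
        if f < best_f:
            best_f, best_x = f, res.x
            converged = bool(res.success)
    # never worse than the MDF-optimal start
    f_mdf = objective(x_mdf)
    if f_mdf < best_f:
        best_f, best_x = f_mdf, x_mdf

    ln_conc = {m: float(best_x[idx[m]]) for m in mets}
    per = {r.id: enzyme_demand(r, ln_conc, pathway.rel_flux[r.id],
                               pathway.temperature)
           for r in pathway.reactions}
    total = float(sum(per.values()))
    share = {rid: v / total for rid, v in per.items()}
    return EnzymeCostSolution(per_enzyme_cost=per, total_cost=total,
                              ln_conc=ln_conc, per_enzyme_share=share,
                              converged=converged)


def timecourse_cost(pathway: PathwayModel, substrate_series: dict,
                    seed: int = 0, n_restarts: int = 2):
    """Minimal pathway cost at each timepoint with substrates pinned at the
    supplied concentrations (mM, floored at 10⁻³ mM).

    Returns ``(total, per_enzyme_traces, infeasible)`` where ``total`` is an
    array (nan at infeasible points), ``per_enzyme_traces`` maps reaction id
    → array, and ``infeasible`` is the list of failed timepoint indices.
    Successive points are warm-started from the previous optimum.
    """
    names = list(substrate_series)
    arrays = [np.asarray(substrate_series[m], dtype=float) for m in names]
    n_t = arrays[0].size
    if any(a.size != n_t for a in arrays):
        raise ValueError("substrate series must have equal length")
    total = np.full(n_t, np.nan)
    traces = {r.id: np.full(n_t, np.nan) for r in pathway.reactions}
    infeasible = []
    warm = None
    mets = pathway.metabolites()
    for t in range(n_t):
        pins = {m: max(float(a[t]), CONC_FLOOR_MM)
                for m, a in zip(names, arrays)}
        model = pathway.with_fixed_conc(pins)
        try:
            sol = minimize_pathway_cost(model, seed=seed,
                                        n_restarts=n_restarts, x0=warm)
        except (ValueError, RuntimeError):
            infeasible.append(t)
            continue
        total[t] = sol.total_cost
        for rid, v in sol.per_enzyme_cost.items():
            traces[rid][t] = v
        warm = np.array([sol.ln_conc[m] for m in mets])
    return total, traces, infeasible
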