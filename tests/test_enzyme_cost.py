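"""Tests for the enzyme protein-cost layer (common modular rate law)."""

import numpy as np
import pytest

import zymoflux as zf
from zymoflux.pathway_thermo import R_KJ_MOL_K, ThermoReaction, PathwayModel
from zymoflux.enzyme_cost import (
    EnzymeKinetics, haldane_kcat_rev, enzyme_demand, minimize_pathway_cost,
    timecourse_cost,
)
from zymoflux.synthetic_data import ToyPathwaySpec, generate_toy_pathway

RT = R_KJ_MOL_K * 298.15


def uni_uni(dg0=0.0, km_s=1.0, km_p=1.0, kcat=10.0, mw=5e4,
            reversible=True):
    kin = EnzymeKinetics(kcat_fwd=kcat, km={"S": km_s, "P": km_p}, mw=mw,
                         irreversible=not reversible)
    return ThermoReaction(id="r", stoich={"S": -1.0, "P": 1.0},
                          dg0_prime=dg0, reversible=reversible, kinetics=kin)


class TestHaldane:
    def test_symmetric_identity(self):
        r = uni_uni(dg0=0.0, km_s=0.5, km_p=0.5)
        assert haldane_kcat_rev(r.kinetics, 0.0, r.stoich) == \
            pytest.approx(r.kinetics.kcat_fwd)

    def test_keq_ten_divides_kcat(self):
        dg0 = -RT * np.log(10.0)  # Keq = 10
        r = uni_uni(dg0=dg0, km_s=1.0, km_p=1.0)
        assert haldane_kcat_rev(r.kinetics, dg0, r.stoich) == \
            pytest.approx(r.kinetics.kcat_fwd / 10.0, rel=1e-9)

    def test_irreversible_refuses(self):
        r = uni_uni(reversible=False)
        with pytest.raises(ValueError, match="irreversible"):
            haldane_kcat_rev(r.kinetics, 0.0, r.stoich)

    def test_missing_km_named(self):
        kin = EnzymeKinetics(kcat_fwd=10.0, km={"S": 1.0}, mw=5e4)
        with pytest.raises(KeyError, match="P"):
            haldane_kcat_rev(kin, 0.0, {"S": -1.0, "P": 1.0})


class TestEnzymeDemand:
    def test_full_saturation_limit(self):
        r = uni_uni(reversible=False, km_s=0.001)
        ln_conc = {"S": np.log(10e-3)}  # s = 10 mM >> Km
        demand = enzyme_demand(r, ln_conc, flux=1.0)
        floor = r.kinetics.mw * 1.0 / r.kinetics.kcat_fwd
        assert demand == pytest.approx(floor, rel=1e-3)

    def test_half_saturation_doubles_demand(self):
        r = uni_uni(reversible=False, km_s=1.0)
        ln_conc = {"S": np.log(1e-3)}  # s = Km
        demand = enzyme_demand(r, ln_conc, flux=1.0)
        floor = r.kinetics.mw / r.kinetics.kcat_fwd
        assert demand == pytest.approx(2.0 * floor, rel=1e-9)

    def test_eta_rev_half_doubles_demand(self):
        # dG' = -RT ln 2 -> eta_rev = 1/2; compare at matched saturation
        r = uni_uni(dg0=0.0, km_s=1.0, km_p=1e6)  # product term negligible
        s = np.log(1e-3)
        near = {"S": s, "P": s - np.log(2.0)}   # dG' = -RT ln 2
        far = {"S": s, "P": s - 30.0}           # dG' ~ -RT*30, eta_rev ~ 1
        d_near = enzyme_demand(r, near, flux=1.0)
        d_far = enzyme_demand(r, far, flux=1.0)
        assert d_near == pytest.approx(2.0 * d_far, rel=1e-3)

    def test_infeasible_direction_raises(self):
        r = uni_uni(dg0=0.0)
        with pytest.raises(ValueError, match="infeasible"):
            enzyme_demand(r, {"S": np.log(1e-3), "P": np.log(2e-3)}, 1.0)

    def test_demand_never_below_capacity_floor(self):
        """1000 random states: demand >= MW*v/kcat (eta factors <= 1)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            ns, np_ = rng.integers(1, 3), rng.integers(1, 3)
            mets_s = [f"S{i}" for i in range(ns)]
            mets_p = [f"P{i}" for i in range(np_)]
            km = {m: float(rng.uniform(0.05, 5.0))
                  for m in mets_s + mets_p}
            kin = EnzymeKinetics(kcat_fwd=float(rng.uniform(1, 500)),
                                 km=km, mw=float(rng.uniform(1e4, 3e5)))
            stoich = {m: -1.0 for m in mets_s} | {m: 1.0 for m in mets_p}
            rxn = ThermoReaction(id="r", stoich=stoich,
                                 dg0_prime=float(rng.uniform(-60, -20)),
                                 reversible=True, kinetics=kin)
            ln_conc = {m: float(np.log(rng.uniform(1e-6, 1e-2)))
                       for m in stoich}
            try:
                d = enzyme_demand(rxn, ln_conc, flux=1.0)
            except ValueError:
                continue  # thermodynamically infeasible draw
            flux_floor = kin.mw * 1.0 / kin.kcat_fwd
            assert d >= flux_floor * (1 - 1e-12)


class TestMinimizeCost:
    def test_single_irreversible_reaction_pushes_substrate_up(self):
        r = uni_uni(reversible=False, km_s=1.0, kcat=10.0, mw=5e4)
        pw = PathwayModel(reactions=[r], rel_flux={"r": 1.0},
                          boundary={"S", "P"}, product="P")
        sol = minimize_pathway_cost(pw, seed=0, n_restarts=4)
        ub = np.log(pw.conc_ub * 1e-3)
        assert sol.ln_conc["S"] == pytest.approx(ub, abs=1e-4)
        eta = (pw.conc_ub / r.kinetics.km["S"]) / \
            (1 + pw.conc_ub / r.kinetics.km["S"])
        assert sol.total_cost == pytest.approx(
            r.kinetics.mw / (r.kinetics.kcat_fwd * eta), rel=1e-4)

    def test_two_reaction_chain_matches_grid_search(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=2, seed=13))
        sol = minimize_pathway_cost(pw, seed=0, n_restarts=6)
        # dense 2-D grid over the free metabolites A1, A2
        lo, hi = np.log(pw.conc_lb * 1e-3), np.log(pw.conc_ub * 1e-3)
        xs = np.linspace(lo, hi, 160)
        pinned = np.log(pw.fixed_conc["A0"] * 1e-3)
        best = np.inf
        for x1 in xs:
            for x2 in xs:
                ln_conc = {"A0": pinned, "A1": x1, "A2": x2}
                try:
                    total = sum(
                        enzyme_demand(r, ln_conc, pw.rel_flux[r.id])
                        for r in pw.reactions)
                except ValueError:
                    continue
                best = min(best, total)
        assert sol.total_cost == pytest.approx(best, rel=0.01)

    def test_solution_invariants(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=3, seed=21))
        sol = minimize_pathway_cost(pw, seed=1, n_restarts=4)
        assert sol.total_cost == pytest.approx(
            sum(sol.per_enzyme_cost.values()))
        assert sum(sol.per_enzyme_share.values()) == pytest.approx(1.0)
        assert all(v > 0 for v in sol.per_enzyme_cost.values())
        # every reversible reaction strictly forward-feasible
        for r in pw.reactions:
            dg = zf.reaction_dg(r, sol.ln_conc, pw.temperature)
            assert dg < 0

    def test_never_worse_than_mdf_start(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=3, seed=30))
        mdf_sol = zf.optimize_mdf(pw)
        at_mdf = sum(enzyme_demand(r, mdf_sol.ln_conc, pw.rel_flux[r.id])
                     for r in pw.reactions)
        sol = minimize_pathway_cost(pw, seed=0, n_restarts=2)
        assert sol.total_cost <= at_mdf * (1 + 1e-9)

    def test_infeasible_pathway_names_bottleneck(self):
        r = uni_uni(dg0=+50.0)  # cannot be made favorable within bounds
        pw = PathwayModel(reactions=[r], rel_flux={"r": 1.0},
                          fixed_conc={"S": 1.0, "P": 1.0},
                          boundary={"S", "P"})
        with pytest.raises(ValueError, match="r"):
            minimize_pathway_cost(pw)

    def test_cost_scales_linearly_with_flux(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=2, seed=17))
        sol1 = minimize_pathway_cost(pw, seed=0, n_restarts=3)
        doubled = PathwayModel(
            reactions=pw.reactions,
            rel_flux={k: 2 * v for k, v in pw.rel_flux.items()},
            fixed_conc=dict(pw.fixed_conc), boundary=set(pw.boundary))
        sol2 = minimize_pathway_cost(doubled, seed=0, n_restarts=3)
        assert sol2.total_cost == pytest.approx(2 * sol1.total_cost,
                                                rel=1e-3)


class TestTimecourseCost:
    def test_constant_substrate_constant_cost(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=2, seed=2))
        series = {"A0": np.full(4, 1.0)}
        total, traces, infeasible = timecourse_cost(pw, series, seed=0)
        assert infeasible == []
        assert np.allclose(total, total[0], rtol=1e-3)

    def test_transporter_cost_inverse_in_substrate(self, reference_params):
        """Far below Km, halving the substrate doubles the carrier cost."""
        kin = EnzymeKinetics(kcat_fwd=100.0, km={"glc_e": 40.0}, mw=5e4,
                             irreversible=True)
        glf = ThermoReaction(id="glf", stoich={"glc_e": -1.0, "glc": 1.0},
                             dg0_prime=0.0, reversible=False, kinetics=kin)
        pw = PathwayModel(reactions=[glf], rel_flux={"glf": 1.0},
                          fixed_conc={"glc_e": 0.4}, boundary={"glc_e", "glc"})
        costs = []
        for s in (0.4, 0.2):  # mM, both << Km = 40 mM
            sol = minimize_pathway_cost(pw.with_fixed_conc({"glc_e": s}),
                                        seed=0, n_restarts=2)
            costs.append(sol.per_enzyme_cost["glf"])
        assert costs[1] == pytest.approx(2.0 * costs[0], rel=0.01)

    def test_cost_non_increasing_in_substrate(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=2, seed=19))
        series = {"A0": np.array([5.0, 2.0, 1.0, 0.3, 0.05])}
        total, _, infeasible = timecourse_cost(pw, series, seed=0,
                                               n_restarts=3)
        assert infeasible == []
        assert np.all(np.diff(total) >= -abs(total[0]) * 1e-3)
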