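"""Tests for pathway yields, reaction Gibbs energies and MDF optimization."""

import numpy as np
import pytest

import zymoflux as zf
from zymoflux.pathway_thermo import (
    R_KJ_MOL_K, ThermoReaction, PathwayModel, reaction_dg, optimize_mdf,
    cumulative_profile, standard_state_profile, timecourse_mdf,
    bottleneck_report, cofactor_ratio_scan, net_yields,
)
from zymoflux.synthetic_data import ToyPathwaySpec, generate_toy_pathway
from conftest import two_state_chain, grid_mdf

RT = R_KJ_MOL_K * 298.15


class TestNetYields:
    def test_glucose_route_yields(self, glucose_pathway):
        y = net_yields(glucose_pathway)
        assert y["atp"] == pytest.approx(1.0)
        assert y["glc_e"] == pytest.approx(-1.0)
        assert y["co2"] == pytest.approx(2.0)
        assert y["bdo"] == pytest.approx(1.0)

    def test_xylose_route_yields(self, xylose_pathway):
        y = net_yields(xylose_pathway)
        assert y["atp"] == pytest.approx(1.2)
        assert y["xyl_e"] == pytest.approx(-1.2)
        assert y["co2"] == pytest.approx(2.0)

    def test_carbon_balance_both_routes(self, glucose_pathway, xylose_pathway):
        for pw in (glucose_pathway, xylose_pathway):
            y = net_yields(pw)
            c_in = sum(-v * pw.carbon[m] for m, v in y.items() if v < 0)
            c_out = sum(v * pw.carbon[m] for m, v in y.items() if v > 0)
            assert c_in == pytest.approx(c_out)
            # per-reaction carbon closure
            for r in pw.reactions:
                assert r.carbon_imbalance(pw.carbon) == pytest.approx(0.0)

    def test_steady_state_violation_names_metabolite(self):
        r1 = ThermoReaction(id="r1", stoich={"A": -1.0, "B": 1.0})
        r2 = ThermoReaction(id="r2", stoich={"B": -2.0, "C": 1.0})
        with pytest.raises(ValueError, match="B"):
            PathwayModel(reactions=[r1, r2],
                         rel_flux={"r1": 1.0, "r2": 1.0},
                         boundary={"A", "C"})


class TestReactionDg:
    def test_standard_state(self):
        r = ThermoReaction(id="r", stoich={"A": -1.0, "B": 1.0},
                           dg0_prime=-7.5)
        assert reaction_dg(r, {"A": 0.0, "B": 0.0}) == pytest.approx(-7.5)

    def test_concentration_ratio_term(self):
        r = ThermoReaction(id="r", stoich={"A": -1.0, "B": 1.0},
                           dg0_prime=0.0)
        ln_c = {"A": np.log(1e-3), "B": np.log(1e-2)}
        assert reaction_dg(r, ln_c) == pytest.approx(RT * np.log(10),
                                                     rel=1e-6)
        assert RT * np.log(10) == pytest.approx(5.708, abs=5e-3)

    def test_balanced_reaction_invariant_to_scaling(self):
        r = ThermoReaction(id="r", stoich={"A": -1.0, "B": 1.0},
                           dg0_prime=3.0)
        base = {"A": np.log(2e-3), "B": np.log(5e-4)}
        doubled = {m: v + np.log(2) for m, v in base.items()}
        assert reaction_dg(r, doubled) == pytest.approx(
            reaction_dg(r, base), rel=1e-12)

    def test_missing_metabolite_named(self):
        r = ThermoReaction(id="r", stoich={"A": -1.0, "B": 1.0},
                           dg0_prime=0.0)
        with pytest.raises(KeyError, match="B"):
            reaction_dg(r, {"A": 0.0})


class TestOptimizeMdf:
    def test_single_reaction_closed_form(self):
        r = ThermoReaction(id="r1", stoich={"A": -1.0, "B": 1.0},
                           dg0_prime=0.0)
        pw = PathwayModel(reactions=[r], rel_flux={"r1": 1.0},
                          boundary={"A", "B"})
        sol = optimize_mdf(pw)
        assert sol.mdf == pytest.approx(RT * np.log(1e4), rel=1e-6)
        assert sol.mdf == pytest.approx(22.83, abs=0.01)

    def test_two_reaction_chain_halves(self):
        pw = two_state_chain()
        pw.fixed_conc.clear()  # both ends free
        sol = optimize_mdf(pw)
        assert sol.mdf == pytest.approx(RT * np.log(1e4) / 2, rel=1e-6)
        assert sol.mdf == pytest.approx(11.41, abs=0.01)

    @pytest.mark.parametrize("seed", range(6))
    def test_lp_matches_grid_oracle(self, seed):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=3, seed=seed))
        lp = optimize_mdf(pw).mdf
        grid = grid_mdf(pw)
        assert abs(lp - grid) <= 0.1

    def test_maximin_tightness(self):
        """At the optimum at least one reaction sits exactly at -dG' = B."""
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=4, seed=11))
        sol = optimize_mdf(pw)
        gaps = [-dg - sol.mdf for dg in sol.dg_prime.values()]
        assert min(gaps) >= -1e-6
        assert min(gaps) == pytest.approx(0.0, abs=1e-6)

    def test_concentrations_respect_bounds_and_pins(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=3, seed=2))
        sol = optimize_mdf(pw)
        lo = np.log(pw.conc_lb * 1e-3) - 1e-9
        hi = np.log(pw.conc_ub * 1e-3) + 1e-9
        for m, x in sol.ln_conc.items():
            if m in pw.fixed_conc:
                assert x == pytest.approx(np.log(pw.fixed_conc[m] * 1e-3))
            else:
                assert lo <= x <= hi

    def test_tightening_upper_bound_cannot_increase_mdf(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=3, seed=8))
        base = optimize_mdf(pw).mdf
        pw_tight = pw.with_fixed_conc({})
        pw_tight.conc_ub = pw.conc_ub / 10
        assert optimize_mdf(pw_tight).mdf <= base + 1e-9

    def test_contradictory_pins_report_infeasible(self):
        pw = two_state_chain()
        pw.fixed_conc.update({"A": 1.0, "C": 1.0})
        with pytest.raises(RuntimeError, match="infeasible"):
            optimize_mdf(pw, extra_equalities=[("A", "C", np.log(50.0))])

    def test_missing_dg0_is_explicit(self, glucose_pathway):
        with pytest.raises(ValueError, match="dg0_prime"):
            optimize_mdf(glucose_pathway)


class TestProfilesAndScans:
    def test_cumulative_profile_single_and_total_invariance(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=3, seed=4))
        sol = optimize_mdf(pw)
        prof = cumulative_profile(sol, ["r1"])
        assert prof == [pytest.approx(sol.dg_prime["r1"])]
        order = ["r1", "r2", "r3"]
        shuffled = ["r3", "r1", "r2"]
        assert cumulative_profile(sol, order)[-1] == pytest.approx(
            cumulative_profile(sol, shuffled)[-1])
        with pytest.raises(KeyError):
            cumulative_profile(sol, ["r1", "nope"])

    def test_standard_state_profile_at_1mM(self):
        pw = two_state_chain(dg0_1=-3.0, dg0_2=5.0)
        prof = standard_state_profile(pw, conc_mM=1.0)
        # uni-uni steps at equal concentrations: dG' = dG0'
        assert prof == [pytest.approx(-3.0), pytest.approx(2.0)]

    def test_timecourse_constant_series_constant_mdf(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=2, seed=5))
        series = {"A0": np.full(5, 1.0)}
        mdf, total, traces, _ = timecourse_mdf(pw, series)
        assert np.allclose(mdf, mdf[0])
        assert np.allclose(total, total[0])
        assert set(traces) == {"r1", "r2"}

    def test_decreasing_substrate_weakens_driving_force(self):
        pw = generate_toy_pathway(ToyPathwaySpec(n_reactions=3, seed=6))
        series = {"A0": np.geomspace(10.0, 1e-4, 12)}  # clipped at floor
        _, total, _, _ = timecourse_mdf(pw, series)
        assert np.all(np.diff(total) >= -1e-9)

    def test_bottleneck_report(self, glucose_pathway_merged,
                               xylose_pathway_merged):
        assert bottleneck_report(glucose_pathway_merged) == \
            ["g6pdh", "gapdh", "pgm"]
        assert bottleneck_report(xylose_pathway_merged) == \
            ["xyl", "rpe", "g6pdh", "gapdh", "pgm"]

    def test_bottleneck_threshold_edge(self):
        pw = two_state_chain(dg0_1=-10.0, dg0_2=0.001)
        assert bottleneck_report(pw) == ["r2"]
        pw_ok = two_state_chain(dg0_1=-10.0, dg0_2=-10.0)
        assert bottleneck_report(pw_ok) == []

    def test_cofactor_scan_requires_cofactor(self):
        pw = two_state_chain()
        with pytest.raises(KeyError):
            cofactor_ratio_scan(pw, "ATP/ADP", [1.0])

    def test_atp_consuming_chain_monotone_in_ratio(self):
        # A + atp -> B + adp: lower ATP/ADP weakens the ATP-driven step,
        # so total dG' increases (less negative) as the ratio drops... the
        # reaction *consumes* ATP, so a high ratio drives it forward.
        r1 = ThermoReaction(id="r1",
                            stoich={"A": -1.0, "atp": -1.0,
                                    "B": 1.0, "adp": 1.0},
                            dg0_prime=-5.0)
        pw = PathwayModel(reactions=[r1], rel_flux={"r1": 1.0},
                          fixed_conc={"A": 1.0, "B": 1.0},
                          boundary={"A", "B", "atp", "adp"})
        ratios = [0.1, 1.0, 10.0]
        out = cofactor_ratio_scan(pw, "ATP/ADP", ratios)
        totals = [t for _, t, _ in out]
        assert totals[0] > totals[1] > totals[2]

    def test_ratio_one_matches_equal_pin(self):
        r1 = ThermoReaction(id="r1",
                            stoich={"A": -1.0, "atp": -1.0,
                                    "B": 1.0, "adp": 1.0},
                            dg0_prime=-5.0)
        pw = PathwayModel(reactions=[r1], rel_flux={"r1": 1.0},
                          fixed_conc={"A": 1.0, "B": 1.0,
                                      "atp": 1.0, "adp": 1.0},
                          boundary={"A", "B", "atp", "adp"})
        (_, total, mdf), = cofactor_ratio_scan(pw, "ATP/ADP", [1.0])
        ref = optimize_mdf(pw)
        assert total == pytest.approx(ref.total_dg, abs=1e-8)


class TestPathwayIO:
    def test_round_trip(self, glucose_pathway, tmp_path):
        from zymoflux.pathway_thermo import pathway_to_dict, pathway_from_dict
        doc = pathway_to_dict(glucose_pathway)
        back = pathway_from_dict(doc)
        assert [r.id for r in back.reactions] == \
            [r.id for r in glucose_pathway.reactions]
        assert back.rel_flux == glucose_pathway.rel_flux
        assert net_yields(back) == net_yields(glucose_pathway)

    def test_load_from_file(self, tmp_path, glucose_pathway):
        import json
        from zymoflux.pathway_thermo import pathway_to_dict
        p = tmp_path / "pw.json"
        p.write_text(json.dumps(pathway_to_dict(glucose_pathway)))
        pw = zf.load_pathway(p)
        assert net_yields(pw)["atp"] == pytest.approx(1.0)
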