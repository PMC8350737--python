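import numpy as np
import pytest

import zymoflux as zf
from zymoflux.pathway_thermo import ThermoReaction, PathwayModel


REFERENCE_FIT = zf.TransporterKinetics(
    vmax_glc=29.30, km_glc=40.21, ki_glc=600.0,
    vmax_xyl=3.18, km_xyl=80.96, ki_xyl=200.0)


@pytest.fixture(scope="session")
def reference_params():
    """The fitted glf constants used as synthetic ground truth."""
    return REFERENCE_FIT


@pytest.fixture(scope="session")
def synthetic_table():
    from importlib import resources
    path = resources.files("zymoflux.data").joinpath("synthetic_params.tsv")
    return zf.load_parameter_table(path)


@pytest.fixture(scope="session")
def glucose_pathway():
    return zf.shipped_pathway("glucose_bdo")


@pytest.fixture(scope="session")
def xylose_pathway():
    return zf.shipped_pathway("xylose_bdo")


@pytest.fixture(scope="session")
def glucose_pathway_merged(glucose_pathway, synthetic_table):
    pw, checklist = zf.merge_parameters(glucose_pathway, synthetic_table)
    assert checklist == []
    return pw


@pytest.fixture(scope="session")
def xylose_pathway_merged(xylose_pathway, synthetic_table):
    pw, checklist = zf.merge_parameters(xylose_pathway, synthetic_table)
    assert checklist == []
    return pw


@pytest.fixture(scope="session")
def core_net():
    """Shared read-only core network; tests that mutate bounds must copy."""
    return zf.build_core_network()


@pytest.fixture(scope="session")
def noiseless_course(reference_params):
    spec = zf.SyntheticBatchSpec(noise_cv=0.0, seed=7)
    return zf.generate_fermentation(spec)


def two_state_chain(dg0_1=0.0, dg0_2=0.0):
    """A↔B↔C chain with A pinned at 1 mM, for closed-form MDF checks."""
    r1 = ThermoReaction(id="r1", stoich={"A": -1.0, "B": 1.0}, dg0_prime=dg0_1)
    r2 = ThermoReaction(id="r2", stoich={"B": -1.0, "C": 1.0}, dg0_prime=dg0_2)
    return PathwayModel(reactions=[r1, r2], rel_flux={"r1": 1.0, "r2": 1.0},
                        boundary={"A", "C"}, product="C")


def grid_mdf(pathway, n_coarse=41, n_fine=41):
    """Brute-force MDF oracle: dense grid over free metabolite
    log-concentrations with one local refinement pass."""
    rt = zf.pathway_thermo.R_KJ_MOL_K * pathway.temperature
    mets = pathway.metabolites()
    free = [m for m in mets if m not in pathway.fixed_conc]
    pinned = {m: np.log(c * 1e-3) for m, c in pathway.fixed_conc.items()}
    lo, hi = np.log(pathway.conc_lb * 1e-3), np.log(pathway.conc_ub * 1e-3)

    def evaluate(axes):
        grids = np.meshgrid(*axes, indexing="ij")
        worst = None
        for r in pathway.reactions:
            if not r.reversible:
                continue
            dg = np.full(grids[0].shape, r.dg0_prime)
            for m, nu in r.stoich.items():
                if m in pinned:
                    dg = dg + rt * nu * pinned[m]
                else:
                    dg = dg + rt * nu * grids[free.index(m)]
            neg = -dg
            worst = neg if worst is None else np.minimum(worst, neg)
        idx = np.unravel_index(np.argmax(worst), worst.shape)
        return worst[idx], [axes[d][idx[d]] for d in range(len(axes))]

    axes = [np.linspace(lo, hi, n_coarse) for _ in free]
    best, centre = evaluate(axes)
    step = (hi - lo) / (n_coarse - 1)
    axes = [np.linspace(max(lo, c - step), min(hi, c + step), n_fine)
            for c in centre]
    best, _ = evaluate(axes)
    return best
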