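"""Synthetic fermentation courses and toy pathways with known ground truth.

The fermentation generator emulates the batch co-fermentation used to fit
the transporter model: glucose and xylose start at 443 and 245 mM, deplete
over a 65 h batch according to the competitive-inhibition uptake kinetics,
and biomass follows a prescribed logistic curve (growth is *not* emergent —
the fitting procedure treats biomass as data). Measurement noise is
multiplicative Gaussian (value × (1 + cv·ε), clamped at zero), emulating
HPLC error that scales with concentration.

The toy pathway generator builds linear uni-uni chains A₀→A₁→…→Aₙ with
sampled ΔG°′, Km, kcat and MW, small enough for brute-force grid oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .uptake_kinetics import TransporterKinetics, FermentationTimeCourse, simulate_uptake
from .pathway_thermo import ThermoReaction, PathwayModel

__all__ = [
    "DEFAULT_TRUE_PARAMS", "SyntheticBatchSpec", "SyntheticFermentation",
    "ToyPathwaySpec", "generate_fermentation", "generate_toy_pathway",
    "logistic_biomass",
]

#: defaults for generation: fitted Vmax/Km point estimates for the BC42C
#: Δpdc strain; Ki values are stand-ins (Ki_glc chosen well above Ki_xyl,
#: consistent with glucose inhibition of the carrier being weak)
DEFAULT_TRUE_PARAMS = TransporterKinetics(
    vmax_glc=29.30, km_glc=40.21, ki_glc=600.0,
    vmax_xyl=3.18, km_xyl=80.96, ki_xyl=200.0)


@dataclass(frozen=True)
class SyntheticBatchSpec:
    true_params: TransporterKinetics = DEFAULT_TRUE_PARAMS
    initial_glc: float = 443.0  # mM
    initial_xyl: float = 245.0  # mM
    initial_biomass: float = 0.277  # gDCW/L (OD 0.84 x 0.33 g/L/OD)
    growth_rate: float = 0.12  # h^-1, logistic specific growth rate
    carrying_capacity: float = 5.0  # gDCW/L
    t_end: float = 65.0  # h
    n_samples: int = 27
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("initial_glc", "initial_xyl", "initial_biomass",
                     "growth_rate", "carrying_capacity", "t_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 <= self.noise_cv < 0.5:
            raise ValueError("noise_cv must be in [0, 0.5)")


@dataclass
class SyntheticFermentation:
    noisy: FermentationTimeCourse
    noiseless: FermentationTimeCourse
    spec: SyntheticBatchSpec


def logistic_biomass(spec: SyntheticBatchSpec):
    """Logistic biomass curve X(t) for the generator's prescribed growth."""
    x0, r, k = spec.initial_biomass, spec.growth_rate, spec.carrying_capacity

    def curve(t):
        if x0 == 0 or r == 0:
            return x0
        e = np.exp(r * np.asarray(t, dtype=float))
        return float(k * x0 * e / (k + x0 * (e - 1.0)))

    return curve


def generate_fermentation(spec: SyntheticBatchSpec) -> SyntheticFermentation:
    """Generate a batch co-fermentation course from known transporter
    parameters. Returns noisy and noiseless channels side by side."""
    t_grid = np.linspace(0.0, spec.t_end, spec.n_samples)
    logistic = logistic_biomass(spec)
    # biomass enters as data: sample the logistic at the measurement times
    # and drive the sugar ODEs with its linear interpolation, exactly as the
    # estimation procedure does — the true parameters then sit in the
    # fitting model's class
    X_samples = np.array([logistic(t) for t in t_grid])
    from scipy.interpolate import interp1d
    curve = interp1d(t_grid, X_samples, kind="linear",
                     bounds_error=False,
                     fill_value=(X_samples[0], X_samples[-1]))
    try:
        clean = simulate_uptake(spec.true_params, spec.initial_glc,
                                spec.initial_xyl, curve, t_grid)
    except RuntimeError as err:
        raise RuntimeError(
            "fermentation generation failed; check true_params "
            f"({spec.true_params}): {err}") from err
    if not (np.all(np.isfinite(clean.glc)) and np.all(np.isfinite(clean.xyl))):
        raise RuntimeError(
            "non-finite trajectory from true_params "
            f"vmax_glc={spec.true_params.vmax_glc}, "
            f"vmax_xyl={spec.true_params.vmax_xyl}")
    rng = np.random.default_rng(spec.seed)

    def noisify(values):
        if spec.noise_cv == 0:
            return values.copy()
        eps = rng.standard_normal(values.shape)
        return np.clip(values * (1.0 + spec.noise_cv * eps), 0.0, None)

    noisy = FermentationTimeCourse(
        time=t_grid.copy(), glc=noisify(clean.glc), xyl=noisify(clean.xyl),
        biomass=noisify(clean.biomass))
    return SyntheticFermentation(noisy=noisy, noiseless=clean, spec=spec)


@dataclass(frozen=True)
class ToyPathwaySpec:
    n_reactions: int = 3
    dg0_range: tuple = (-15.0, 5.0)  # kJ/mol
    km_range: tuple = (0.05, 2.0)  # mM
    kcat_range: tuple = (10.0, 200.0)  # s^-1
    mw_range: tuple = (3e4, 1e5)  # g/mol
    seed: int = 0

    def __post_init__(self):
        if self.n_reactions < 1:
            raise ValueError("n_reactions must be >= 1")
        for name in ("dg0_range", "km_range", "kcat_range", "mw_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be an ordered interval")


def generate_toy_pathway(spec: ToyPathwaySpec) -> PathwayModel:
    """A linear chain A0 → A1 → … → An of reversible uni-uni reactions with
    sampled parameters, unit relative flux, the first metabolite pinned at
    1 mM and the rest free within default bounds."""
    from .enzyme_cost import EnzymeKinetics  # deferred: import cycle

    rng = np.random.default_rng(spec.seed)
    n = spec.n_reactions
    mets = [f"A{i}" for i in range(n + 1)]
    reactions = []
    for i in range(n):
        dg0 = float(rng.uniform(*spec.dg0_range))
        km_s = float(np.exp(rng.uniform(*np.log(spec.km_range))))
        km_p = float(np.exp(rng.uniform(*np.log(spec.km_range))))
        kcat = float(np.exp(rng.uniform(*np.log(spec.kcat_range))))
        mw = float(rng.uniform(*spec.mw_range))
        kin = EnzymeKinetics(kcat_fwd=kcat,
                             km={mets[i]: km_s, mets[i + 1]: km_p}, mw=mw)
        reactions.append(ThermoReaction(
            id=f"r{i + 1}", stoich={mets[i]: -1.0, mets[i + 1]: 1.0},
            dg0_prime=dg0, reversible=True, kinetics=kin))
    return PathwayModel(
        reactions=reactions, rel_flux={r.id: 1.0 for r in reactions},
        fixed_conc={mets[0]: 1.0}, boundary={mets[0], mets[-1]},
        product=mets[-1], name=f"toy-chain-{n}")
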