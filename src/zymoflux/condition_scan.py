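"""In-silico fermentation condition scans scored by 2,3-BDO productivity.

Two scans mirror the model-guided optimization of the fermentation:
initial glucose:xylose molar ratio at constant total substrate carbon, and
the oxygen transfer coefficient kLa (proxy for agitation/aeration). The
objective is the maximum 2,3-BDO productivity, max_t [BDO](t)/t; the final
titer is reported alongside because the two objectives favor different
aeration levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .uptake_kinetics import TransporterKinetics
from .core_dfba import (
    CoreNetwork, ExtracellularState, GasTransfer, UptakeLimits,
    BatchTrajectory, simulate_batch, od_to_biomass,
)

__all__ = ["ScanResult", "max_productivity", "sugar_ratio_scan", "kla_scan",
           "DEFAULT_TOTAL_CMOL"]

#: total substrate carbon of the validation condition: 6·443 + 5·245 mM C
DEFAULT_TOTAL_CMOL = 6 * 443.0 + 5 * 245.0


@dataclass
class ScanResult:
    axis: str
    values: list
    trajectories: list  # BatchTrajectory per value
    max_productivity: list  # mmol L^-1 h^-1
    t_at_max: list  # h
    final_titer: list  # mM

    def __post_init__(self):
        n = len(self.values)
        for name in ("trajectories", "max_productivity", "t_at_max",
                     "final_titer"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.axis: self.values,
            "max_productivity_mmol_L_h": self.max_productivity,
            "t_at_max_h": self.t_at_max,
            "final_bdo_mM": self.final_titer,
        })


def max_productivity(traj: BatchTrajectory) -> tuple[float, float]:
    """Maximum 2,3-BDO productivity: max over sampled t > 0 of [BDO](t)/t,
    and its argmax time (earliest on ties)."""
    times = np.array([s.time for s in traj.states])
    bdo = np.array([s.bdo for s in traj.states])
    mask = times > 0
    if not np.any(mask):
        raise ValueError("trajectory has no samples at t > 0")
    t, b = times[mask], bdo[mask]
    prod = b / t
    if np.all(prod == 0):
        return 0.0, float(t[0])
    i = int(np.argmax(prod))  # argmax returns the first (earliest) maximum
    return float(prod[i]), float(t[i])


def _run(net, tk, ul, gas, init, t_end, dt, reuptake):
    traj = simulate_batch(net, tk, ul=ul, gas=gas, init=init,
                          t_end=t_end, dt=dt, reuptake=reuptake)
    p, t_at = max_productivity(traj)
    return traj, p, t_at, traj.states[-1].bdo


def sugar_ratio_scan(ratios, total_cmol: float = DEFAULT_TOTAL_CMOL,
                     net: CoreNetwork = None,
                     tk: TransporterKinetics = None,
                     ul: UptakeLimits | None = None,
                     gas: GasTransfer | None = None,
                     initial_biomass: float | None = None,
                     t_end: float = 65.0, dt: float = 0.1,
                     reuptake: bool = True) -> ScanResult:
    """Simulate batches at different glucose:xylose molar ratios with total
    substrate carbon held constant: 6·glc + 5·xyl = total_cmol, glc = r·xyl.
    """
    if total_cmol <= 0:
        raise ValueError("total_cmol must be > 0")
    gas = gas or GasTransfer()
    X0 = od_to_biomass(0.84) if initial_biomass is None else initial_biomass
    trajs, prods, t_at, titers = [], [], [], []
    for r in ratios:
        if r <= 0:
            raise ValueError("ratios must be > 0")
        xyl0 = total_cmol / (6.0 * r + 5.0)
        glc0 = r * xyl0
        init = ExtracellularState(glc=glc0, xyl=xyl0, o2=gas.o2_sat,
                                  biomass=X0)
        traj, p, t, titer = _run(net, tk, ul, gas, init, t_end, dt, reuptake)
        trajs.append(traj)
        prods.append(p)
        t_at.append(t)
        titers.append(titer)
    return ScanResult(axis="glc_xyl_ratio", values=list(ratios),
                      trajectories=trajs, max_productivity=prods,
                      t_at_max=t_at, final_titer=titers)


def kla_scan(kla_values, net: CoreNetwork = None,
             tk: TransporterKinetics = None,
             ul: UptakeLimits | None = None,
             init: ExtracellularState | None = None,
             o2_sat: float = 0.21, t_end: float = 65.0, dt: float = 0.1,
             reuptake: bool = True) -> ScanResult:
    """Simulate batches over a grid of O₂ mass-transfer coefficients."""
    trajs, prods, t_at, titers = [], [], [], []
    for kla in kla_values:
        if kla < 0:
            raise ValueError("kla must be >= 0")
        gas = GasTransfer(kla=kla, o2_sat=o2_sat)
        base = init or ExtracellularState(glc=443.0, xyl=245.0,
                                          o2=min(o2_sat, o2_sat if kla > 0 else 0.0),
                                          biomass=od_to_biomass(0.84))
        start = ExtracellularState(**vars(base))
        traj, p, t, titer = _run(net, tk, ul, gas, start, t_end, dt, reuptake)
        trajs.append(traj)
        prods.append(p)
        t_at.append(t)
        titers.append(titer)
    return ScanResult(axis="kla_per_h", values=list(kla_values),
                      trajectories=trajs, max_productivity=prods,
                      t_at_max=t_at, final_titer=titers)
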