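"""Dual-substrate sugar uptake kinetics of the *Z. mobilis* glucose
facilitator (glf).

Glf is a low-affinity, high-velocity uniporter that carries both glucose and
xylose; each sugar competitively inhibits uptake of the other. The uptake
rate of glucose is

    v_glc = Vmax_glc * [glc] / (Km_glc * (1 + [xyl]/Ki_xyl) + [glc])

and symmetrically for xylose. Extracellular depletion follows
d[S]/dt = -v_S * [X] with biomass [X] prescribed by the data (linear
interpolation between measured points). The six constants (Vmax, Km, Ki per
sugar) are estimated by multi-restart least squares on the simulated vs.
measured sugar concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d
from scipy.optimize import least_squares

__all__ = [
    "TransporterKinetics", "FermentationTimeCourse", "FitResult",
    "uptake_rates", "simulate_uptake", "fit_transporter", "r_squared",
    "uptake_surface", "specific_rates_from_course",
]

_PARAM_NAMES = ("vmax_glc", "km_glc", "ki_glc", "vmax_xyl", "km_xyl", "ki_xyl")

# fitting box constraints (mM or mmol gDCW^-1 h^-1); Ki is fit in log space
# over [1, 1e4] mM to tame its flat likelihood
_BOUNDS_LO = np.array([1e-3, 1e-2, 1.0, 1e-3, 1e-2, 1.0])
_BOUNDS_HI = np.array([1e3, 1e4, 1e4, 1e3, 1e4, 1e4])


@dataclass(frozen=True)
class TransporterKinetics:
    """The six glf constants: Vmax (mmol gDCW⁻¹ h⁻¹), Km and Ki (mM)."""

    vmax_glc: float
    km_glc: float
    ki_glc: float
    vmax_xyl: float
    km_xyl: float
    ki_xyl: float

    def __post_init__(self):
        for name in _PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            # Vmax = 0 encodes an inactive carrier (useful in synthetic
            # scenarios); the binding constants must be strictly positive
            if name.startswith("vmax") and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
            if not name.startswith("vmax") and v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _PARAM_NAMES])

    @classmethod
    def from_array(cls, a) -> "TransporterKinetics":
        return cls(**dict(zip(_PARAM_NAMES, map(float, a))))

    def to_dict(self) -> dict:
        d = {n: float(getattr(self, n)) for n in _PARAM_NAMES}
        d["units"] = {"vmax": "mmol gDCW-1 h-1", "km": "mM", "ki": "mM"}
        return d


@dataclass
class FermentationTimeCourse:
    """Extracellular concentrations (mM) and biomass (gDCW L⁻¹) over time (h)."""

    time: np.ndarray
    glc: np.ndarray
    xyl: np.ndarray
    biomass: np.ndarray
    actn: np.ndarray | None = None
    bdo: np.ndarray | None = None
    glyc: np.ndarray | None = None
    o2: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        for name in ("glc", "xyl", "biomass", "actn", "bdo", "glyc", "o2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if v.shape != self.time.shape:
                    raise ValueError(f"{name} length does not match time")
                if np.any(v < 0):
                    raise ValueError(f"{name} has negative concentrations")
        if self.time.size < 2:
            raise ValueError("time course needs at least 2 rows")
        if np.any(~np.isfinite(self.time)):
            raise ValueError("missing/non-finite time values")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def biomass_interpolant(self):
        """Linear interpolation of biomass between data points."""
        return interp1d(self.time, self.biomass, kind="linear",
                        bounds_error=False,
                        fill_value=(self.biomass[0], self.biomass[-1]))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_h": self.time, "glc_mM": self.glc, "xyl_mM": self.xyl,
                "biomass_gdcw_L": self.biomass}
        for name, col in (("actn", "actn_mM"), ("bdo", "bdo_mM"),
                          ("glyc", "glyc_mM"), ("o2", "o2_mM")):
            v = getattr(self, name)
            if v is not None:
                cols[col] = v
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FermentationTimeCourse":
        def opt(col):
            return df[col].to_numpy() if col in df.columns else None
        return cls(time=df["time_h"].to_numpy(), glc=df["glc_mM"].to_numpy(),
                   xyl=df["xyl_mM"].to_numpy(),
                   biomass=df["biomass_gdcw_L"].to_numpy(),
                   actn=opt("actn_mM"), bdo=opt("bdo_mM"),
                   glyc=opt("glyc_mM"), o2=opt("o2_mM"))

    @classmethod
    def from_tsv(cls, path) -> "FermentationTimeCourse":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class FitResult:
    params: TransporterKinetics
    r_squared: float
    residual_ss: float
    converged: bool
    n_restarts_used: int
    restart_ss: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "r_squared": float(self.r_squared),
            "residual_ss_mM2": float(self.residual_ss),
            "converged": bool(self.converged),
            "n_restarts_used": int(self.n_restarts_used),
        }


def uptake_rates(glc, xyl, params: TransporterKinetics):
    """Specific uptake rates (mmol gDCW⁻¹ h⁻¹) at the given sugar
    concentrations (mM). Vectorized over ``glc``/``xyl``."""
    glc = np.asarray(glc, dtype=float)
    xyl = np.asarray(xyl, dtype=float)
    if np.any(glc < 0) or np.any(xyl < 0):
        raise ValueError("concentrations must be non-negative")
    v_glc = params.vmax_glc * glc / (
        params.km_glc * (1.0 + xyl / params.ki_xyl) + glc)
    v_xyl = params.vmax_xyl * xyl / (
        params.km_xyl * (1.0 + glc / params.ki_glc) + xyl)
    if v_glc.ndim == 0:
        return float(v_glc), float(v_xyl)
    return v_glc, v_xyl


def _rhs(t, y, params, biomass_curve):
    glc = max(y[0], 0.0)
    xyl = max(y[1], 0.0)
    X = float(biomass_curve(t))
    v_glc = params.vmax_glc * glc / (params.km_glc * (1 + xyl / params.ki_xyl) + glc)
    v_xyl = params.vmax_xyl * xyl / (params.km_xyl * (1 + glc / params.ki_glc) + xyl)
    return (-v_glc * X, -v_xyl * X)


def simulate_uptake(params: TransporterKinetics, initial_glc: float,
                    initial_xyl: float, biomass_curve, t_grid,
                    rtol: float = 1e-8, atol: float = 1e-8,
                    ) -> FermentationTimeCourse:
    """Integrate d[S]/dt = -v_S·[X] against a prescribed biomass curve.

    ``biomass_curve`` is any callable t (h) → gDCW L⁻¹ defined on the span of
    ``t_grid``. Concentrations are clamped at zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing with >= 2 points")
    sol = solve_ivp(_rhs, (t_grid[0], t_grid[-1]), [initial_glc, initial_xyl],
                    t_eval=t_grid, args=(params, biomass_curve),
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else t_grid[0]
        raise RuntimeError(
            f"uptake ODE integration failed at t={t_last:.3f} h: {sol.message}")
    glc = np.clip(sol.y[0], 0.0, None)
    xyl = np.clip(sol.y[1], 0.0, None)
    X = np.asarray([float(biomass_curve(t)) for t in t_grid])
    return FermentationTimeCourse(time=t_grid, glc=glc, xyl=xyl, biomass=X)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot.

    Returns ``nan`` when the observations have zero variance (R² undefined).
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size or observed.size < 2:
        raise ValueError("series must have equal length >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _course_residuals(logp, course, biomass_curve, rtol, w_glc=1.0, w_xyl=1.0):
    params = TransporterKinetics.from_array(10.0 ** logp)
    sol = solve_ivp(_rhs, (course.time[0], course.time[-1]),
                    [course.glc[0], course.xyl[0]], t_eval=course.time,
                    args=(params, biomass_curve), method="LSODA",
                    rtol=rtol, atol=rtol)
    if not sol.success:
        return np.full(2 * course.time.size, 1e6)
    return np.concatenate([(sol.y[0] - course.glc) * w_glc,
                           (sol.y[1] - course.xyl) * w_xyl])


def _heuristic_guess(course: FermentationTimeCourse) -> np.ndarray:
    """Crude data-driven start: Vmax from peak finite-difference specific
    rates, Km from the mid-range concentrations, Ki well above Km."""
    with np.errstate(divide="ignore", invalid="ignore"):
        v_glc = -np.gradient(course.glc, course.time) / course.biomass
        v_xyl = -np.gradient(course.xyl, course.time) / course.biomass
    def peak(v):
        v = v[np.isfinite(v)]
        return max(float(np.max(v, initial=0.0)), 1e-2)
    vmax_glc = 1.2 * peak(v_glc)
    vmax_xyl = 1.2 * peak(v_xyl)
    km_glc = max(float(np.median(course.glc)) / 4.0, 1.0)
    km_xyl = max(float(np.median(course.xyl)) / 4.0, 1.0)
    return np.array([vmax_glc, km_glc, 5.0 * km_glc,
                     vmax_xyl, km_xyl, 5.0 * km_xyl])


def fit_transporter(course: FermentationTimeCourse,
                    initial_guess: TransporterKinetics | None = None,
                    n_restarts: int = 20, seed: int = 0,
                    rtol: float = 1e-7,
                    weighting: str = "relative") -> FitResult:
    """Estimate the six glf constants by least squares on a time course.

    The loss pools glucose and xylose residuals across both channels.
    ``weighting="relative"`` (default) divides each residual by the observed
    concentration (floored at 2% of the initial value), matching the
    proportional error structure of HPLC measurements; ``"absolute"`` uses
    raw mM residuals. Biomass is linearly interpolated between data points.
    The first start is ``initial_guess`` when provided, else a crude
    estimate from finite-difference rates; the rest are drawn log-uniformly
    within the fitting box (deterministic given ``seed``).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if weighting == "relative":
        w_glc = 1.0 / np.maximum(course.glc, 0.02 * max(course.glc[0], 1.0))
        w_xyl = 1.0 / np.maximum(course.xyl, 0.02 * max(course.xyl[0], 1.0))
    elif weighting == "absolute":
        w_glc = w_xyl = np.ones(course.time.size)
    else:
        raise ValueError("weighting must be 'relative' or 'absolute'")
    biomass_curve = course.biomass_interpolant()
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(_BOUNDS_LO), np.log10(_BOUNDS_HI)
    starts = []
    if initial_guess is not None:
        starts.append(np.clip(np.log10(initial_guess.as_array()), lo, hi))
    else:
        starts.append(np.clip(np.log10(_heuristic_guess(course)), lo, hi))
    while len(starts) < n_restarts:
        starts.append(rng.uniform(lo, hi))

    best = None
    restart_ss = []
    any_converged = False
    for x0 in starts:
        try:
            res = least_squares(_course_residuals, x0, bounds=(lo, hi),
                                args=(course, biomass_curve, rtol,
                                      w_glc, w_xyl),
                                method="trf", ftol=1e-14, xtol=1e-13,
                                gtol=1e-14, diff_step=1e-4, max_nfev=600)
        except Exception:
            restart_ss.append(np.inf)
            continue
        ss = float(np.sum(res.fun ** 2))
        restart_ss.append(ss)
        if res.status > 0:
            any_converged = True
        if best is None or ss < best[0]:
            best = (ss, res.x)

    if best is None:
        raise RuntimeError("all restarts failed to evaluate")
    _, logp = best
    params = TransporterKinetics.from_array(10.0 ** logp)
    sim = simulate_uptake(params, course.glc[0], course.xyl[0],
                          biomass_curve, course.time, rtol=rtol, atol=rtol)
    obs = np.concatenate([course.glc, course.xyl])
    pred = np.concatenate([sim.glc, sim.xyl])
    r2 = r_squared(obs, pred)
    ss_mm2 = float(np.sum((obs - pred) ** 2))  # reported unweighted (mM^2)
    return FitResult(params=params, r_squared=r2, residual_ss=ss_mm2,
                     converged=any_converged, n_restarts_used=len(starts),
                     restart_ss=restart_ss)


def uptake_surface(params: TransporterKinetics, glc_grid, xyl_grid):
    """Rate matrices over a concentration grid; element [i, j] is the rate at
    (glc_grid[i], xyl_grid[j]). Mirrors the uptake-rate contour plots."""
    glc_grid = np.asarray(glc_grid, dtype=float)
    xyl_grid = np.asarray(xyl_grid, dtype=float)
    G, X = np.meshgrid(glc_grid, xyl_grid, indexing="ij")
    v_glc, v_xyl = uptake_rates(G, X, params)
    return np.atleast_2d(v_glc), np.atleast_2d(v_xyl)


def specific_rates_from_course(course: FermentationTimeCourse,
                               params: TransporterKinetics | None = None):
    """Specific uptake rates (mmol gDCW⁻¹ h⁻¹): −d[S]/dt divided by biomass.

    With ``params`` given, concentrations are first replaced by the model
    simulation (the fitted curve) before differentiating; otherwise central
    finite differences of the raw data are used. Points with zero biomass are
    returned as ``nan``.
    """
    if course.time.size < 3:
        raise ValueError("need at least 3 time points")
    if params is not None:
        sim = simulate_uptake(params, course.glc[0], course.xyl[0],
                              course.biomass_interpolant(), course.time)
        glc, xyl = sim.glc, sim.xyl
    else:
        glc, xyl = course.glc, course.xyl
    dglc = np.gradient(glc, course.time)
    dxyl = np.gradient(xyl, course.time)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_glc = np.where(course.biomass > 0, -dglc / course.biomass, np.nan)
        v_xyl = np.where(course.biomass > 0, -dxyl / course.biomass, np.nan)
    return v_glc, v_xyl
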