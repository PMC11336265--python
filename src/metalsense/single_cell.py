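"""Deterministic kinetics of one bacterium carrying n sensor-circuit copies.

Mechanism: a constitutive promoter produces the repressor R (ArsR, MerR or
PbrR).  Free repressor silences the metal-sensitive promoter through a Hill
term; ambient metal M sequesters R into an inactive metal-repressor dimer D,
derepressing the promoter and letting the chromoprotein C accumulate.
With n circuit copies per cell:

    dR/dt = n*alpha_R - k_bind*R*M + k_unbind*D - delta_R*R
    dD/dt = k_bind*R*M - k_unbind*D - delta_D*D
    dC/dt = n*alpha_C*P_on(R) - delta_C*C,   P_on(R) = 1 / (1 + (R/K_rep)^h)

The metal concentration is an imposed boundary condition (the bath is not
depleted), so R and D close among themselves and the steady state has the
closed form

    R_ss(M) = n*alpha_R / (delta_R + k_bind*M*delta_D/(k_unbind + delta_D))

which is what calibration and the steady-state dose response use.  A copy
counts as expressing when its promoter activity P_on exceeds
``on_fraction``; per-metal ``k_bind`` is calibrated so the dose response
flips exactly at the sensor's activation threshold (10 ug/L arsenic,
6 ug/L mercury, 10 ug/L lead).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ._defaults import load_defaults
from .errors import CalibrationError, NumericalFailureError
from .scenarios import ACTIVATION_THRESHOLD, Metal

#: tie tolerance when comparing promoter activity with on_fraction, so a
#: sensor calibrated to flip exactly at its threshold reads ON there
_ON_TOL = 1e-9

_ATOL = 1e-9
_RTOL = 1e-6


@dataclass(frozen=True)
class SingleCellParams:
    """Kinetic constants of the single-cell sensor model (units in doc above)."""

    n_copies: int = load_defaults()["kinetics"]["n_copies"]
    alpha_R: float = load_defaults()["kinetics"]["alpha_R"]
    delta_R: float = load_defaults()["kinetics"]["delta_R"]
    k_bind: float = load_defaults()["kinetics"]["k_bind"]
    k_unbind: float = load_defaults()["kinetics"]["k_unbind"]
    delta_D: float = load_defaults()["kinetics"]["delta_D"]
    K_rep: float = load_defaults()["kinetics"]["K_rep"]
    h: float = load_defaults()["kinetics"]["hill"]
    alpha_C: float = load_defaults()["kinetics"]["alpha_C"]
    delta_C: float = load_defaults()["kinetics"]["delta_C"]
    on_fraction: float = load_defaults()["kinetics"]["on_fraction"]

    def __post_init__(self) -> None:
        rates = (
            self.alpha_R, self.delta_R, self.k_bind, self.k_unbind,
            self.delta_D, self.alpha_C, self.delta_C,
        )
        if any(r < 0 for r in rates):
            raise ValueError("all rate constants must be non-negative")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if not 0.0 < self.on_fraction < 1.0:
            raise ValueError("on_fraction must lie in (0, 1)")
        if self.h < 1:
            raise ValueError("Hill coefficient must be >= 1")
        if self.K_rep <= 0:
            raise ValueError("K_rep must be positive")


@dataclass(frozen=True)
class SingleCellState:
    """Species of one cell at one instant."""

    t: float   # min
    R: float   # free repressor, molecules
    D: float   # metal-repressor dimer, molecules
    C: float   # chromoprotein, molecules
    M: float   # ambient metal, ug/L (imposed)


@dataclass(frozen=True)
class CellTimeSeries:
    """Output of :func:`simulate_cell` on the requested time grid."""

    times: np.ndarray              # min
    expressing_copies: np.ndarray  # real-valued n*P_on, for plotting
    R: np.ndarray
    D: np.ndarray
    C: np.ndarray
    n_copies: int

    @property
    def expressing_counts(self) -> np.ndarray:
        """Integer copy counts, ``round(n * P_on)``."""
        return np.rint(self.expressing_copies).astype(int)


def promoter_activity(R: float | np.ndarray, params: SingleCellParams):
    """Hill repression: fraction of time the reporter promoter is free."""
    return 1.0 / (1.0 + (np.asarray(R, dtype=float) / params.K_rep) ** params.h)


def steady_state_R(params: SingleCellParams, M: float) -> float:
    """Closed-form steady-state free repressor at ambient metal ``M``."""
    if M < 0:
        raise ValueError("metal concentration must be non-negative")
    sink = params.delta_R
    if M > 0 and params.k_bind > 0:
        # dimer branch drains repressor at rate k_bind*M*delta_D/(k_unbind+delta_D)
        sink += params.k_bind * M * params.delta_D / (params.k_unbind + params.delta_D)
    if sink == 0:
        return np.inf
    return params.n_copies * params.alpha_R / sink


def _rhs(t: float, y: np.ndarray, params: SingleCellParams, M: float) -> list[float]:
    R, D, C = y
    bind = params.k_bind * max(R, 0.0) * M
    unbind = params.k_unbind * max(D, 0.0)
    return [
        params.n_copies * params.alpha_R - bind + unbind - params.delta_R * R,
        bind - unbind - params.delta_D * D,
        params.n_copies * params.alpha_C * float(promoter_activity(max(R, 0.0), params))
        - params.delta_C * C,
    ]


def simulate_cell(
    params: SingleCellParams, M: float, t_end: float, dt_out: float
) -> CellTimeSeries:
    """Integrate the single-cell ODEs from an empty cell (R=D=C=0 at t=0).

    Returns species and the real-valued expressing-copy number
    ``n * P_on(R(t))`` on the grid ``0, dt_out, ..., t_end``.
    """
    if t_end <= 0 or dt_out <= 0:
        raise ValueError("t_end and dt_out must be positive")
    if M < 0:
        raise ValueError("metal concentration must be non-negative")
    times = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(
        _rhs,
        (0.0, float(times[-1])),
        [0.0, 0.0, 0.0],
        method="LSODA",
        t_eval=times,
        args=(params, M),
        atol=_ATOL,
        rtol=_RTOL,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise NumericalFailureError(
            f"integration failed at M={M}: {sol.message}"
        )
    R, D, C = (np.clip(sol.y[i], 0.0, None) for i in range(3))
    return CellTimeSeries(
        times=sol.t,
        expressing_copies=params.n_copies * promoter_activity(R, params),
        R=R,
        D=D,
        C=C,
        n_copies=params.n_copies,
    )


def steady_state_on(params: SingleCellParams, M: float) -> bool:
    """Whether the sensor is ON at steady state under ambient metal ``M``.

    ON means steady-state promoter activity >= ``on_fraction`` (up to a
    1e-9 tie tolerance); monotone non-decreasing in M.
    """
    R_ss = steady_state_R(params, M)
    if not np.isfinite(R_ss):
        return False
    return float(promoter_activity(R_ss, params)) >= params.on_fraction - _ON_TOL


def calibrate_threshold(
    params: SingleCellParams, target_threshold: float
) -> SingleCellParams:
    """Adjust ``k_bind`` so the steady-state dose response flips exactly at
    ``target_threshold`` (ug/L), via 1-D root finding on the closed-form
    steady state.  All other parameters are untouched."""
    if target_threshold <= 0:
        raise ValueError("target_threshold must be positive")

    def gap(k_bind: float) -> float:
        trial = replace(params, k_bind=k_bind)
        R_ss = steady_state_R(trial, target_threshold)
        return float(promoter_activity(R_ss, trial)) - params.on_fraction

    lo, hi = 1e-12, 1.0
    while gap(hi) < 0 and hi < 1e12:
        hi *= 10.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"no dose-response flip for threshold {target_threshold} ug/L in "
            f"k_bind bracket [{lo}, {hi}]; check alpha_R/delta_R/K_rep"
        )
    root = brentq(gap, lo, hi, xtol=1e-15, rtol=1e-14)
    return replace(params, k_bind=float(root))


def params_for(metal: Metal | str, **overrides) -> SingleCellParams:
    """Calibrated single-cell parameters for a sensor metal.

    Starts from the package defaults (optionally overridden) and calibrates
    ``k_bind`` to the sensor's activation threshold."""
    metal = Metal(metal)
    base = SingleCellParams(**overrides)
    return calibrate_threshold(base, ACTIVATION_THRESHOLD[metal])
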