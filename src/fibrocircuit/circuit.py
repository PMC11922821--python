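"""Four-variable myofibroblast-macrophage circuit: dynamics and fixed points.

State variables: F (fibroblasts/myofibroblasts, cells), M (macrophages,
cells), c12 (macrophage growth factor, molecules), c21 (fibroblast growth
factor, molecules).  The dynamics are

    dc12/dt = beta12*F - alpha12*c12/(k12+c12)*M - gamma*c12
    dc21/dt = beta11*F + beta21*M - alpha21*c21/(k21+c21)*F - gamma*c21
    dF/dt   = F*(lambda1*c21/(k21+c21)*(1-F/K) - mu1)
    dM/dt   = M*(lambda2*c12/(k12+c12) - mu2)

Growth factors are produced by cells, removed by receptor-mediated
endocytosis (saturating in the factor) and by first-order degradation.  F
proliferates logistically under c21 signalling up to carrying capacity K; M
proliferates under c12 signalling with no carrying capacity of its own.

The wild-type circuit is bistable: a *healing* state at the origin and a
*cold-fibrosis* state with F>0 and M=0.  Parameters are such that no stable
*hot* state (elevated F and M together) exists.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import CircuitParameters

__all__ = [
    "CircuitState", "Trajectory", "FixedPoint", "Outcome", "Stability",
    "circuit_derivatives", "circuit_jacobian", "simulate_circuit",
    "injury_initial_state", "default_injury_state", "find_fixed_points",
    "classify_state",
]

#: Default classification thresholds, as a fraction of the carrying capacity.
THETA_FRACTION = 1e-2

#: Scale-free steady-state criterion: max_i |dx_i/dt|/(|x_i|+1) below this.
STEADY_TOL = 1e-6

#: Default integration horizon in days.
DEFAULT_HORIZON = 1000.0

#: Eigenvalue real-part tolerance for stability calls (1/day).
EIG_TOL = 1e-8


class Outcome(str, enum.Enum):
    HEALING = "healing"
    COLD_FIBROSIS = "cold_fibrosis"
    HOT_FIBROSIS = "hot_fibrosis"
    OTHER = "other"


class Stability(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    SADDLE = "saddle"


@dataclasses.dataclass(frozen=True)
class CircuitState:
    F: float
    M: float
    c12: float
    c21: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite state component: {arr}")
        if np.any(arr < 0):
            raise ValueError(f"negative state component: {arr}")

    def as_array(self) -> np.ndarray:
        return np.array([self.F, self.M, self.c12, self.c21], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "CircuitState":
        y = np.asarray(y, dtype=float)
        return cls(F=float(y[0]), M=float(y[1]), c12=float(y[2]), c21=float(y[3]))


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """Time course of the circuit. ``states`` has one row (F,M,c12,c21) per time."""

    times: np.ndarray
    states: np.ndarray
    steady: bool = False

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> CircuitState:
        return CircuitState.from_array(self.states[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_days": self.times,
                "F_cells": self.states[:, 0],
                "M_cells": self.states[:, 1],
                "c12_molecules": self.states[:, 2],
                "c21_molecules": self.states[:, 3],
            }
        )


@dataclasses.dataclass(frozen=True)
class FixedPoint:
    state: CircuitState
    stability: Stability
    label: Outcome
    residual_norm: float
    eigenvalues: tuple[complex, ...] = ()


def _rhs(y: np.ndarray, p: CircuitParameters) -> np.ndarray:
    F, M, c12, c21 = np.maximum(y, 0.0)
    h12 = c12 / (p.k12 + c12)
    h21 = c21 / (p.k21 + c21)
    return np.array(
        [
            F * (p.lambda1 * h21 * (1.0 - F / p.K) - p.mu1),
            M * (p.lambda2 * h12 - p.mu2),
            p.beta12 * F - p.alpha12 * h12 * M - p.gamma * c12,
            p.beta11 * F + p.beta21 * M - p.alpha21 * h21 * F - p.gamma * c21,
        ]
    )


def circuit_derivatives(state: CircuitState, params: CircuitParameters) -> np.ndarray:
    """Right-hand side of the circuit ODEs as (dF, dM, dc12, dc21)/dt."""
    return _rhs(state.as_array(), params)


def circuit_jacobian(y: np.ndarray, p: CircuitParameters) -> np.ndarray:
    """Analytic Jacobian of the vector field at ``y = (F, M, c12, c21)``."""
    F, M, c12, c21 = np.maximum(np.asarray(y, dtype=float), 0.0)
    h12 = c12 / (p.k12 + c12)
    h21 = c21 / (p.k21 + c21)
    dh12 = p.k12 / (p.k12 + c12) ** 2
    dh21 = p.k21 / (p.k21 + c21) ** 2
    J = np.zeros((4, 4))
    J[0, 0] = p.lambda1 * h21 * (1.0 - 2.0 * F / p.K) - p.mu1
    J[0, 3] = F * p.lambda1 * dh21 * (1.0 - F / p.K)
    J[1, 1] = p.lambda2 * h12 - p.mu2
    J[1, 2] = M * p.lambda2 * dh12
    J[2, 0] = p.beta12
    J[2, 1] = -p.alpha12 * h12
    J[2, 2] = -p.alpha12 * dh12 * M - p.gamma
    J[3, 0] = p.beta11 - p.alpha21 * h21
    J[3, 1] = p.beta21
    J[3, 3] = -p.alpha21 * dh21 * F - p.gamma
    return J


def _steady_metric(y: np.ndarray, p: CircuitParameters) -> float:
    d = _rhs(y, p)
    return float(np.max(np.abs(d) / (np.abs(y) + 1.0)))


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time {last_time:g} d)")
        self.last_time = last_time


def simulate_circuit(
    params: CircuitParameters,
    init: CircuitState,
    horizon: float = DEFAULT_HORIZON,
    rtol: float = 1e-8,
    atol: Sequence[float] = (1e-6, 1e-6, 1e-3, 1e-3),
    steady_tol: float = STEADY_TOL,
    t_eval: Sequence[float] | None = None,
    stop_at_steady: bool = True,
) -> Trajectory:
    """Integrate the circuit from ``init`` with a stiff-capable adaptive solver.

    Stops early once the scale-free steady-state criterion
    max_i |dx_i/dt|/(|x_i|+1) < ``steady_tol`` is met (unless
    ``stop_at_steady`` is False or explicit output times are requested).
    Reported states are clipped at zero; the vector field itself keeps exact
    non-negative states invariant, so clipping only removes solver round-off.
    """
    if not (horizon > 0):
        raise ValueError("horizon must be positive")
    y0 = init.as_array()

    def rhs(t, y):
        return _rhs(y, params)

    def jac(t, y):
        return circuit_jacobian(y, params)

    events = None
    if stop_at_steady and t_eval is None:

        def steady_event(t, y):
            return _steady_metric(y, params) - steady_tol

        steady_event.terminal = True
        steady_event.direction = -1
        events = steady_event

    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        y0,
        method="LSODA",
        jac=jac,
        rtol=rtol,
        atol=list(atol),
        t_eval=None if t_eval is None else np.asarray(t_eval, dtype=float),
        events=events,
    )
    if not sol.success:
        raise IntegrationError(sol.message, float(sol.t[-1]) if len(sol.t) else 0.0)
    states = np.maximum(sol.y.T, 0.0)
    times = sol.t
    steady = _steady_metric(states[-1], params) < steady_tol
    return Trajectory(times=times, states=states, steady=steady)


def _quasi_steady_factor(production: float, alpha: float, k: float, cells: float,
                         gamma: float) -> float:
    """Unique non-negative root of production - alpha*c/(k+c)*cells - gamma*c.

    The loss side is strictly increasing in c, so the root is bracketed by
    [0, production/gamma] and unique.
    """
    if production == 0.0:
        return 0.0

    def f(c: float) -> float:
        return production - alpha * c / (k + c) * cells - gamma * c

    upper = production / gamma
    return float(brentq(f, 0.0, upper, xtol=1e-12, rtol=8.9e-16))


def injury_initial_state(params: CircuitParameters, F0: float, M0: float) -> CircuitState:
    """State with cell counts (F0, M0) and growth factors at quasi-steady state.

    The growth factors equilibrate on a faster timescale than the cells, so
    phase-portrait initial conditions are taken on the (F, M) plane with c12,
    c21 solved from dc/dt = 0 at the given cell counts.
    """
    if F0 < 0 or M0 < 0:
        raise ValueError("cell counts must be non-negative")
    c12 = _quasi_steady_factor(params.beta12 * F0, params.alpha12, params.k12, M0, params.gamma)
    c21 = _quasi_steady_factor(
        params.beta11 * F0 + params.beta21 * M0, params.alpha21, params.k21, F0, params.gamma
    )
    return CircuitState(F=F0, M=M0, c12=c12, c21=c21)


def default_injury_state(params: CircuitParameters) -> CircuitState:
    """Default acute-injury condition: macrophage-dominated transient.

    F0 = 0.05 K activated fibroblasts with M0 = 0.5 K infiltrating
    macrophages, growth factors at quasi-steady state.
    """
    return injury_initial_state(params, 0.05 * params.K, 0.5 * params.K)


def classify_state(
    state: CircuitState,
    params: CircuitParameters,
    theta_F: float | None = None,
    theta_M: float | None = None,
) -> Outcome:
    """Label a state healing / cold_fibrosis / hot_fibrosis by cell abundance.

    Defaults: theta_F = theta_M = 1e-2*K. Healing means both populations
    below threshold; cold fibrosis elevated F only; hot fibrosis both
    elevated. Elevated M with low F does not occur as an attractor and is
    labelled ``other``.
    """
    tF = THETA_FRACTION * params.K if theta_F is None else theta_F
    tM = THETA_FRACTION * params.K if theta_M is None else theta_M
    if state.F < tF and state.M < tM:
        return Outcome.HEALING
    if state.F >= tF and state.M < tM:
        return Outcome.COLD_FIBROSIS
    if state.F >= tF and state.M >= tM:
        return Outcome.HOT_FIBROSIS
    return Outcome.OTHER


def _stability(eigs: np.ndarray, tol: float = EIG_TOL) -> Stability | None:
    re = eigs.real
    if np.any(np.abs(re) < tol):
        return None  # marginal: caller labels the point "other"
    if np.all(re < 0):
        return Stability.STABLE
    if np.all(re > 0):
        return Stability.UNSTABLE
    return Stability.SADDLE


def _make_fixed_point(y: np.ndarray, params: CircuitParameters) -> FixedPoint:
    residual = float(np.max(np.abs(_rhs(y, params))))
    eigs = np.linalg.eigvals(circuit_jacobian(y, params))
    stab = _stability(eigs)
    state = CircuitState.from_array(np.maximum(y, 0.0))
    if stab is None:
        label = Outcome.OTHER
        stab = Stability.STABLE  # flagged marginal: conservatively kept
    else:
        label = classify_state(state, params)
    return FixedPoint(
        state=state,
        stability=stab,
        label=label,
        residual_norm=residual,
        eigenvalues=tuple(eigs),
    )


def _m_zero_branch_phi(F: float, params: CircuitParameters) -> float:
    """Phi(F) = h21(c21_qss(F, M=0)) * (1 - F/K) on the macrophage-free branch."""
    c21 = _quasi_steady_factor(params.beta11 * F, params.alpha21, params.k21, F, params.gamma)
    return c21 / (params.k21 + c21) * (1.0 - F / params.K)


def _m_zero_branch_roots(params: CircuitParameters, n_scan: int) -> list[np.ndarray]:
    """Fixed points with F>0, M=0: roots of lambda1*Phi(F) - mu1 on (0, K)."""

    def g(F: float) -> float:
        return params.lambda1 * _m_zero_branch_phi(F, params) - params.mu1

    Fs = np.logspace(-2, np.log10(params.K * 0.999999), n_scan)
    gs = np.array([g(F) for F in Fs])
    roots = []
    for i in range(len(Fs) - 1):
        if gs[i] == 0.0:
            roots.append(Fs[i])
        elif gs[i] * gs[i + 1] < 0:
            roots.append(brentq(g, Fs[i], Fs[i + 1], xtol=1e-10, rtol=8.9e-16))
    out = []
    for F in roots:
        c12 = params.beta12 * F / params.gamma  # no endocytosis at M=0
        c21 = _quasi_steady_factor(params.beta11 * F, params.alpha21, params.k21, F, params.gamma)
        out.append(np.array([F, 0.0, c12, c21]))
    return out


def _hot_branch_roots(params: CircuitParameters, n_scan: int) -> list[np.ndarray]:
    """Fixed points with F>0 and M>0.

    dM/dt=0 pins h12 = mu2/lambda2, hence c12* = mu2*k12/(lambda2-mu2);
    dc12/dt=0 then gives M(F); dF/dt=0 gives c21(F); the residual of
    dc21/dt=0 is scanned in F.
    """
    if params.lambda2 <= params.mu2:
        return []
    c12s = params.mu2 * params.k12 / (params.lambda2 - params.mu2)
    h12s = params.mu2 / params.lambda2
    F_lo = params.gamma * c12s / params.beta12  # M(F) >= 0
    F_hi = params.K * (1.0 - params.mu1 / params.lambda1)  # h21 <= 1
    if F_lo >= F_hi:
        return []

    def M_of(F: float) -> float:
        return (params.beta12 * F - params.gamma * c12s) / (params.alpha12 * h12s)

    def resid(F: float) -> float:
        s = params.mu1 / (params.lambda1 * (1.0 - F / params.K))
        c21 = params.k21 * s / (1.0 - s)
        return (
            params.beta11 * F
            + params.beta21 * M_of(F)
            - params.alpha21 * s * F
            - params.gamma * c21
        )

    eps = (F_hi - F_lo) * 1e-9
    Fs = np.linspace(F_lo + eps, F_hi - eps, n_scan)
    vals = np.array([resid(F) for F in Fs])
    out = []
    for i in range(len(Fs) - 1):
        if vals[i] * vals[i + 1] < 0:
            F = brentq(resid, Fs[i], Fs[i + 1], xtol=1e-10, rtol=8.9e-16)
            s = params.mu1 / (params.lambda1 * (1.0 - F / params.K))
            out.append(np.array([F, M_of(F), c12s, params.k21 * s / (1.0 - s)]))
    return out


def find_fixed_points(
    params: CircuitParameters,
    n_scan: int = 800,
    merge_rtol: float = 1e-6,
) -> list[FixedPoint]:
    """All fixed points of the circuit, with stability and outcome labels.

    The four-dimensional root problem factorises exactly by branch: the
    origin; the macrophage-free branch (F>0, M=0), reduced to a scalar root
    problem in F; and the coexistence branch (F>0, M>0), reduced via the
    pinned macrophage signalling level h12 = mu2/lambda2.  A branch with F=0
    and M>0 is impossible because c12 is produced only by F.  ``n_scan`` sets
    the density of the 1-D bracketing scans.
    """
    candidates = [np.zeros(4)]
    candidates += _m_zero_branch_roots(params, n_scan)
    candidates += _hot_branch_roots(params, n_scan)

    merged: list[np.ndarray] = []
    for y in candidates:
        if not any(np.all(np.abs(y - m) / (np.abs(m) + 1.0) < merge_rtol) for m in merged):
            merged.append(y)
    points = [_make_fixed_point(y, params) for y in merged]
    for fp in points:
        if fp.residual_norm > 1e-3 * (1.0 + np.max(np.abs(fp.state.as_array()))):
            warnings.warn(
                f"fixed point residual {fp.residual_norm:g} above tolerance at {fp.state}"
            )
    return points


def stable_outcomes(points: list[FixedPoint]) -> set[Outcome]:
    return {fp.label for fp in points if fp.stability is Stability.STABLE}
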