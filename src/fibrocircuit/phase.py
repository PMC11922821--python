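"""Phase-portrait analysis: basins of attraction, separatrix, bifurcations.

The healing margin of the circuit is quantified by sampling initial
conditions on an (F, M) grid, integrating each to steady state, and
labelling the outcome.  The separatrix is the boundary of the healing basin.
Weakening the myofibroblast autocrine loop (scaling the fibroblast maximal
proliferation rate lambda1, or the autocrine production rate beta11) removes
the cold-fibrosis fixed point through a saddle-node bifurcation; the scan
locates the minimal fractional decrease at which this happens.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .circuit import (
    IntegrationError,
    Outcome,
    Stability,
    classify_state,
    default_injury_state,
    find_fixed_points,
    injury_initial_state,
    simulate_circuit,
)
from .params import CircuitParameters, perturb_parameter

__all__ = [
    "BasinMap", "BifurcationResult", "default_grid", "compute_basin_map",
    "extract_separatrix", "healing_basin_fraction", "find_autocrine_threshold",
]


@dataclasses.dataclass(frozen=True)
class BasinMap:
    """Outcome labels over an (F, M) grid of initial conditions.

    ``labels[i, j]`` is the outcome starting from (F_grid[i], M_grid[j]) with
    growth factors at quasi-steady state.
    """

    F_grid: np.ndarray
    M_grid: np.ndarray
    labels: np.ndarray  # dtype object of Outcome, shape (|F|, |M|)
    params_used: CircuitParameters
    perturbation: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.labels.shape != (len(self.F_grid), len(self.M_grid)):
            raise ValueError("labels shape does not match grids")

    def to_frame(self):
        import pandas as pd

        F, M = np.meshgrid(self.F_grid, self.M_grid, indexing="ij")
        return pd.DataFrame(
            {
                "F": F.ravel(),
                "M": M.ravel(),
                "label": [lab.value for lab in self.labels.ravel()],
            }
        )


@dataclasses.dataclass(frozen=True)
class BifurcationResult:
    """Outcome of the autocrine-weakening scan.

    ``threshold_fraction`` is the minimal fractional decrease x of the scaled
    parameter at which the acute-injury simulation heals;
    ``fixed_point_threshold`` is the minimal x at which the cold-fibrosis
    stable fixed point no longer exists.  Both are reported because the
    simulated transient can linger near a saddle-node ghost slightly past the
    bifurcation itself.
    """

    scaled_parameter: str
    threshold_fraction: float
    fixed_point_threshold: float
    resolution: float
    outcome_by_fraction: dict[float, Outcome]
    cold_exists_by_fraction: dict[float, bool]


def default_grid(params: CircuitParameters, n: int = 50) -> np.ndarray:
    """Log-spaced grid over [1e2, 1.2*K] prepended with the zero axis."""
    return np.concatenate([[0.0], np.logspace(2.0, np.log10(1.2 * params.K), n - 1)])


def _outcome_from_init(params: CircuitParameters, F0: float, M0: float,
                       horizon: float = 1000.0) -> Outcome:
    init = injury_initial_state(params, F0, M0)
    traj = simulate_circuit(params, init, horizon=horizon)
    return classify_state(traj.final_state, params)


def compute_basin_map(
    params: CircuitParameters,
    F_grid: np.ndarray | None = None,
    M_grid: np.ndarray | None = None,
    horizon: float = 1000.0,
    perturbation: tuple[str, float] | None = None,
) -> BasinMap:
    """Label every grid initial condition by the attractor it reaches.

    ``perturbation=(name, scale)`` applies :func:`perturb_parameter` first and
    records it in the result.  Integrator failures at single grid points are
    labelled ``other`` with a warning rather than aborting the map.
    """
    if perturbation is not None:
        params = perturb_parameter(params, *perturbation)
    if F_grid is None:
        F_grid = default_grid(params)
    if M_grid is None:
        M_grid = default_grid(params)
    F_grid = np.asarray(F_grid, dtype=float)
    M_grid = np.asarray(M_grid, dtype=float)
    if len(F_grid) < 8 or len(M_grid) < 8:
        raise ValueError("grids need at least 8 points per axis")
    if np.any(F_grid < 0) or np.any(M_grid < 0):
        raise ValueError("grids must be non-negative")

    labels = np.empty((len(F_grid), len(M_grid)), dtype=object)
    for i, F0 in enumerate(F_grid):
        for j, M0 in enumerate(M_grid):
            try:
                labels[i, j] = _outcome_from_init(params, F0, M0, horizon=horizon)
            except IntegrationError as err:
                warnings.warn(f"integration failed at (F={F0:g}, M={M0:g}): {err}")
                labels[i, j] = Outcome.OTHER
    return BasinMap(F_grid=F_grid, M_grid=M_grid, labels=labels,
                    params_used=params, perturbation=perturbation)


def healing_basin_fraction(basin: BasinMap) -> float:
    """Fraction of grid initial conditions that heal."""
    flat = basin.labels.ravel()
    if len(flat) == 0:
        raise ValueError("empty basin map")
    return float(np.mean([lab is Outcome.HEALING for lab in flat]))


def extract_separatrix(basin: BasinMap) -> np.ndarray:
    """Healing/non-healing boundary as an array of (F, M) points.

    Midpoints are linearly interpolated between adjacent grid points of
    differing label along both axes, then ordered by angle around their
    centroid.  Returns an empty (0, 2) array for single-label basins.
    """
    heal = np.array([[lab is Outcome.HEALING for lab in row] for row in basin.labels])
    pts: list[tuple[float, float]] = []
    for i in range(heal.shape[0] - 1):
        for j in range(heal.shape[1]):
            if heal[i, j] != heal[i + 1, j]:
                pts.append((0.5 * (basin.F_grid[i] + basin.F_grid[i + 1]), basin.M_grid[j]))
    for i in range(heal.shape[0]):
        for j in range(heal.shape[1] - 1):
            if heal[i, j] != heal[i, j + 1]:
                pts.append((basin.F_grid[i], 0.5 * (basin.M_grid[j] + basin.M_grid[j + 1])))
    if not pts:
        return np.empty((0, 2))
    arr = np.array(pts)
    centroid = arr.mean(axis=0)
    order = np.argsort(np.arctan2(arr[:, 1] - centroid[1], arr[:, 0] - centroid[0]))
    return arr[order]


def _cold_point_exists(params: CircuitParameters) -> bool:
    points = find_fixed_points(params)
    return any(
        fp.label is Outcome.COLD_FIBROSIS and fp.stability is Stability.STABLE
        for fp in points
    )


def _injury_heals(params: CircuitParameters, horizon: float = 1000.0) -> bool:
    traj = simulate_circuit(params, default_injury_state(params), horizon=horizon)
    return classify_state(traj.final_state, params) is Outcome.HEALING


def find_autocrine_threshold(
    params: CircuitParameters,
    scaled_parameter: str = "lambda1",
    resolution: float = 0.01,
    refine: bool = False,
    refine_resolution: float = 1e-3,
    horizon: float = 1000.0,
) -> BifurcationResult:
    """Scan fractional decreases of the autocrine-loop strength.

    For x = 0, resolution, 2*resolution, ... the scaled parameter is
    multiplied by (1-x); the default acute-injury simulation is run and the
    existence of the cold stable fixed point is checked.  The scan stops once
    both criteria indicate healing (outcomes are monotone in x for this
    circuit).  With ``refine=True`` the fixed-point threshold is bisected
    down to ``refine_resolution``.
    """
    if not (0.0 < resolution <= 0.25):
        raise ValueError("resolution must be in (0, 0.25]")
    outcome_by_fraction: dict[float, Outcome] = {}
    cold_by_fraction: dict[float, bool] = {}
    sim_threshold = None
    fp_threshold = None
    n_steps = int(round(1.0 / resolution))
    for k in range(n_steps + 1):
        x = k * resolution
        scale = 1.0 - x
        p = params if x == 0.0 else perturb_parameter(params, scaled_parameter, scale)
        traj = simulate_circuit(p, default_injury_state(p), horizon=horizon)
        outcome = classify_state(traj.final_state, p)
        cold = _cold_point_exists(p)
        outcome_by_fraction[round(x, 10)] = outcome
        cold_by_fraction[round(x, 10)] = cold
        if sim_threshold is None and outcome is Outcome.HEALING:
            sim_threshold = x
        if fp_threshold is None and not cold:
            fp_threshold = x
        if sim_threshold is not None and fp_threshold is not None:
            break
    if sim_threshold is None:
        sim_threshold = 1.0
    if fp_threshold is None:
        fp_threshold = 1.0
    if fp_threshold == 0.0:
        warnings.warn("cold attractor already absent at zero decrease; threshold 0")
    elif refine:
        lo, hi = fp_threshold - resolution, fp_threshold
        while hi - lo > refine_resolution:
            mid = 0.5 * (lo + hi)
            if _cold_point_exists(perturb_parameter(params, scaled_parameter, 1.0 - mid)):
                lo = mid
            else:
                hi = mid
        fp_threshold = hi
    return BifurcationResult(
        scaled_parameter=scaled_parameter,
        threshold_fraction=float(sim_threshold),
        fixed_point_threshold=float(fp_threshold),
        resolution=float(resolution),
        outcome_by_fraction=outcome_by_fraction,
        cold_exists_by_fraction=cold_by_fraction,
    )
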