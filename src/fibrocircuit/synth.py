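"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its configuration and seed and returns
the ground truth next to the data, so every quantification stage has a
recovery test.  The generators emulate the statistical structure of the real
inputs — noisy circuit trajectories after acute injury, cold (6:1
myofibroblast:macrophage) and hot (1:1) tissue maps with infarct / remote /
suture regions, bulk counts mixed from known cell-type fractions, single
cells drawn from a known archetype simplex, and ligand-activity /
cluster-abundance tables with a dominant myofibroblast autocrine block —
but not, e.g., spatial cell-cell exclusion, batch effects, or sequencing
read structure.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import CircuitState, Trajectory, simulate_circuit
from .expression import ArchetypeSet, GeneSignature
from .params import CircuitParameters
from .spatial import CELL_TYPES, CellMap

__all__ = [
    "SpatialConfig", "BulkConfig", "ArchetypeConfig", "LigandConfig",
    "gen_trajectory_observations", "gen_cell_map", "gen_bulk_counts",
    "gen_archetype_cells", "gen_ligand_tables",
]


def gen_trajectory_observations(
    params: CircuitParameters,
    init: CircuitState,
    times: Sequence[float],
    noise_cv: float = 0.1,
    seed: int = 0,
) -> Trajectory:
    """Noisy observations of a circuit trajectory at the requested times.

    Multiplicative lognormal noise with coefficient of variation ``noise_cv``
    is applied independently per variable and time, emulating measurement
    noise on cell counts and factor levels.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    times = np.asarray(times, dtype=float)
    traj = simulate_circuit(params, init, horizon=float(times[-1]), t_eval=times)
    if noise_cv == 0:
        return traj
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=traj.states.shape)
    return Trajectory(times=traj.times, states=traj.states * factors, steady=traj.steady)


@dataclasses.dataclass(frozen=True)
class SpatialConfig:
    """Homogeneous Poisson tissue-map generator settings.

    ``scenario`` fixes the myofibroblast:macrophage intensity ratio — 6 for
    cold (infarct-like), 1 for hot (pressure-overload / foreign-body-like).
    Intensities are cells/um^2; the default total interstitial intensity is
    spread over the three non-cardiomyocyte types according to the ratio.
    """

    scenario: str = "cold"
    fov_size_um: float = 1000.0
    cardiomyocyte_intensity: float = 4e-4
    macrophage_plus_myofibroblast_intensity: float = 7e-4
    other_intensity: float = 1e-4
    ratio: float | None = None  # override the scenario default
    edu_probability: float = 0.0  # P(EdU+ | myofibroblast)
    suture: bool = False
    suture_center: tuple[float, float] = (500.0, 500.0)
    suture_radius_um: float = 150.0
    suture_macrophage_boost: float = 6.0

    def type_intensities(self) -> dict[str, float]:
        ratio = self.ratio
        if ratio is None:
            if self.scenario == "cold":
                ratio = 6.0
            elif self.scenario == "hot":
                ratio = 1.0
            elif self.scenario == "healing":
                ratio = 0.1
            else:
                raise ValueError(f"unknown scenario {self.scenario!r}")
        pool = self.macrophage_plus_myofibroblast_intensity
        return {
            "cardiomyocyte": self.cardiomyocyte_intensity,
            "myofibroblast": pool * ratio / (1.0 + ratio),
            "macrophage": pool / (1.0 + ratio),
            "other": self.other_intensity,
        }


def gen_cell_map(
    config: SpatialConfig,
    seed: int = 0,
    fov_id: str = "fov0",
    animal_id: str = "animal0",
    region: str = "infarct",
) -> CellMap:
    """Sample one field of view as independent Poisson point processes per type.

    With ``config.suture`` the macrophage intensity is boosted inside a disk
    around the suture centre, emulating the foreign-body (hot) pattern.
    EdU positivity is a Bernoulli mark on myofibroblasts.
    """
    L = config.fov_size_um
    if not (L > 0):
        raise ValueError("zero FOV area")
    rng = np.random.default_rng(seed)
    rows = []
    for cell_type, lam in config.type_intensities().items():
        n = rng.poisson(lam * L * L)
        xy = rng.uniform(0.0, L, size=(n, 2))
        for x, y in xy:
            rows.append((x, y, cell_type))
        if cell_type == "macrophage" and config.suture:
            extra_lam = lam * (config.suture_macrophage_boost - 1.0)
            area = np.pi * config.suture_radius_um**2
            n_extra = rng.poisson(extra_lam * area)
            r = config.suture_radius_um * np.sqrt(rng.uniform(size=n_extra))
            ang = rng.uniform(0.0, 2 * np.pi, size=n_extra)
            cx, cy = config.suture_center
            for rr, aa in zip(r, ang):
                x, y = cx + rr * np.cos(aa), cy + rr * np.sin(aa)
                if 0 <= x <= L and 0 <= y <= L:
                    rows.append((x, y, cell_type))
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "cell_type"])
    edu = np.zeros(len(df), dtype=int)
    if config.edu_probability > 0:
        is_mf = (df["cell_type"] == "myofibroblast").to_numpy()
        edu[is_mf] = rng.binomial(1, config.edu_probability, size=is_mf.sum())
    df["EdU_positive"] = edu
    return CellMap(cells=df, fov_id=fov_id, animal_id=animal_id, region=region)


@dataclasses.dataclass(frozen=True)
class BulkConfig:
    """Bulk-mixture generator emulating the paired infarct/remote design.

    Two conditions x two timepoints x paired zones, ``n_replicates`` animals
    per group, counts drawn multinomially at ``depth`` per sample from a
    mixture of cell-type profiles with disjoint marker blocks.
    ``infarct_fold`` maps (cell_type, timepoint) to the factor by which that
    type's mixture fraction is elevated in the infarct zone relative to
    remote.  The defaults encode the cold-fibrosis time course: macrophages
    transiently elevated (FC 3 early, back to 1 late), myofibroblasts
    persistently and clearly elevated (FC 4 at both times, well inside the
    myofibroblast-dominated regime).
    """

    n_genes_per_block: int = 50
    n_replicates: int = 4
    depth: int = 1_000_000
    conditions: tuple[str, ...] = ("saline", "treated")
    timepoints: tuple[str, ...] = ("t1", "t2")
    cell_types: tuple[str, ...] = ("myofibroblast", "macrophage", "background")
    remote_fractions: tuple[float, ...] = (0.1, 0.1, 0.8)
    infarct_fold: tuple[tuple[str, str, float], ...] = (
        ("myofibroblast", "t1", 4.0), ("myofibroblast", "t2", 4.0),
        ("macrophage", "t1", 3.0), ("macrophage", "t2", 1.0),
    )


def _block_profiles(cfg: BulkConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, GeneSignature]]:
    """Cell-type expression profiles with disjoint marker blocks."""
    genes = []
    profiles = {}
    signatures = {}
    for ct in cfg.cell_types:
        block = [f"{ct}_gene{i}" for i in range(cfg.n_genes_per_block)]
        genes.extend(block)
        signatures[ct] = GeneSignature(ct, block)
    mat = pd.DataFrame(0.0, index=genes, columns=list(cfg.cell_types))
    for ct in cfg.cell_types:
        weights = rng.dirichlet(np.full(cfg.n_genes_per_block, 5.0))
        mat.loc[signatures[ct].genes, ct] = weights
    return mat, signatures


def gen_bulk_counts(config: BulkConfig, seed: int = 0):
    """Synthetic bulk count matrix with known mixing fractions.

    Returns (counts genes x samples, metadata per sample, true fraction table,
    signatures per cell type).  Infarct fractions are the remote fractions
    scaled by the configured fold changes and renormalised on the background.
    """
    rng = np.random.default_rng(seed)
    profiles, signatures = _block_profiles(config, rng)
    fold = {(ct, tp): f for ct, tp, f in config.infarct_fold}
    remote = dict(zip(config.cell_types, config.remote_fractions))
    if not np.isclose(sum(remote.values()), 1.0):
        raise ValueError("remote fractions must sum to 1")
    samples, meta_rows, frac_rows = {}, [], []
    for cond in config.conditions:
        for tp in config.timepoints:
            for zone in ("remote", "infarct"):
                fracs = dict(remote)
                if zone == "infarct":
                    for ct in config.cell_types:
                        fracs[ct] = remote[ct] * fold.get((ct, tp), 1.0)
                    # absorb the change into the background type
                    others = sum(v for k, v in fracs.items() if k != "background")
                    fracs["background"] = 1.0 - others
                    if fracs["background"] < 0:
                        raise ValueError("infarct folds leave no background fraction")
                expected = sum(
                    fracs[ct] * profiles[ct] for ct in config.cell_types
                )
                for rep in range(config.n_replicates):
                    name = f"{cond}_{tp}_{zone}_r{rep}"
                    counts = rng.multinomial(config.depth, expected.to_numpy())
                    samples[name] = counts
                    meta_rows.append({"sample": name, "condition": cond,
                                      "timepoint": tp, "zone": zone, "replicate": rep})
                frac_rows.append({"condition": cond, "timepoint": tp, "zone": zone,
                                  **fracs})
    counts = pd.DataFrame(samples, index=profiles.index)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    true_fractions = pd.DataFrame(frac_rows)
    return counts, metadata, true_fractions, signatures


@dataclasses.dataclass(frozen=True)
class ArchetypeConfig:
    """Archetype-simplex single-cell generator settings.

    ``day_shift_archetype`` concentrates the Dirichlet mass of the
    late-timepoint cells near one archetype, emulating the appearance of a
    new specialist program after injury.
    """

    n_archetypes: int = 4
    n_genes: int = 30
    n_cells_per_day: int = 200
    alpha: float = 1.0
    noise_sigma: float = 0.0
    days: tuple[str, ...] = ("day0", "day3")
    day_shift_archetype: int | None = 3   # 0-based, shifted on the last day
    day_shift_strength: float = 8.0
    archetype_scale: float = 10.0


def gen_archetype_cells(config: ArchetypeConfig, seed: int = 0):
    """Cells as convex combinations of known archetypes plus Gaussian noise.

    Returns (cell matrix n_cells x n_genes, true theta matrix, day labels,
    ArchetypeSet).  Raises if the sampled archetype positions are affinely
    dependent (retry with another seed / more genes).
    """
    if config.n_archetypes < 2:
        raise ValueError("need at least two archetypes")
    rng = np.random.default_rng(seed)
    A = rng.normal(0.0, config.archetype_scale,
                   size=(config.n_genes, config.n_archetypes))
    arch = ArchetypeSet(positions=A,
                        labels=tuple(f"archetype_{i+1}" for i in range(config.n_archetypes)))
    thetas, days = [], []
    for day in config.days:
        alpha = np.full(config.n_archetypes, config.alpha)
        if day == config.days[-1] and config.day_shift_archetype is not None:
            alpha[config.day_shift_archetype] *= config.day_shift_strength
        thetas.append(rng.dirichlet(alpha, size=config.n_cells_per_day))
        days.extend([day] * config.n_cells_per_day)
    theta = np.vstack(thetas)
    cells = theta @ A.T
    if config.noise_sigma > 0:
        cells = cells + rng.normal(0.0, config.noise_sigma, size=cells.shape)
    return cells, theta, pd.Series(days, name="day"), arch


@dataclasses.dataclass(frozen=True)
class LigandConfig:
    """Ligand-activity / cluster-abundance generator settings.

    The myofibroblast self-pair receives ``autocrine_boost`` times the base
    mean activity, and myofibroblast abundance rises by ``mf_fold`` at the
    late timepoint, so the autocrine edge dominates the interaction graph by
    construction.
    """

    cell_types: tuple[str, ...] = ("fibroblast", "macrophage", "myofibroblast")
    n_ligands_per_pair: int = 5
    base_activity: float = 0.05
    activity_sd: float = 0.01
    autocrine_boost: float = 5.0
    baseline_percents: tuple[float, ...] = (30.0, 10.0, 5.0)
    fold_changes: tuple[float, ...] = (1.0, 2.0, 8.0)
    timepoint: str = "day28"
    baseline: str = "day0"


def gen_ligand_tables(config: LigandConfig, seed: int = 0):
    """Synthetic NicheNet-style ligand-activity and abundance tables.

    Returns (activities DataFrame, abundances DataFrame).  Activities are
    truncated at zero; abundances realise the configured fold changes
    exactly.
    """
    rng = np.random.default_rng(seed)
    act_rows = []
    for s in config.cell_types:
        for r in config.cell_types:
            mean = config.base_activity
            if s == r == "myofibroblast":
                mean *= config.autocrine_boost
            for l in range(config.n_ligands_per_pair):
                rho = max(0.0, rng.normal(mean, config.activity_sd))
                act_rows.append({"sender": s, "receiver": r,
                                 "ligand": f"{s[:2]}_{r[:2]}_lig{l}",
                                 "activity": rho, "timepoint": config.timepoint})
    ab_rows = []
    for ct, pct0, fc in zip(config.cell_types, config.baseline_percents,
                            config.fold_changes):
        ab_rows.append({"cell_type": ct, "timepoint": config.baseline,
                        "percent_of_cells": pct0})
        ab_rows.append({"cell_type": ct, "timepoint": config.timepoint,
                        "percent_of_cells": pct0 * fc})
    return pd.DataFrame(act_rows), pd.DataFrame(ab_rows)
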