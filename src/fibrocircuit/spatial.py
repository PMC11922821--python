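"""Neighborhood composition of typed cell maps (double-reporter imaging).

Input is a point pattern of segmented cells (x, y in micrometres) typed as
cardiomyocyte / macrophage / myofibroblast / other, optionally carrying
binary markers such as EdU positivity.  For every cell, the composition of
the disk of radius 50 um around it (100 um diameter neighborhood) is
computed; per-cell profiles are averaged per field of view (FOV) and then
across FOVs per animal.  Group comparisons use the Mann-Whitney test with
Bonferroni correction.  Regions are called *cold* (myofibroblast-dominated,
the 6:1 regime of infarcts) or *hot* (near 1:1 myofibroblast:macrophage, the
pressure-overload / foreign-body regime) from the per-animal mean
composition.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

__all__ = [
    "CELL_TYPES", "CellMap", "NeighborhoodProfile", "neighborhood_composition",
    "aggregate", "compare_groups", "classify_fibrosis_region",
    "proliferative_fraction",
]

CELL_TYPES = ("cardiomyocyte", "macrophage", "myofibroblast", "other")
DEFAULT_RADIUS_UM = 50.0


@dataclasses.dataclass
class CellMap:
    """Typed point pattern for one field of view.

    ``cells`` columns: x_um, y_um, cell_type, optional 0/1 marker columns
    (e.g. EdU_positive), optional fov_id / animal_id / region columns.
    """

    cells: pd.DataFrame
    fov_id: str = "fov0"
    animal_id: str = "animal0"
    region: str = "unspecified"

    def __post_init__(self) -> None:
        required = {"x_um", "y_um", "cell_type"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell map missing columns: {sorted(missing)}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("non-finite cell coordinates")
        unknown = set(self.cells["cell_type"]) - set(CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types: {sorted(unknown)}; map them to 'other' first")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def coordinates(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)


@dataclasses.dataclass
class NeighborhoodProfile:
    """Per-cell disk composition: counts and percentages per cell type."""

    counts: pd.DataFrame       # one row per cell, one column per cell type
    percentages: pd.DataFrame  # same shape; rows sum to 100
    radius: float
    fov_id: str
    animal_id: str
    region: str


def _neighbor_lists(xy: np.ndarray, radius: float) -> list[np.ndarray]:
    tree = cKDTree(xy)
    return [np.asarray(idx) for idx in tree.query_ball_point(xy, r=radius)]


def neighborhood_composition(
    cell_map: CellMap,
    radius: float = DEFAULT_RADIUS_UM,
    exclude_margin: float = 0.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> NeighborhoodProfile:
    """Composition of the radius-``radius`` disk around each cell.

    The focal cell is included in its own disk, so the percentage denominator
    (total in-disk cells) is never zero.  No edge correction is applied by
    default; ``exclude_margin`` drops focal cells closer than that distance
    to the FOV border (``bounds`` = (xmin, xmax, ymin, ymax), defaulting to
    the coordinate bounding box) while still counting them as neighbors.
    """
    if not (radius > 0):
        raise ValueError("radius must be positive")
    if len(cell_map) == 0:
        raise ValueError("empty cell map")
    types = cell_map.cells["cell_type"].to_numpy()
    type_codes = np.array([CELL_TYPES.index(t) for t in types])
    xy = cell_map.coordinates
    neighbors = _neighbor_lists(xy, radius)
    counts = np.zeros((len(cell_map), len(CELL_TYPES)), dtype=int)
    for i, idx in enumerate(neighbors):
        counts[i] = np.bincount(type_codes[idx], minlength=len(CELL_TYPES))
    keep = np.ones(len(cell_map), dtype=bool)
    if exclude_margin > 0:
        if bounds is None:
            bounds = (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())
        xmin, xmax, ymin, ymax = bounds
        keep = (
            (xy[:, 0] >= xmin + exclude_margin) & (xy[:, 0] <= xmax - exclude_margin)
            & (xy[:, 1] >= ymin + exclude_margin) & (xy[:, 1] <= ymax - exclude_margin)
        )
    index = cell_map.cells.index[keep]
    counts = counts[keep]
    totals = counts.sum(axis=1, keepdims=True)
    counts_df = pd.DataFrame(counts, columns=list(CELL_TYPES), index=index)
    pct_df = pd.DataFrame(100.0 * counts / totals, columns=list(CELL_TYPES),
                          index=index)
    return NeighborhoodProfile(
        counts=counts_df, percentages=pct_df, radius=radius,
        fov_id=cell_map.fov_id, animal_id=cell_map.animal_id, region=cell_map.region,
    )


def aggregate(profiles: Iterable[NeighborhoodProfile]) -> pd.DataFrame:
    """Two-level aggregation: cells -> FOV means -> per-animal means.

    Each FOV contributes one unweighted mean regardless of its cell count,
    mirroring the average-per-FOV-then-per-animal imaging workflow.  Returns
    one row per animal with mean counts (``count_<type>``), mean percentages
    (``pct_<type>``), and the numbers of FOVs and cells behind each mean.
    """
    fov_rows = []
    for prof in profiles:
        row = {"fov_id": prof.fov_id, "animal_id": prof.animal_id,
               "region": prof.region, "n_cells": len(prof.counts)}
        for t in CELL_TYPES:
            row[f"count_{t}"] = prof.counts[t].mean()
            row[f"pct_{t}"] = prof.percentages[t].mean()
        fov_rows.append(row)
    if not fov_rows:
        raise ValueError("no profiles to aggregate")
    fov_df = pd.DataFrame(fov_rows)
    value_cols = [c for c in fov_df.columns if c.startswith(("count_", "pct_"))]
    per_animal = (
        fov_df.groupby("animal_id")
        .agg(**{c: (c, "mean") for c in value_cols},
             n_fovs=("fov_id", "nunique"), n_cells=("n_cells", "sum"))
        .reset_index()
    )
    return per_animal


def compare_groups(
    values: pd.DataFrame,
    group_col: str,
    value_col: str,
    comparisons: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Mann-Whitney tests between group pairs with Bonferroni correction.

    ``values`` has one row per animal.  The Bonferroni factor is the number
    of planned comparisons; adjusted p-values are capped at 1.  Pairs where a
    group has fewer than two observations are skipped with a warning.
    """
    rows = []
    n_comp = len(comparisons)
    for a, b in comparisons:
        xa = values.loc[values[group_col] == a, value_col].to_numpy(dtype=float)
        xb = values.loc[values[group_col] == b, value_col].to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"comparison {a} vs {b} skipped: group with < 2 observations")
            continue
        res = mannwhitneyu(xa, xb, alternative="two-sided",
                           method="exact" if max(len(xa), len(xb)) <= 20 else "asymptotic")
        rows.append({
            "group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb),
            "U": float(res.statistic), "p_raw": float(res.pvalue),
            "p_bonferroni": float(min(1.0, res.pvalue * n_comp)),
        })
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b",
                                       "U", "p_raw", "p_bonferroni"])


def classify_fibrosis_region(
    summary: pd.Series | dict,
    r_cold: float = 3.0,
    r_hot: float = 2.0,
    baseline_macrophage: float = 0.0,
    baseline_myofibroblast: float = 0.0,
) -> str:
    """Call a region cold / hot / indeterminate from mean cell composition.

    Anchored to the observed regimes: infarct cold fibrosis shows roughly 6:1
    myofibroblast:macrophage, hot fibrosis close to 1:1.  Cold requires ratio
    >= ``r_cold``; hot requires ratio <= ``r_hot`` with both types above their
    baselines; in between is indeterminate.  A zero macrophage mean with
    myofibroblasts present is treated as an infinite ratio (cold).
    """
    mf = float(summary["count_myofibroblast"] if "count_myofibroblast" in summary
               else summary["myofibroblast"])
    mp = float(summary["count_macrophage"] if "count_macrophage" in summary
               else summary["macrophage"])
    if mp == 0.0:
        if mf > 0.0:
            warnings.warn("zero macrophage mean; ratio treated as infinite")
            return "cold"
        return "indeterminate"
    ratio = mf / mp
    if ratio >= r_cold:
        return "cold"
    if ratio <= r_hot and mf > baseline_myofibroblast and mp > baseline_macrophage:
        return "hot"
    return "indeterminate"


def proliferative_fraction(
    cell_map: CellMap,
    radius: float = DEFAULT_RADIUS_UM,
    marker: str = "EdU_positive",
) -> pd.Series:
    """Percent of proliferating myofibroblasts per cellular neighborhood.

    For each focal cell, 100 x (# myofibroblast AND marker-positive cells in
    the disk) / (total cells in the disk), the per-neighborhood abundance of
    tdTomato+EdU+ cells.  Aggregate with :func:`aggregate`-style means per
    FOV/animal as needed.
    """
    if marker not in cell_map.cells.columns:
        raise ValueError(f"marker column {marker!r} not present in cell map")
    if len(cell_map) == 0:
        raise ValueError("empty cell map")
    is_target = (
        (cell_map.cells["cell_type"] == "myofibroblast")
        & (cell_map.cells[marker].astype(int) == 1)
    ).to_numpy()
    neighbors = _neighbor_lists(cell_map.coordinates, radius)
    frac = np.array([100.0 * is_target[idx].sum() / len(idx) for idx in neighbors])
    return pd.Series(frac, index=cell_map.cells.index, name="pct_proliferative_myofibroblast")
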