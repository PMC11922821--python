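"""Expression-based quantification stages.

Covers: fraction-of-total-counts normalisation of bulk RNA-seq and
signature scoring (mean over marker genes for cell-type abundance, sum for
archetype signatures); infarct-vs-remote fold changes; cluster-abundance
fold changes C_i(t) and the weighted cell-cell interaction score
W_{S->R}(t) = C_S(t) * C_R(t) * sum_l rho_l; the cell-cycle proliferation
score with the 1e3-1e4 total-count retention window; and convex archetype
decomposition of single cells with occupancy fold changes.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

__all__ = [
    "GeneSignature", "ArchetypeSet", "fraction_normalize", "signature_score",
    "zone_fold_change", "cluster_fold_change", "weighted_interaction",
    "interaction_graph", "proliferation_score", "score_correlation",
    "convex_decomposition", "archetype_occupancy_fold_change",
]


@dataclasses.dataclass(frozen=True)
class GeneSignature:
    """Named gene list (duplicates removed, order preserved)."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes: Sequence[str]):
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g)
        if not seen:
            raise ValueError(f"signature {name!r} is empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)


@dataclasses.dataclass(frozen=True)
class ArchetypeSet:
    """Archetype positions in gene-expression space, one column per archetype."""

    positions: np.ndarray  # shape (n_genes, n_archetypes)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        A = np.asarray(self.positions, dtype=float)
        if A.ndim != 2 or A.shape[1] < 2:
            raise ValueError("need a (genes x >=2 archetypes) position matrix")
        if A.shape[1] != len(self.labels):
            raise ValueError("labels/positions mismatch")
        # affine independence: differences to the last archetype have full rank
        diffs = A[:, :-1] - A[:, -1:]
        if np.linalg.matrix_rank(diffs) < A.shape[1] - 1:
            raise ValueError("archetype positions are affinely dependent")

    @property
    def n_archetypes(self) -> int:
        return self.positions.shape[1]


def fraction_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractions: each gene's share of the sample's total counts.

    ``counts`` is genes x samples.  Columns of the result sum to one; the
    normalisation is invariant to per-sample scaling of the raw counts.
    """
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {list(zero.index)}")
    return counts / totals


def signature_score(fractions: pd.DataFrame, signature: GeneSignature,
                    mode: str = "mean") -> pd.Series:
    """Score each sample by its fractional expression over signature genes.

    ``mode="mean"`` (cell-type abundance signatures) averages the gene
    fractions; ``mode="sum"`` (archetype signatures) sums them, so the score
    is the signature's share of the sample's transcriptome.  Signature genes
    absent from the matrix are dropped with a warning.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    present = [g for g in signature.genes if g in fractions.index]
    missing = len(signature) - len(present)
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} present in the matrix")
    if missing:
        warnings.warn(
            f"signature {signature.name!r}: {missing}/{len(signature)} genes absent; "
            f"scoring on the {len(present)} present"
        )
    sub = fractions.loc[present]
    score = sub.mean(axis=0) if mode == "mean" else sub.sum(axis=0)
    score.name = signature.name
    return score


def zone_fold_change(
    scores: pd.Series,
    metadata: pd.DataFrame,
    zone_col: str = "zone",
    group_cols: Sequence[str] = ("condition", "timepoint"),
    infarct: str = "infarct",
    remote: str = "remote",
) -> pd.DataFrame:
    """Infarct/remote fold change of a score per condition x timepoint.

    Scores are first averaged over replicates within each (group, zone), then
    the ratio group-mean(infarct) / group-mean(remote) is taken.  A zero
    remote mean yields NaN with a ``flagged`` marker instead of an exception.
    """
    df = metadata.copy()
    df["_score"] = scores.reindex(df.index).to_numpy()
    if df["_score"].isna().any():
        raise ValueError("scores missing for some samples in metadata")
    rows = []
    for keys, grp in df.groupby(list(group_cols)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        zone_means = grp.groupby(zone_col)["_score"].mean()
        if infarct not in zone_means.index or remote not in zone_means.index:
            raise ValueError(f"group {keys} lacks one of the zones {infarct!r}/{remote!r}")
        rem = zone_means[remote]
        flagged = rem == 0.0
        fc = np.nan if flagged else zone_means[infarct] / rem
        row = dict(zip(group_cols, keys))
        row.update(infarct_mean=zone_means[infarct], remote_mean=rem,
                   fold_change=fc, flagged=flagged)
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_fold_change(percent_t: float, percent_t0: float) -> float:
    """Cluster-size fold change C_i(t) = %cells(t) / %cells(0)."""
    if percent_t < 0 or percent_t0 < 0:
        raise ValueError("percentages must be non-negative")
    if percent_t0 == 0:
        raise ValueError("zero baseline cluster percentage")
    return percent_t / percent_t0


def weighted_interaction(C_S: float, C_R: float, activities: Sequence[float]) -> float:
    """Weighted interaction W = C_S * C_R * sum of ligand activities rho_l."""
    acts = np.asarray(list(activities), dtype=float)
    if acts.size == 0:
        raise ValueError("activities must be non-empty")
    return float(C_S * C_R * acts.sum())


def interaction_graph(
    abundances: pd.DataFrame,
    activities: pd.DataFrame,
    timepoint,
    baseline,
) -> nx.DiGraph:
    """Weighted directed cell-communication graph at one timepoint.

    ``abundances`` columns: cell_type, timepoint, percent_of_cells;
    ``activities`` columns: sender, receiver, ligand, activity, timepoint.
    Node weight is C_i(t) relative to ``baseline``; edge weight is
    W_{S->R}(t).  Self-edges (autocrine signalling) are permitted.
    """
    ab_t = abundances[abundances["timepoint"] == timepoint].set_index("cell_type")
    ab_0 = abundances[abundances["timepoint"] == baseline].set_index("cell_type")
    act_t = activities[activities["timepoint"] == timepoint]

    def C(cell_type: str) -> float:
        for tab, when in ((ab_t, timepoint), (ab_0, baseline)):
            if cell_type not in tab.index:
                raise KeyError(f"no abundance for cell type {cell_type!r} at {when!r}")
        return cluster_fold_change(ab_t.loc[cell_type, "percent_of_cells"],
                                   ab_0.loc[cell_type, "percent_of_cells"])

    G = nx.DiGraph(timepoint=timepoint, baseline=baseline)
    for ct in ab_t.index:
        G.add_node(ct, fold_change=C(ct))
    for (s, r), grp in act_t.groupby(["sender", "receiver"]):
        rho_sum = float(grp["activity"].sum())
        G.add_edge(s, r, weight=weighted_interaction(C(s), C(r), [rho_sum]),
                   rho_sum=rho_sum, n_ligands=len(grp))
    return G


def proliferation_score(
    counts: pd.DataFrame,
    cell_cycle: GeneSignature,
    total_bounds: tuple[float, float] = (1e3, 1e4),
) -> tuple[pd.Series, pd.Series]:
    """Cell-cycle count fraction per cell with a total-count retention window.

    ``counts`` is genes x cells.  Cells are retained iff their total count
    lies in ``total_bounds`` (inclusive); the score is the retained cell's
    cell-cycle counts divided by its total counts.  Returns (scores over
    retained cells, boolean retention mask over all cells).
    """
    lo, hi = total_bounds
    totals = counts.sum(axis=0)
    retained = (totals >= lo) & (totals <= hi)
    if not retained.any():
        warnings.warn("no cell retained by the total-count window")
    present = [g for g in cell_cycle.genes if g in counts.index]
    if not present:
        raise ValueError("no cell-cycle gene present in the matrix")
    cc = counts.loc[present].sum(axis=0)
    scores = (cc[retained] / totals[retained]).astype(float)
    scores.name = "proliferation_score"
    retained.name = "retained"
    return scores, retained


def score_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation and two-sided p across timepoint means.

    Used to relate the mean myofibroblast proliferation score to the mean
    expression of a candidate autocrine factor (e.g. Timp1) over timepoints.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired timepoints")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = pearsonr(x, y)
    return float(r), float(p)


#: Weight of the sum-to-one constraint row in the augmented NNLS system,
#: relative to the data scale.  Large enough that the constraint violation is
#: far below the 1e-8 simplex tolerance before renormalisation.
_SIMPLEX_PENALTY = 1e6


def convex_decomposition(cell: np.ndarray, archetypes: ArchetypeSet) -> np.ndarray:
    """Best convex combination of archetypes for one expression vector.

    Solves min ||G_c - sum_i theta_i G_i*||^2 subject to theta >= 0 and
    sum theta = 1, by active-set non-negative least squares on the system
    augmented with a heavily weighted sum-to-one row, followed by exact
    renormalisation onto the simplex.  Exact (to solver tolerance) for any
    point inside the archetype simplex.
    """
    g = np.asarray(cell, dtype=float)
    A = archetypes.positions
    if g.shape != (A.shape[0],):
        raise ValueError(f"cell vector has dimension {g.shape}, archetypes {A.shape[0]}")
    scale = max(np.abs(A).max(), np.abs(g).max(), 1.0)
    w = _SIMPLEX_PENALTY * scale
    A_aug = np.vstack([A, w * np.ones((1, A.shape[1]))])
    b_aug = np.concatenate([g, [w]])
    theta, _ = nnls(A_aug, b_aug)
    s = theta.sum()
    if s == 0.0:  # pathological; fall back to uniform weights
        return np.full(A.shape[1], 1.0 / A.shape[1])
    return theta / s


def closest_archetype(theta: np.ndarray) -> int:
    """Index of the dominant archetype; ties broken by lowest index."""
    return int(np.argmax(theta))


def decompose_cells(cells: np.ndarray, archetypes: ArchetypeSet) -> pd.DataFrame:
    """Convex weights and closest-archetype assignment for a cell matrix.

    ``cells`` is (n_cells x n_genes).  Returns one row per cell with theta
    columns (named by archetype label) and a ``closest`` column.
    """
    cells = np.atleast_2d(np.asarray(cells, dtype=float))
    thetas = np.array([convex_decomposition(c, archetypes) for c in cells])
    df = pd.DataFrame(thetas, columns=[f"theta_{lab}" for lab in archetypes.labels])
    df["closest"] = [archetypes.labels[closest_archetype(t)] for t in thetas]
    return df


def archetype_occupancy_fold_change(
    assignments: pd.Series,
    day_labels: pd.Series,
    day, baseline,
    archetype_labels: Sequence[str],
) -> pd.DataFrame:
    """Per-archetype fold change of closest-cell proportions between days.

    FC_i = proportion(day, closest=i) / proportion(baseline, closest=i); a
    zero baseline proportion gives infinite FC with a flag.
    """
    sel_day = assignments[day_labels == day]
    sel_base = assignments[day_labels == baseline]
    if len(sel_day) == 0 or len(sel_base) == 0:
        raise ValueError("both day groups must be non-empty")
    rows = []
    for lab in archetype_labels:
        p_day = (sel_day == lab).mean()
        p_base = (sel_base == lab).mean()
        flagged = p_base == 0.0
        fc = np.inf if flagged and p_day > 0 else (np.nan if flagged else p_day / p_base)
        rows.append({"archetype": lab, "proportion_day": p_day,
                     "proportion_baseline": p_base, "fold_change": fc,
                     "flagged": flagged})
    return pd.DataFrame(rows)
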