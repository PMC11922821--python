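"""Readers and writers for the CSV / MatrixMarket dialects of the pipeline."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .spatial import CELL_TYPES, CellMap

logger = logging.getLogger("fibrocircuit")

__all__ = ["read_cell_map", "write_cell_map", "read_expression",
           "write_expression_csv", "write_expression_mtx", "read_signature"]


def read_cell_map(path: str | Path) -> list[CellMap]:
    """Read a cell-map CSV/TSV into one CellMap per (animal, FOV).

    Required columns: x_um, y_um, cell_type.  Optional: marker columns (0/1),
    fov_id, animal_id, region.  Unknown cell-type values are mapped to
    ``other`` with a logged count.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("x_um", "y_um", "cell_type"):
        if col not in df.columns:
            raise ValueError(f"cell map file {path} is missing required column {col!r}")
    unknown = ~df["cell_type"].isin(CELL_TYPES)
    if unknown.any():
        logger.warning("%d cells with unknown cell_type mapped to 'other'", unknown.sum())
        df.loc[unknown, "cell_type"] = "other"
    for col, default in (("fov_id", "fov0"), ("animal_id", "animal0"),
                         ("region", "unspecified")):
        if col not in df.columns:
            df[col] = default
    maps = []
    for (animal, fov), grp in df.groupby(["animal_id", "fov_id"], sort=True):
        region = str(grp["region"].iloc[0])
        maps.append(CellMap(cells=grp.reset_index(drop=True), fov_id=str(fov),
                            animal_id=str(animal), region=region))
    return maps


def write_cell_map(maps: list[CellMap] | CellMap, path: str | Path) -> None:
    if isinstance(maps, CellMap):
        maps = [maps]
    frames = []
    for m in maps:
        df = m.cells.copy()
        df["fov_id"] = m.fov_id
        df["animal_id"] = m.animal_id
        df["region"] = m.region
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _validate_expression(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers in {origin}: {dupes}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative counts in {origin}")
    return df


def read_expression(path: str | Path, genes: str | Path | None = None,
                    samples: str | Path | None = None) -> pd.DataFrame:
    """Read a genes x samples count matrix from CSV or MTX + index files.

    CSV: first column holds gene identifiers, header holds sample names.
    MTX: ``genes`` and ``samples`` are one-identifier-per-line text files
    matching the matrix dimensions.  Both routes yield the same DataFrame
    for equivalent content.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        if genes is None or samples is None:
            raise ValueError("MTX input requires genes and samples index files")
        raw = mmread(path)
        mat = np.asarray(raw.toarray() if hasattr(raw, "toarray") else raw)
        gene_ids = Path(genes).read_text().split()
        sample_ids = Path(samples).read_text().split()
        if mat.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match index files "
                f"({len(gene_ids)} genes, {len(sample_ids)} samples)"
            )
        df = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    else:
        df = pd.read_csv(path, index_col=0)
    return _validate_expression(df, str(path))


def write_expression_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path)


def write_expression_mtx(df: pd.DataFrame, mtx_path: str | Path,
                         genes_path: str | Path, samples_path: str | Path) -> None:
    mmwrite(str(mtx_path), csr_matrix(df.to_numpy()))
    Path(genes_path).write_text("\n".join(map(str, df.index)) + "\n")
    Path(samples_path).write_text("\n".join(map(str, df.columns)) + "\n")


def read_signature(path: str | Path, name: str | None = None):
    """Read a one-gene-per-line signature file."""
    from .expression import GeneSignature

    path = Path(path)
    genes = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return GeneSignature(name or path.stem, genes)
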