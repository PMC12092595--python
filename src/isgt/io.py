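"""Readers and writers for the on-disk formats the pipeline consumes.

Count matrices come in two renderings: a Matrix Market triplet
(``matrix.mtx`` with genes x cells orientation plus ``genes.tsv`` and
``barcodes.tsv``, the layout sequencing pipelines emit) or a dense CSV
(rows = cells, header = gene ids, first column = cell_id).  Cell tables
and spatial maps are plain CSV; gene sets are GMT or newline-delimited
symbol lists.  Every writer/reader pair round-trips bitwise on counts
and field-wise on metadata.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .datatypes import (
    CountMatrix,
    GeneSet,
    RunConfig,
    validate_cell_table,
    validate_spatial_map,
)

logger = logging.getLogger("isgt")


# ---------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a raw count matrix from MTX-triplet or dense-CSV layout.

    ``path`` may be a directory containing ``matrix.mtx``, ``genes.tsv``
    and ``barcodes.tsv``; the ``matrix.mtx`` file itself (siblings are
    looked up next to it); or a dense ``.csv``.  Row/column order is
    preserved from the input and the result carries ``layer='raw'``.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_triplet(path / "matrix.mtx")
    if path.suffix == ".mtx":
        return _read_mtx_triplet(path)
    if path.suffix == ".csv":
        return _read_dense_csv(path)
    raise ValueError(f"unrecognized count-matrix path {path}; expected .mtx, .csv or directory")


def _read_mtx_triplet(mtx_path: Path) -> CountMatrix:
    genes_path = mtx_path.with_name("genes.tsv")
    barcodes_path = mtx_path.with_name("barcodes.tsv")
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    # genes x cells on disk, transpose to cells x genes in memory
    m = scipy.io.mmread(str(mtx_path)).T.tocsr()
    gene_ids = genes_path.read_text().splitlines()
    gene_ids = [line.split("\t")[0] for line in gene_ids if line]
    cell_ids = [line for line in barcodes_path.read_text().splitlines() if line]
    return CountMatrix(cell_ids, gene_ids, m, layer="raw")


def _read_dense_csv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, index_col=0)
    counts = df.to_numpy()
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), counts, layer="raw")


def write_count_matrix(m: CountMatrix, path: str | Path, fmt: str = "mtx") -> None:
    """Write a count matrix as an MTX triplet directory or a dense CSV."""
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        mat = m.counts if sp.issparse(m.counts) else sp.csr_matrix(m.counts)
        scipy.io.mmwrite(str(path / "matrix.mtx"), mat.T.tocoo())
        (path / "genes.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    elif fmt == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids)
        df.index.name = "cell_id"
        df.to_csv(path)
    else:
        raise ValueError(f"unknown count-matrix format {fmt!r}")


# ---------------------------------------------------------------------
# cell tables and spatial maps
# ---------------------------------------------------------------------

def read_cell_table(
    path: str | Path,
    lineage_map: Mapping[str, str] | None = None,
    t_cell_types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a per-cell annotation CSV and assign lineage classes.

    Lineage is filled from the user-supplied ``lineage_map``
    (cell_type -> lineage); unmapped types get ``other`` with one logged
    warning per distinct type — lineage is never inferred silently.
    ``is_T`` is set from ``t_cell_types`` when given, otherwise taken
    from an ``is_T`` column if present, otherwise False.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
    missing = [c for c in ("cell_id", "sample_id") if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} missing required columns: {missing}")
    if "condition" not in df.columns:
        df["condition"] = "unknown"
    if "cell_type" not in df.columns:
        df["cell_type"] = "unknown"
    df = assign_lineage(df, lineage_map or {})
    if t_cell_types is not None:
        df["is_T"] = df["cell_type"].isin(set(t_cell_types))
    elif "is_T" in df.columns:
        df["is_T"] = df["is_T"].astype(bool)
    else:
        df["is_T"] = False
    return validate_cell_table(df)


def assign_lineage(cells: pd.DataFrame, lineage_map: Mapping[str, str]) -> pd.DataFrame:
    """Fill the lineage column from an explicit cell_type -> lineage map."""
    cells = cells.copy()
    unmapped = sorted(set(cells["cell_type"].unique()) - set(lineage_map))
    for t in unmapped:
        logger.warning("cell type %r has no lineage mapping; assigned 'other'", t)
    cells["lineage"] = cells["cell_type"].map(lineage_map).fillna("other")
    return cells


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    validate_cell_table(cells).to_csv(path, index=False)


def read_spatial_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
    return validate_spatial_map(df)


def write_spatial_map(smap: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    validate_spatial_map(smap).to_csv(path, index=False)


# ---------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (one set per line) or a newline symbol list.

    Order of sets and of genes is preserved.  Duplicates within a set
    are dropped with a warning; a set that is empty after deduplication
    is an error.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"gene-set file {path} is empty")
    if path.suffix.lower() == ".gmt":
        sets = []
        for line in text.splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            name, genes = fields[0], [g for g in fields[2:] if g]
            sets.append(_dedup_gene_set(name, genes))
        if not sets:
            raise ValueError(f"no gene sets found in {path}")
        return sets
    genes = [line.strip() for line in text.splitlines() if line.strip()]
    return [_dedup_gene_set(path.stem, genes)]


def _dedup_gene_set(name: str, genes: list[str]) -> GeneSet:
    seen: dict[str, None] = {}
    dropped = 0
    for g in genes:
        if g in seen:
            dropped += 1
        else:
            seen[g] = None
    if dropped:
        logger.warning("gene set %r: dropped %d duplicate symbol(s)", name, dropped)
    if not seen:
        raise ValueError(f"gene set {name!r} is empty after deduplication")
    return GeneSet(name, list(seen))


def write_gene_sets(sets: Sequence[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML or JSON (YAML is a JSON superset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return RunConfig.from_dict(data)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
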