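"""Core in-memory containers shared by every pipeline stage.

The pipeline moves three kinds of data around: a cells x genes count
matrix (raw integer counts at ingest, real-valued after normalization),
a per-cell annotation table (sample, condition, cell type, lineage
class, T-cell flag) and a per-cell spatial map in micrometers.  The
annotation table and spatial map are plain :class:`pandas.DataFrame`
objects with a required column contract; the count matrix gets a small
dedicated container because it carries an extra piece of state (the
layer tag) that determines which operations are legal on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: legal layer tags for a CountMatrix, in pipeline order
LAYERS = ("raw", "normalized", "lognorm")

#: legal lineage classes for cells
LINEAGES = ("lymphocyte", "non_lymphocyte", "other")

#: required columns of a cell annotation table
CELL_TABLE_COLUMNS = ("cell_id", "sample_id", "condition", "cell_type", "lineage", "is_T")

#: required columns of a spatial map
SPATIAL_COLUMNS = ("cell_id", "x_um", "y_um", "sample_id")


class CountMatrixError(ValueError):
    """Raised on invalid count-matrix construction or layer misuse."""


@dataclass
class CountMatrix:
    """Cells x genes matrix with identifier lists and a layer tag.

    Parameters
    ----------
    cell_ids, gene_ids
        Unique string identifiers for rows (cells) and columns (genes).
    counts
        ``(n_cells, n_genes)`` array or sparse matrix, all entries >= 0.
        Integer-valued on the ``raw`` layer, real-valued after
        normalization.
    layer
        One of ``raw``, ``normalized``, ``lognorm``.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray | sp.spmatrix
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise CountMatrixError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountMatrixError("duplicate gene identifiers")
        if self.layer not in LAYERS:
            raise CountMatrixError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
        else:
            self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise CountMatrixError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.layer == "raw" and self.min() < 0:
            raise CountMatrixError("negative entries in raw count matrix")

    # -- basic queries -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def min(self) -> float:
        if sp.issparse(self.counts):
            return float(self.counts.min()) if self.counts.nnz else 0.0
        return float(self.counts.min()) if self.counts.size else 0.0

    def total(self) -> float:
        return float(self.counts.sum())

    def dense(self) -> np.ndarray:
        """Counts as a dense float array (copy when sparse)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with a nonzero entry, per cell."""
        if sp.issparse(self.counts):
            return np.asarray((self.counts > 0).sum(axis=1)).ravel()
        return (self.counts > 0).sum(axis=1)

    def cells_per_gene(self) -> np.ndarray:
        """Number of cells with a nonzero entry, per gene."""
        if sp.issparse(self.counts):
            return np.asarray((self.counts > 0).sum(axis=0)).ravel()
        return (self.counts > 0).sum(axis=0)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    # -- subsetting ----------------------------------------------------
    def subset(
        self,
        cell_mask: np.ndarray | None = None,
        gene_mask: np.ndarray | None = None,
    ) -> "CountMatrix":
        """Return a new matrix restricted to masked cells/genes (order kept)."""
        counts = self.counts
        cell_ids = self.cell_ids
        gene_ids = self.gene_ids
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask, dtype=bool)
            counts = counts[cell_mask]
            cell_ids = [c for c, keep in zip(cell_ids, cell_mask) if keep]
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask, dtype=bool)
            counts = counts[:, gene_mask]
            gene_ids = [g for g, keep in zip(gene_ids, gene_mask) if keep]
        return CountMatrix(cell_ids, gene_ids, counts, layer=self.layer)

    def require_layer(self, layer: str, op: str) -> None:
        if self.layer != layer:
            raise CountMatrixError(
                f"{op} requires a {layer!r} matrix, got layer {self.layer!r}"
            )


@dataclass
class GeneSet:
    """A named, duplicate-free, nonempty list of gene symbols."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def present_in(self, gene_ids: Iterable[str], case_insensitive: bool = False) -> list[str]:
        """Subset of this set found among ``gene_ids`` (set order kept).

        With ``case_insensitive`` the match falls back to
        case-insensitive comparison and returns the matrix's spelling,
        which absorbs human/mouse symbol casing (ISG15 vs Isg15).
        """
        ids = list(gene_ids)
        if case_insensitive:
            lookup = {g.upper(): g for g in ids}
            return [lookup[g.upper()] for g in self.genes if g.upper() in lookup]
        idset = set(ids)
        return [g for g in self.genes if g in idset]


#: type I interferon-stimulated genes named in the main text; users
#: supply fuller panels for real analyses
DEFAULT_ISG_SET = GeneSet("ISG", ["ISG15", "ISG20", "IFIT1", "IRF7"])

#: cytotoxicity anchor gene (granzyme B)
DEFAULT_CYTOTOXICITY_SET = GeneSet("cytotoxicity", ["GZMB"])


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-table column contract and uniqueness invariants."""
    missing = [c for c in ("cell_id", "sample_id") if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing required columns: {missing}")
    if cells["cell_id"].duplicated().any():
        dups = cells.loc[cells["cell_id"].duplicated(), "cell_id"].head(3).tolist()
        raise ValueError(f"duplicated cell_id values, e.g. {dups}")
    if "lineage" in cells.columns:
        bad = set(cells["lineage"].unique()) - set(LINEAGES)
        if bad:
            raise ValueError(f"unknown lineage classes {sorted(bad)}; allowed: {LINEAGES}")
    return cells


def validate_spatial_map(smap: pd.DataFrame) -> pd.DataFrame:
    """Check the spatial-map contract: columns, finiteness, one row per cell."""
    missing = [c for c in SPATIAL_COLUMNS if c not in smap.columns]
    if missing:
        raise ValueError(f"spatial map missing required columns: {missing}")
    if smap["cell_id"].duplicated().any():
        raise ValueError("spatial map has multiple records for the same cell")
    xy = smap[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates in spatial map")
    return smap


@dataclass
class RunConfig:
    """Serializable bundle of every tunable the pipeline exposes.

    A run is reproducible from (inputs, RunConfig): all randomness is
    seeded from ``seed`` and every stage reads its parameters from here.
    """

    seed: int = 0
    # QC thresholds (sequencing-based spatial dialect)
    min_genes_per_cell: int = 100
    min_cells_per_gene: int = 3
    min_counts_per_cell: int = 2000
    max_counts_per_cell: int = 35000
    # normalization dialect: visium | xenium | custom
    dialect: str = "visium"
    target_sum: float = 10000.0
    log_base: str = "2"
    pseudocount: float = 1.0
    # module scoring
    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    # ISG-T calling rule, e.g. "sd:3", "quantile:0.99", "abs:0.5"
    isgt_rule: str = "sd:3"
    # classifier
    cv_folds: int = 5
    strength_grid: list[float] = field(
        default_factory=lambda: list(np.logspace(-4, 4, 10))
    )
    # proximity
    focal_type: str = "ISG-T"
    pooling: str = "pooled_cells"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["strength_grid"] = [float(x) for x in d["strength_grid"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)
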