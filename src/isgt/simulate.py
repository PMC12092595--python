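"""Synthetic expression matrices and tissue maps with known ground truth.

Two independent generators emulate the statistical structure the
downstream analysis assumes:

* :func:`simulate_expression` draws negative-binomial counts for a
  mixed cell population in which a minority of T cells carries an
  upregulated interferon-stimulated-gene (ISG) program — the situation
  in which a module score must separate program-positive from
  program-negative cells.
* :func:`simulate_tissue` places cells on a planar tissue domain as a
  Thomas-like clustered point process: parent cells (plasmacytoid
  dendritic cells, pDC) are uniform, offspring cells (ISG-T) scatter
  around a uniformly chosen parent with isotropic Gaussian displacement
  of scale ``attraction_sigma_um``, and every other type is uniform.
  This is the ground-truth model for the nearest-neighbor proximity
  statistic: smaller sigma means tighter ISG-T/pDC attraction.

Expression and tissue use distinct seed streams so that fixing one
simulation does not perturb the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneSet

# stream tags mixed into the seed so the two generators never share a stream
_EXPR_STREAM = 0x45585052
_TISSUE_STREAM = 0x54495353

#: default cell-type mix of the expression simulator
DEFAULT_PROPORTIONS = {"T": 0.4, "B": 0.2, "Myeloid": 0.25, "NK": 0.15}

#: default per-type counts of a 4 mm^2 tissue sample
DEFAULT_TISSUE_COUNTS = {
    "ISG-T": 100,
    "pDC": 50,
    "Tn": 300,
    "B": 200,
    "PT": 500,
    "EC": 300,
    "FIB": 200,
    "MAC": 150,
}

#: lineage classes of the default tissue types
DEFAULT_TISSUE_LINEAGE = {
    "ISG-T": "lymphocyte",
    "Tn": "lymphocyte",
    "B": "lymphocyte",
    "pDC": "non_lymphocyte",
    "PT": "non_lymphocyte",
    "EC": "non_lymphocyte",
    "FIB": "non_lymphocyte",
    "MAC": "non_lymphocyte",
}

#: T-cell types of the default tissue mix
DEFAULT_TISSUE_T_TYPES = ("ISG-T", "Tn")


@dataclass
class ExpressionSimSpec:
    """Parameters of the negative-binomial expression simulator.

    ``baseline_mean`` may be given explicitly (one positive real per
    gene); when None, per-gene baseline means are drawn log-normally
    with log-mean ``baseline_log_mean`` and log-sd ``baseline_log_sd``
    (defaults centered near 0.5 counts/gene, a typical droplet-depth
    scale).  Counts follow NB(mean, dispersion) with
    ``variance = mu + mu^2 / dispersion``; the ISG program multiplies
    the mean of each program gene by ``2**program_log2fc`` in
    program-positive cells, which are a ``program_fraction`` subset of
    T cells.  Per-cell library factors are log-normal with coefficient
    of variation ``library_size_cv`` and unit mean.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    cell_type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    baseline_mean: np.ndarray | None = None
    baseline_log_mean: float = np.log(0.5)
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 2.0
    program_genes: GeneSet | None = None
    program_log2fc: float = 1.0
    program_fraction: float = 0.05
    library_size_cv: float = 0.3
    t_cell_types: Sequence[str] = ("T",)
    type_markers: Mapping[str, Sequence[str]] | None = None
    type_marker_log2fc: float = 2.0
    sample_id: str = "sample_0"
    condition: str = "simulated"
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.cell_type_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell_type_proportions sum to {total}, expected 1")
        if not 0.0 <= self.program_fraction <= 1.0:
            raise ValueError("program_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be nonnegative")


@dataclass
class TissueSimSpec:
    """Parameters of the Thomas-like tissue simulator.

    ``attraction_sigma_um`` is the Gaussian displacement scale of
    offspring around parents; ``numpy.inf`` places offspring uniformly
    (no attraction).  Offspring displaced outside the domain are
    reflected at the boundary so per-type counts are exact.
    """

    domain: tuple[float, float] = (2000.0, 2000.0)
    counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_TISSUE_COUNTS))
    parent_type: str = "pDC"
    offspring_type: str = "ISG-T"
    attraction_sigma_um: float = 30.0
    sample_id: str = "sample_0"
    condition: str = "simulated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain[0] <= 0 or self.domain[1] <= 0:
            raise ValueError("domain sides must be positive")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("per-type counts must be nonnegative")
        if self.attraction_sigma_um <= 0 and not np.isinf(self.attraction_sigma_um):
            # sigma == 0 is allowed as the degenerate limit; negative is not
            if self.attraction_sigma_um < 0:
                raise ValueError("attraction_sigma_um must be >= 0 or inf")


def _program_gene_ids(n_genes: int, program: GeneSet | None,
                      markers: Mapping[str, Sequence[str]] | None) -> list[str]:
    """Gene identifiers with named program/marker genes placed first."""
    named: dict[str, None] = {}
    if program is not None:
        for g in program.genes:
            named[g] = None
    if markers:
        for genes in markers.values():
            for g in genes:
                named[g] = None
    if len(named) > n_genes:
        raise ValueError(
            f"{len(named)} named program/marker genes exceed n_genes={n_genes}"
        )
    filler: list[str] = []
    i = 0
    while len(filler) < n_genes - len(named):
        gid = f"gene_{i:05d}"
        if gid not in named:
            filler.append(gid)
        i += 1
    return list(named) + filler


def simulate_expression(spec: ExpressionSimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a raw count matrix plus a cell table with truth labels.

    Returns
    -------
    (CountMatrix, DataFrame)
        Raw counts and a cell table with the usual annotation columns
        plus ``truth_is_program_positive``.
    """
    rng = np.random.default_rng([spec.seed, _EXPR_STREAM])
    gene_ids = _program_gene_ids(spec.n_genes, spec.program_genes, spec.type_markers)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    # cell types: deterministic proportional allocation, order shuffled
    types = sorted(spec.cell_type_proportions)
    n_by_type = {t: int(round(spec.cell_type_proportions[t] * spec.n_cells)) for t in types}
    drift = spec.n_cells - sum(n_by_type.values())
    n_by_type[types[0]] += drift
    cell_type = np.repeat(types, [n_by_type[t] for t in types])
    rng.shuffle(cell_type)

    is_t = np.isin(cell_type, list(spec.t_cell_types))
    if spec.program_fraction > 0 and spec.program_genes is not None and not is_t.any():
        raise ValueError("program_fraction > 0 but the simulated population has no T cells")

    # truth program labels among T cells
    truth = np.zeros(spec.n_cells, dtype=bool)
    if spec.program_genes is not None and spec.program_fraction > 0:
        t_idx = np.flatnonzero(is_t)
        n_pos = int(round(spec.program_fraction * t_idx.size))
        truth[rng.choice(t_idx, size=n_pos, replace=False)] = True

    if spec.baseline_mean is not None:
        base = np.asarray(spec.baseline_mean, dtype=float)
        if base.shape != (spec.n_genes,):
            raise ValueError("baseline_mean must have one entry per gene")
        if (base <= 0).any():
            raise ValueError("baseline_mean entries must be positive")
    else:
        base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)

    # per-cell x per-gene mean: baseline x library factor x program fold changes
    if spec.library_size_cv > 0:
        sigma2 = np.log1p(spec.library_size_cv ** 2)
        lib = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), spec.n_cells)
    else:
        lib = np.ones(spec.n_cells)

    mu = np.outer(lib, base)
    if spec.program_genes is not None and spec.program_log2fc != 0:
        cols = [gene_pos[g] for g in spec.program_genes.genes]
        mu[np.ix_(truth, cols)] *= 2.0 ** spec.program_log2fc
    if spec.type_markers:
        for t, genes in spec.type_markers.items():
            rows = cell_type == t
            cols = [gene_pos[g] for g in genes]
            mu[np.ix_(rows, cols)] *= 2.0 ** spec.type_marker_log2fc

    # NB via gamma-Poisson mixture: var = mu + mu^2/theta
    theta = spec.nb_dispersion
    lam = rng.gamma(theta, mu / theta)
    counts = rng.poisson(lam)

    cell_ids = [f"{spec.sample_id}_c{i:05d}" for i in range(spec.n_cells)]
    m = CountMatrix(cell_ids, gene_ids, counts, layer="raw")
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": spec.sample_id,
            "condition": spec.condition,
            "cell_type": cell_type,
            "lineage": "other",
            "is_T": is_t,
            "truth_is_program_positive": truth,
        }
    )
    return m, cells


def _reflect(x: np.ndarray, hi: float) -> np.ndarray:
    """Fold coordinates into [0, hi] by reflection at both boundaries."""
    period = 2.0 * hi
    x = np.mod(x, period)
    return np.where(x > hi, period - x, x)


def simulate_tissue(
    spec: TissueSimSpec,
    lineage_map: Mapping[str, str] | None = None,
    t_cell_types: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one tissue sample; returns (spatial map, cell table).

    Parent cells are uniform on the domain; each offspring cell picks a
    parent uniformly and is displaced by an isotropic Gaussian of scale
    ``attraction_sigma_um``, reflected at the domain boundary.  All
    other types are uniform.  ``lineage_map`` and ``t_cell_types``
    default to the built-in mappings for the default type mix.
    """
    rng = np.random.default_rng([spec.seed, _TISSUE_STREAM])
    w, h = spec.domain
    if lineage_map is None:
        lineage_map = DEFAULT_TISSUE_LINEAGE
    if t_cell_types is None:
        t_cell_types = DEFAULT_TISSUE_T_TYPES

    n_off = spec.counts.get(spec.offspring_type, 0)
    n_par = spec.counts.get(spec.parent_type, 0)
    if np.isfinite(spec.attraction_sigma_um) and n_off > 0 and n_par == 0:
        raise ValueError(
            f"finite attraction_sigma_um requires >= 1 {spec.parent_type!r} parent cell"
        )

    rows_xy: list[np.ndarray] = []
    rows_type: list[str] = []
    # stable type order for determinism; parents drawn before offspring
    order = sorted(spec.counts, key=lambda t: (t != spec.parent_type, t))
    parents: np.ndarray | None = None
    for t in order:
        n = spec.counts[t]
        if n == 0:
            continue
        if t == spec.offspring_type and np.isfinite(spec.attraction_sigma_um):
            assert parents is not None
            choice = rng.integers(0, parents.shape[0], size=n)
            disp = rng.normal(0.0, spec.attraction_sigma_um, size=(n, 2))
            xy = parents[choice] + disp
            xy[:, 0] = _reflect(xy[:, 0], w)
            xy[:, 1] = _reflect(xy[:, 1], h)
        else:
            xy = rng.uniform(0.0, [w, h], size=(n, 2))
        if t == spec.parent_type:
            parents = xy
        rows_xy.append(xy)
        rows_type.extend([t] * n)

    xy = np.vstack(rows_xy) if rows_xy else np.empty((0, 2))
    cell_ids = [f"{spec.sample_id}_c{i:05d}" for i in range(len(rows_type))]
    smap = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "sample_id": spec.sample_id,
        }
    )
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": spec.sample_id,
            "condition": spec.condition,
            "cell_type": rows_type,
        }
    )
    cells["lineage"] = cells["cell_type"].map(dict(lineage_map)).fillna("other")
    cells["is_T"] = cells["cell_type"].isin(set(t_cell_types))
    return smap, cells


def simulate_cohort(
    condition_specs: Mapping[str, TissueSimSpec],
    n_samples_per_condition: int,
    base_seed: int,
    lineage_map: Mapping[str, str] | None = None,
    t_cell_types: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-sample, multi-condition cohort of tissue maps.

    Sample ``j`` of condition ``c`` reuses that condition's spec with
    seed ``base_seed + global sample index`` and sample id
    ``"{c}_s{j}"``, so the whole cohort is reproducible from one seed.
    """
    if not condition_specs:
        raise ValueError("at least one condition is required")
    if n_samples_per_condition < 1:
        raise ValueError("n_samples_per_condition must be >= 1")
    maps, tables = [], []
    idx = 0
    for cond in condition_specs:
        spec = condition_specs[cond]
        for j in range(n_samples_per_condition):
            sub = TissueSimSpec(
                domain=spec.domain,
                counts=dict(spec.counts),
                parent_type=spec.parent_type,
                offspring_type=spec.offspring_type,
                attraction_sigma_um=spec.attraction_sigma_um,
                sample_id=f"{cond}_s{j}",
                condition=cond,
                seed=base_seed + idx,
            )
            smap, cells = simulate_tissue(sub, lineage_map, t_cell_types)
            maps.append(smap)
            tables.append(cells)
            idx += 1
    return (
        pd.concat(maps, ignore_index=True),
        pd.concat(tables, ignore_index=True),
    )
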