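"""Nearest-focal-cell distances, median-distance networks, comparisons.

The central spatial statistic: within each tissue sample, the minimum
Euclidean distance (in micrometers) from every non-focal cell to its
nearest focal cell (ISG-T by default).  Distances never cross sample
boundaries — each biopsy is analyzed separately — and samples without
any focal cell are excluded rather than given infinite distances.

Per-type medians of these distances summarize which cell types sit
closest to the focal population; they are ranked within lineage class
(lymphocyte / non-lymphocyte) and laid out as a star network with the
focal type at the hub.  Distances for a chosen type pair are compared
across conditions with one-way ANOVA plus Tukey HSD, or the two-group
nonparametric/Welch alternatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import validate_cell_table, validate_spatial_map

POOLINGS = ("pooled_cells", "median_of_sample_medians")


# ---------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------

def nearest_focal_distances(
    smap: pd.DataFrame,
    cells: pd.DataFrame,
    focal_type: str = "ISG-T",
) -> tuple[pd.DataFrame, list[str]]:
    """Distance from every non-focal cell to its nearest focal cell.

    Computed per sample with an exact KD-tree query.  Returns the
    distance records (``cell_id``, ``sample_id``, ``condition``,
    ``cell_type``, ``lineage``, ``d_min_um``) and the list of samples
    skipped because they contain no focal cell.
    """
    validate_spatial_map(smap)
    validate_cell_table(cells)
    df = smap.merge(
        cells[[c for c in ("cell_id", "condition", "cell_type", "lineage") if c in cells.columns]],
        on="cell_id",
        how="inner",
    )
    if (df["cell_type"] == focal_type).sum() == 0:
        raise ValueError(f"focal type {focal_type!r} absent from every sample")

    records = []
    skipped: list[str] = []
    for sample_id, g in df.groupby("sample_id", sort=True):
        focal = g["cell_type"] == focal_type
        if not focal.any():
            skipped.append(str(sample_id))
            continue
        tree = cKDTree(g.loc[focal, ["x_um", "y_um"]].to_numpy(dtype=float))
        others = g.loc[~focal]
        if others.empty:
            continue
        d, _ = tree.query(others[["x_um", "y_um"]].to_numpy(dtype=float), k=1)
        rec = others[["cell_id", "sample_id", "cell_type"]].copy()
        rec["condition"] = others["condition"] if "condition" in others else "unknown"
        rec["lineage"] = others["lineage"] if "lineage" in others else "other"
        rec["d_min_um"] = d
        records.append(rec)
    out = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["cell_id", "sample_id", "cell_type", "condition", "lineage", "d_min_um"])
    )
    return out[["cell_id", "sample_id", "condition", "cell_type", "lineage", "d_min_um"]], skipped


def median_distance_by_type(
    records: pd.DataFrame,
    pooling: str = "pooled_cells",
    by_condition: bool = False,
) -> pd.DataFrame:
    """Per-type median nearest-focal distance under the chosen pooling.

    ``pooled_cells`` takes the median over all cells of the type
    (within condition when ``by_condition``); the legend-style n is the
    cell count.  ``median_of_sample_medians`` first takes each sample's
    median, then the median of those — robust to unbalanced biopsies.
    """
    if pooling not in POOLINGS:
        raise ValueError(f"unknown pooling {pooling!r}; expected one of {POOLINGS}")
    if records.empty:
        raise ValueError("no distance records to summarize")
    keys = ["condition", "cell_type"] if by_condition else ["cell_type"]
    rows = []
    for key, g in records.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        if pooling == "pooled_cells":
            med = float(g["d_min_um"].median())
            n = len(g)
        else:
            sample_medians = g.groupby("sample_id")["d_min_um"].median()
            med = float(sample_medians.median())
            n = sample_medians.size
        lineage = g["lineage"].iloc[0] if "lineage" in g else "other"
        rows.append({**dict(zip(keys, key)), "lineage": lineage,
                     "median_d_um": med, "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# network / ranking
# ---------------------------------------------------------------------

@dataclass
class ProximityNetwork:
    """Star network: the focal type at the hub, one spoke per cell type.

    Each spoke carries the type's median nearest-focal distance and its
    ascending rank within its lineage class; rank 1 is the closest
    neighbor of that class.
    """

    focal_type: str
    table: pd.DataFrame  # cell_type, lineage, median_d_um, n, rank, is_closest, tied
    graph: nx.Graph = field(repr=False, default=None)

    def closest(self, lineage: str) -> str | None:
        sub = self.table[(self.table["lineage"] == lineage) & (self.table["rank"] == 1)]
        return None if sub.empty else str(sub["cell_type"].iloc[0])

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "focal_type": self.focal_type,
            "nodes": self.table.to_dict(orient="records"),
        }
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(json.dumps(payload, indent=2) + "\n")
        return payload


def rank_neighbors(
    medians: pd.DataFrame,
    focal_type: str = "ISG-T",
) -> ProximityNetwork:
    """Rank cell types by median distance within each lineage class.

    Ties in the median are broken by type-name order for the rank but
    flagged ``tied`` so both types are reported as joint neighbors.
    Lineage classes with no types are simply absent.
    """
    required = {"cell_type", "lineage", "median_d_um"}
    if not required <= set(medians.columns):
        raise ValueError(f"medians table must have columns {sorted(required)}")
    table = medians[medians["cell_type"] != focal_type].copy()
    table = table.sort_values(["lineage", "median_d_um", "cell_type"], kind="stable")
    table["rank"] = table.groupby("lineage")["median_d_um"].rank(method="first").astype(int)
    tied = table.duplicated(subset=["lineage", "median_d_um"], keep=False)
    table["tied"] = tied
    table["is_closest"] = table["rank"] == 1
    table = table.reset_index(drop=True)

    g = nx.Graph()
    g.add_node(focal_type, role="focal")
    for _, row in table.iterrows():
        g.add_node(row["cell_type"], lineage=row["lineage"])
        g.add_edge(
            focal_type,
            row["cell_type"],
            distance=float(row["median_d_um"]),
            rank=int(row["rank"]),
        )
    return ProximityNetwork(focal_type=focal_type, table=table, graph=g)


def plot_proximity_network(network: ProximityNetwork, path: str | Path) -> None:
    """Radial figure: focal hub centered, types on a circle, edges
    colored blue (near) to red (far) with width inversely tied to
    distance."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = network.table
    n = len(t)
    fig, ax = plt.subplots(figsize=(7, 7))
    if n:
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        d = t["median_d_um"].to_numpy(dtype=float)
        dn = (d - d.min()) / (d.max() - d.min()) if d.max() > d.min() else np.zeros(n)
        cmap = plt.get_cmap("coolwarm")
        for i, (_, row) in enumerate(t.iterrows()):
            x, y = np.cos(theta[i]), np.sin(theta[i])
            ax.plot([0, x], [0, y], color=cmap(dn[i]), linewidth=1 + 4 * (1 - dn[i]))
            ax.annotate(f"{row['cell_type']}\n{row['median_d_um']:.1f} um",
                        (x, y), ha="center", fontsize=8)
    ax.scatter([0], [0], s=250, color="black", zorder=3)
    ax.annotate(network.focal_type, (0, 0.08), ha="center", fontsize=10)
    ax.set_axis_off()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------
# condition comparisons
# ---------------------------------------------------------------------

TESTS = ("anova_tukey", "mann_whitney", "welch_t", "wilcoxon", "pearson")


@dataclass
class ConditionComparison:
    """Result of comparing per-cell distances across condition groups."""

    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    group_medians: dict[str, float]
    pairwise: pd.DataFrame | None = None  # Tukey HSD table for anova_tukey
    note: str = ""

    def to_dict(self) -> dict:
        d = {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_sizes": self.group_sizes,
            "group_medians": self.group_medians,
            "note": self.note,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def compare_conditions(
    groups: Mapping[str, Sequence[float]],
    test: str = "anova_tukey",
) -> ConditionComparison:
    """Compare distance distributions between condition groups.

    ``anova_tukey`` (3+ groups, or 2): one-way ANOVA F/p plus all
    pairwise Tukey HSD adjusted p-values.  ``mann_whitney``,
    ``welch_t`` and ``wilcoxon`` (two-sided rank-sum) require exactly
    two groups.  Groups that are all identical constants make the test
    statistic undefined; the p-value is reported as NaN with a note
    rather than raising.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    if test == "pearson":
        raise ValueError("pearson compares two paired numeric vectors; use pearson_correlation")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("at least two condition groups are required")
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs at least two observations")
    sizes = {k: int(a.size) for k, a in arrays.items()}
    medians = {k: float(np.median(a)) for k, a in arrays.items()}

    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        return ConditionComparison(
            test=test, statistic=np.nan, p_value=np.nan,
            group_sizes=sizes, group_medians=medians,
            note="degenerate groups: zero variance everywhere, test undefined",
        )

    names = list(arrays)
    if test == "anova_tukey":
        f, p = stats.f_oneway(*arrays.values())
        values = np.concatenate([arrays[k] for k in names])
        labels = np.concatenate([[k] * arrays[k].size for k in names])
        tukey = pairwise_tukeyhsd(values, labels)
        pairwise = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        return ConditionComparison(
            test=test, statistic=float(f), p_value=float(p),
            group_sizes=sizes, group_medians=medians, pairwise=pairwise,
        )

    if len(arrays) != 2:
        raise ValueError(f"test {test!r} requires exactly two groups")
    a, b = (arrays[k] for k in names)
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:  # wilcoxon rank-sum
        res = stats.ranksums(a, b)
    return ConditionComparison(
        test=test, statistic=float(res.statistic), p_value=float(res.pvalue),
        group_sizes=sizes, group_medians=medians,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson correlation needs two equal-length vectors, n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
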