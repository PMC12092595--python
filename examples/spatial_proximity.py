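"""Nearest-neighbor proximity analysis on a simulated two-condition cohort.

Simulates 5 disease biopsies, in which ISG-T cells scatter around pDC
parents with sigma = 30 um, and 5 control biopsies with uniform ISG-T
placement.  Computes per-sample nearest-ISG-T distances, pooled
per-type medians, the ranked median-distance network, and the
disease-vs-control comparison for pDC.
"""

import numpy as np

from isgt import (
    TissueSimSpec,
    compare_conditions,
    median_distance_by_type,
    nearest_focal_distances,
    rank_neighbors,
    simulate_cohort,
)

smap, cells = simulate_cohort(
    {
        "disease": TissueSimSpec(attraction_sigma_um=30.0),
        "control": TissueSimSpec(attraction_sigma_um=np.inf),
    },
    n_samples_per_condition=5,
    base_seed=11,
)

records, skipped = nearest_focal_distances(smap, cells, focal_type="ISG-T")
print(f"{len(records)} nearest-ISG-T distances across "
      f"{records['sample_id'].nunique()} samples (skipped: {skipped})")

medians = median_distance_by_type(
    records[records["condition"] == "disease"], pooling="pooled_cells"
)
network = rank_neighbors(medians, focal_type="ISG-T")
print("\nDisease cohort, median distance to the nearest ISG-T cell (um):")
print(network.table[["cell_type", "lineage", "median_d_um", "rank"]]
      .sort_values(["lineage", "rank"]).to_string(index=False))
print(f"\nclosest non-lymphocyte neighbor: {network.closest('non_lymphocyte')}")

pdc = records[records["cell_type"] == "pDC"]
groups = {c: g["d_min_um"].to_numpy() for c, g in pdc.groupby("condition")}
result = compare_conditions(groups, test="anova_tukey")
print("\npDC -> nearest ISG-T, disease vs control:")
for cond, med in result.group_medians.items():
    print(f"  median[{cond}] = {med:.2f} um (n={result.group_sizes[cond]})")
print(f"  one-way ANOVA: F = {result.statistic:.1f}, p = {result.p_value:.3g}")
print(
    "\npDC ranking first among non-lymphocytes and a much smaller disease\n"
    "median reproduce the built-in ISG-T/pDC attraction."
)
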