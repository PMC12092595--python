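"""Score an ISG program and call ISG-T cells on simulated data.

Simulates a 2,000-cell population in which 5% of T cells carry a
4-fold upregulated 20-gene interferon-stimulated-gene (ISG) program,
normalizes, computes the bin-matched module score, calls ISG-T cells
with the default mean + 3 SD rule, and checks the calls against the
simulator's ground truth.
"""

import numpy as np

from isgt import (
    ExpressionSimSpec,
    GeneSet,
    ScoreParams,
    XENIUM_DIALECT,
    call_isgt,
    isgt_frequency,
    normalize,
    score_program,
    simulate_expression,
)

panel = GeneSet("ISG_panel", [f"ISGX{i}" for i in range(20)])
spec = ExpressionSimSpec(
    n_cells=2000,
    n_genes=2000,
    program_genes=panel,
    program_log2fc=2.0,   # 4-fold on the mean of each program gene
    program_fraction=0.05,
    seed=7,
)
matrix, cells = simulate_expression(spec)
matrix = matrix.subset(cell_mask=matrix.counts_per_cell() > 0)
cells = cells[cells["cell_id"].isin(matrix.cell_ids)]

lognorm = normalize(matrix, XENIUM_DIALECT)
scores = score_program(lognorm, panel, ScoreParams(seed=0))
calls = call_isgt(scores, cells, "sd:3")

truth = cells.set_index("cell_id").loc[calls["cell_id"], "truth_is_program_positive"]
called = calls["is_isgt"].to_numpy()
t = truth.to_numpy()

print(f"cells scored:          {len(scores)}")
print(f"true program-positive: {t.sum()}")
print(f"called ISG-T:          {called.sum()}")
print(f"sensitivity:           {(called & t).sum() / t.sum():.3f}")
print(f"specificity:           {(~called & ~t).sum() / (~t).sum():.3f}")
print(f"per-sample ISG-T frequency among T cells:")
print(isgt_frequency(calls, cells).round(4).to_string())
print(
    "\nA frequency near the simulated 0.05 and sensitivity/specificity near 1\n"
    "mean the score threshold recovers the planted ISG-T subset."
)
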