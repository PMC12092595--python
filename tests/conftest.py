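import logging

import numpy as np
import pytest

from isgt import (
    CountMatrix,
    ExpressionSimSpec,
    GeneSet,
    ScoreParams,
    XENIUM_DIALECT,
    normalize,
    simulate_expression,
)


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    """Keep the expected per-operation warnings out of the test output."""
    logging.getLogger("isgt").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def isg_panel() -> GeneSet:
    """A 20-gene stand-in for a realistic ISG panel."""
    return GeneSet("ISG_panel", [f"ISGX{i}" for i in range(20)])


@pytest.fixture(scope="session")
def programmed_expression(isg_panel):
    """A simulated cohort with a strong ISG program in 5% of T cells.

    Shared across scoring/calling tests; simulated once per session.
    """
    spec = ExpressionSimSpec(
        n_cells=2000,
        n_genes=2000,
        program_genes=isg_panel,
        program_log2fc=2.0,
        program_fraction=0.05,
        seed=7,
    )
    m, cells = simulate_expression(spec)
    keep = m.counts_per_cell() > 0
    m = m.subset(cell_mask=keep)
    cells = cells[cells["cell_id"].isin(m.cell_ids)].reset_index(drop=True)
    lognorm = normalize(m, XENIUM_DIALECT)
    return lognorm, cells


@pytest.fixture
def tiny_lognorm() -> CountMatrix:
    """Deterministic 6-gene x 3-cell log-normalized toy matrix."""
    values = np.array(
        [
            [1.0, 2.0, 0.5, 1.5, 3.0, 0.0],
            [2.0, 1.0, 1.5, 0.5, 2.5, 1.0],
            [0.0, 3.0, 2.5, 2.0, 1.0, 2.0],
        ]
    )
    return CountMatrix(
        ["c1", "c2", "c3"], [f"g{i}" for i in range(1, 7)], values, layer="lognorm"
    )
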