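"""Per-cell gene-program scores with expression-matched control genes.

The module score of a gene program (e.g. an interferon-stimulated-gene
panel) in a cell is the mean log-normalized expression of the program
genes minus the mean expression of a randomly drawn control pool.
Controls are matched on overall expression level: all genes are ranked
by their mean expression across cells and cut into equal-frequency
bins, and each program gene contributes ``n_ctrl_per_gene`` random
non-program genes from its own bin to the pool.  Matching on expression
bins makes the subtraction a proper null — without it, highly expressed
programs would score high in every cell.

ISG-T cells are then called from the score by an explicit, auditable
threshold rule (absolute cutoff, score quantile, or mean + k standard
deviations of a program-free reference population).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, GeneSet

logger = logging.getLogger("isgt")


@dataclass
class ScoreParams:
    """Control-matching parameters: bin count, controls per program gene, seed."""

    n_bins: int = 24
    n_ctrl_per_gene: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_ctrl_per_gene < 1:
            raise ValueError("n_ctrl_per_gene must be >= 1")


def bin_genes(m: CountMatrix, n_bins: int) -> dict[str, int]:
    """Assign every gene to an equal-frequency mean-expression bin.

    Genes are ranked by mean expression over all cells (ties broken by
    input gene order, which keeps the assignment deterministic) and cut
    into ``n_bins`` contiguous rank bins whose sizes differ by at most
    one.  Bin 0 holds the lowest-expressed genes.
    """
    m.require_layer("lognorm", "bin_genes")
    if n_bins > m.n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds the {m.n_genes} available genes")
    means = np.asarray(m.counts.mean(axis=0)).ravel()
    order = np.argsort(means, kind="stable")
    assignment: dict[str, int] = {}
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        for gi in chunk:
            assignment[m.gene_ids[gi]] = b
    return assignment


def score_program(
    m: CountMatrix,
    gs: GeneSet,
    p: ScoreParams | None = None,
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """Score a gene program in every cell against bin-matched controls.

    For each cell: ``score = mean(program-gene expression) -
    mean(control-pool expression)``.  The control pool concatenates,
    for every program gene present in the matrix,
    ``n_ctrl_per_gene`` genes drawn without replacement from that
    gene's expression bin after excluding all program genes; when a bin
    has too few eligible genes the draw falls back to sampling with
    replacement (warned).  The draw is fixed by ``p.seed``.

    Returns a DataFrame with columns ``cell_id``, ``program``,
    ``score``.
    """
    m.require_layer("lognorm", "score_program")
    p = p or ScoreParams()
    rng = np.random.default_rng(p.seed)

    present = gs.present_in(m.gene_ids, case_insensitive=case_insensitive)
    absent = [g for g in gs.genes if g not in set(present)] if not case_insensitive else [
        g for g in gs.genes if g.upper() not in {x.upper() for x in present}
    ]
    if not present:
        raise ValueError(f"no gene of program {gs.name!r} is present in the matrix")
    if absent:
        logger.warning(
            "program %r: %d gene(s) absent from the matrix and dropped: %s",
            gs.name, len(absent), absent,
        )

    bins = bin_genes(m, p.n_bins)
    gene_pos = m.gene_index()
    program_set = set(present)
    by_bin: dict[int, list[str]] = {}
    for g, b in bins.items():
        by_bin.setdefault(b, []).append(g)

    control_genes: list[str] = []
    for g in present:
        pool = [x for x in by_bin[bins[g]] if x not in program_set]
        if not pool:
            raise ValueError(
                f"bin of program gene {g!r} holds no non-program genes to draw controls from"
            )
        if len(pool) >= p.n_ctrl_per_gene:
            draw = rng.choice(len(pool), size=p.n_ctrl_per_gene, replace=False)
        else:
            logger.warning(
                "bin of %r has only %d eligible controls (< %d); sampling with replacement",
                g, len(pool), p.n_ctrl_per_gene,
            )
            draw = rng.choice(len(pool), size=p.n_ctrl_per_gene, replace=True)
        control_genes.extend(pool[i] for i in draw)

    X = m.counts
    prog_cols = [gene_pos[g] for g in present]
    ctrl_cols = [gene_pos[g] for g in control_genes]
    prog_mean = np.asarray(X[:, prog_cols].mean(axis=1)).ravel()
    # control pool is a multiset: repeats keep their multiplicity in the mean
    ctrl_mean = np.asarray(X[:, ctrl_cols].mean(axis=1)).ravel()
    score = prog_mean - ctrl_mean
    return pd.DataFrame({"cell_id": m.cell_ids, "program": gs.name, "score": score})


@dataclass
class CallRule:
    """Threshold rule for calling program-positive cells.

    kind
        ``"sd"`` — threshold = mean + value * SD of the reference
        scores; ``"quantile"`` — threshold = that quantile of the
        reference scores; ``"abs"`` — absolute score cutoff.
    reference
        ``"non_t"`` (default) uses non-T cells as the program-free
        reference when any are among the scored cells, falling back to
        all scored cells; ``"all"`` always uses all scored cells.
        Ignored for ``kind="abs"``.
    """

    kind: str = "sd"
    value: float = 3.0
    reference: str = "non_t"

    @classmethod
    def parse(cls, text: str) -> "CallRule":
        """Parse ``"sd:3"``, ``"quantile:0.99"`` or ``"abs:0.5"``."""
        try:
            kind, value = text.split(":", 1)
            return cls(kind=kind.strip(), value=float(value))
        except ValueError as exc:
            raise ValueError(f"cannot parse call rule {text!r}; expected kind:value") from exc

    def __post_init__(self) -> None:
        if self.kind not in ("sd", "quantile", "abs"):
            raise ValueError(f"unknown call-rule kind {self.kind!r}")
        if self.kind == "quantile" and not 0.0 <= self.value <= 1.0:
            raise ValueError("quantile rule value must lie in [0, 1]")
        if self.reference not in ("non_t", "all"):
            raise ValueError(f"unknown reference population {self.reference!r}")


def call_isgt(
    scores: pd.DataFrame,
    cells: pd.DataFrame,
    rule: CallRule | str = "sd:3",
) -> pd.DataFrame:
    """Call ISG-program-positive cells from their scores.

    Returns a DataFrame with ``cell_id``, ``is_isgt`` and ``rule`` (a
    human-readable description including the realized threshold).
    Calls are deterministic given (scores, rule).
    """
    if isinstance(rule, str):
        rule = CallRule.parse(rule)
    merged = scores.merge(cells[["cell_id", "is_T"]], on="cell_id", how="left")
    if merged["is_T"].isna().any():
        missing = merged.loc[merged["is_T"].isna(), "cell_id"].head(3).tolist()
        raise ValueError(f"scored cells missing from cell table, e.g. {missing}")

    s = merged["score"].to_numpy(dtype=float)
    if rule.kind == "abs":
        threshold = rule.value
        desc = f"abs:{rule.value}"
    else:
        if rule.reference == "non_t" and (~merged["is_T"]).any():
            ref = s[~merged["is_T"].to_numpy(dtype=bool)]
            ref_name = "non-T cells"
        else:
            ref = s
            ref_name = "all scored cells"
        if ref.size == 0:
            raise ValueError("empty reference population for threshold rule")
        if rule.kind == "sd":
            threshold = float(ref.mean() + rule.value * ref.std(ddof=1))
            desc = f"sd:{rule.value} over {ref_name} (threshold={threshold:.6g})"
        else:
            threshold = float(np.quantile(ref, rule.value))
            desc = f"quantile:{rule.value} over {ref_name} (threshold={threshold:.6g})"

    return pd.DataFrame(
        {
            "cell_id": merged["cell_id"],
            "is_isgt": s > threshold,
            "rule": desc,
        }
    )


def isgt_frequency(calls: pd.DataFrame, cells: pd.DataFrame) -> pd.Series:
    """Per-sample fraction of ISG-T cells among T cells.

    Samples without any T cell get NaN (the frequency is undefined
    there), never zero.
    """
    merged = calls.merge(
        cells[["cell_id", "sample_id", "is_T"]], on="cell_id", how="left"
    )
    if merged["sample_id"].isna().any():
        raise ValueError("called cells missing from cell table")

    def _freq(g: pd.DataFrame) -> float:
        n_t = int(g["is_T"].sum())
        if n_t == 0:
            return np.nan
        return float((g["is_isgt"] & g["is_T"]).sum() / n_t)

    out = merged.groupby("sample_id", sort=True).apply(_freq, include_groups=False)
    out.name = "isgt_frequency"
    return out
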