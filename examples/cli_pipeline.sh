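#!/usr/bin/env bash
# Full pipeline via the command line: simulate expression and tissue,
# QC + normalize, score the ISG program, call ISG-T cells, run the
# proximity analysis and compare conditions. Outputs land in ./out.
set -euo pipefail

OUT=out
SEED=42

isgt simulate-expression --out-dir "$OUT/expr" --seed $SEED \
    --n-cells 1000 --n-genes 500 --log2fc 2.0 --fraction 0.05
isgt qc --out-dir "$OUT/expr" --matrix "$OUT/expr/counts" \
    --min-genes 20 --min-counts 20 --max-counts 100000 --min-cells-per-gene 3
isgt normalize --out-dir "$OUT/expr" --matrix "$OUT/expr/filtered" --dialect xenium
isgt score --out-dir "$OUT/expr" --matrix "$OUT/expr/normalized.csv" --seed $SEED \
    --n-bins 12 --n-ctrl 30
isgt call-isgt --out-dir "$OUT/expr" --scores "$OUT/expr/scores.csv" \
    --cells "$OUT/expr/cells.csv"

isgt simulate-tissue --out-dir "$OUT/tissue" --seed $SEED \
    --sigma 30 --n-samples 5 --with-control
isgt proximity --out-dir "$OUT/tissue" --spatial "$OUT/tissue/spatial.csv" \
    --cells "$OUT/tissue/tissue_cells.csv" --focal-type ISG-T --figure
isgt compare --out-dir "$OUT/tissue" --distances "$OUT/tissue/distances.csv" \
    --cell-type pDC --test anova_tukey
isgt report --out-dir "$OUT" --medians "$OUT/tissue/medians.csv" \
    --comparison "$OUT/tissue/comparison.json"

echo "Pipeline outputs written under $OUT/"
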