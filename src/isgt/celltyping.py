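"""Reference-based cell typing by regularized multinomial regression.

Imaging-based spatial panels are annotated by training a multinomial
logistic classifier on a labeled reference (log-normalized expression
as features, cell-type labels as targets) and applying it to the query
cells.  The L2 regularization strength is chosen by stratified
cross-validated log-loss over a grid.  The trained model is a plain
(weights, intercepts, gene list, class list) bundle serialized as
JSON, so prediction is independent of the training library version and
invariant to gene order in the query matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .datatypes import CountMatrix

logger = logging.getLogger("isgt")


@dataclass
class ClassifierModel:
    """Linear multinomial classifier with its feature space recorded."""

    gene_ids: list[str]
    class_labels: list[str]
    weights: np.ndarray  # (n_classes, n_genes)
    intercepts: np.ndarray  # (n_classes,)
    regularization_strength: float  # selected C (inverse penalty)
    cv_folds: int
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "gene_ids": self.gene_ids,
            "class_labels": self.class_labels,
            "weights": np.asarray(self.weights).tolist(),
            "intercepts": np.asarray(self.intercepts).tolist(),
            "regularization_strength": float(self.regularization_strength),
            "cv_folds": self.cv_folds,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=d["gene_ids"],
            class_labels=d["class_labels"],
            weights=np.asarray(d["weights"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            regularization_strength=d["regularization_strength"],
            cv_folds=d["cv_folds"],
            metadata=d.get("metadata", {}),
        )


def train_classifier(
    ref: CountMatrix,
    labels: Sequence[str],
    cv_folds: int = 5,
    strength_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the reference classifier with cross-validated regularization.

    ``strength_grid`` lists candidate C values (inverse L2 penalty);
    the value minimizing stratified CV log-loss is kept and the model
    refit on all reference cells.  Every class must have at least
    ``cv_folds`` members so stratification is possible.
    """
    ref.require_layer("lognorm", "train_classifier")
    y = np.asarray([str(l) for l in labels])
    if y.shape[0] != ref.n_cells:
        raise ValueError("one label per reference cell is required")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("at least two classes are required")
    small = classes[counts < cv_folds]
    if small.size:
        raise ValueError(
            f"classes {small.tolist()} have fewer than cv_folds={cv_folds} cells; "
            f"reduce cv_folds or drop these classes"
        )
    grid = np.asarray(strength_grid if strength_grid is not None else np.logspace(-4, 4, 10),
                      dtype=float)
    if (grid <= 0).any():
        raise ValueError("strength_grid entries must be positive")

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=grid,
        cv=cv,
        l1_ratios=(0.0,),  # pure L2 penalty
        scoring="neg_log_loss",
        solver="lbfgs",
        max_iter=2000,
        random_state=seed,
        use_legacy_attributes=True,
    )
    clf.fit(ref.dense(), y)
    weights = np.asarray(clf.coef_, dtype=float)
    intercepts = np.asarray(clf.intercept_, dtype=float)
    if weights.shape[0] == 1 and classes.size == 2:
        # binary fit stores one logit row (for classes_[1]); expand to
        # the per-class form the softmax predictor expects
        weights = np.vstack([np.zeros_like(weights[0]), weights[0]])
        intercepts = np.array([0.0, intercepts[0]])
    return ClassifierModel(
        gene_ids=list(ref.gene_ids),
        class_labels=[str(c) for c in clf.classes_],
        weights=weights,
        intercepts=intercepts,
        regularization_strength=float(np.ravel(clf.C_)[0]),
        cv_folds=cv_folds,
        metadata={"seed": seed, "strength_grid": grid.tolist()},
    )


def _align_features(model: ClassifierModel, m: CountMatrix) -> np.ndarray:
    """Query matrix reordered to the model's feature space.

    Genes are matched by identifier; query genes unknown to the model
    are dropped, model genes absent from the query are imputed as 0 on
    the log-normalized scale (warned).  More than half the model genes
    missing is treated as a feature-space mismatch and is an error.
    """
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    present = [g for g in model.gene_ids if g in pos]
    if len(present) < 0.5 * len(model.gene_ids):
        raise ValueError(
            f"only {len(present)}/{len(model.gene_ids)} model genes present in the "
            f"query matrix; feature spaces are incompatible"
        )
    missing = len(model.gene_ids) - len(present)
    if missing:
        logger.warning(
            "predict: %d/%d model genes absent from query; imputed as 0",
            missing, len(model.gene_ids),
        )
    X = np.zeros((m.n_cells, len(model.gene_ids)))
    dense = m.dense()
    for j, g in enumerate(model.gene_ids):
        if g in pos:
            X[:, j] = dense[:, pos[g]]
    return X


def predict_types(model: ClassifierModel, m: CountMatrix) -> pd.DataFrame:
    """Assign a cell type and per-class probabilities to every cell.

    Returns a DataFrame indexed like the input cells with a
    ``cell_type`` column (argmax class; ties go to the earlier class
    label) followed by one probability column per class.
    """
    m.require_layer("lognorm", "predict_types")
    X = _align_features(model, m)
    logits = X @ np.asarray(model.weights).T + np.asarray(model.intercepts)
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    # np.argmax returns the first maximum: ties break by class-label order
    calls = [model.class_labels[i] for i in probs.argmax(axis=1)]
    out = pd.DataFrame({"cell_id": m.cell_ids, "cell_type": calls})
    for j, c in enumerate(model.class_labels):
        out[f"prob_{c}"] = probs[:, j]
    return out
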