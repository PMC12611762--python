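"""Cell-type interaction map from niche composition.

A multinomial logistic regression classifier predicts each cell's type from
the enrichment-normalized composition of its contact niche. Positive
regression coefficients indicate preferential colocalization of the niche
type with the central type; the coefficient matrix, thresholded, yields the
directed niche-interaction network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .graph import NicheComposition

__all__ = ["InteractionMap", "fit_interaction_map", "extract_network"]


@dataclass
class InteractionMap:
    """Fitted niche classifier: coefficients and held-out performance.

    ``coefficients`` rows are central (predicted) cell types, columns niche
    cell types; entries are fold-averaged classifier weights on the
    enrichment features.
    """

    coefficients: pd.DataFrame
    per_class_accuracy: pd.Series
    confusion: pd.DataFrame
    overall_accuracy: float
    regularization: float
    folds: int
    seed: int
    n_cells_used: int


def fit_interaction_map(
    composition: NicheComposition,
    labels: pd.Series | None = None,
    regularization: float = 1.0,
    folds: int = 5,
    seed: int = 0,
) -> InteractionMap:
    """Fit the niche-composition classifier with stratified cross-validation.

    Parameters
    ----------
    composition
        Per-cell niche composition, enrichment mode recommended (features
        already normalized by global type frequencies, so coefficients are
        comparable across types and to the conventional 0.14 edge
        threshold). Isolated cells are excluded.
    labels
        Central cell-type label per cell (indexed by cell_id). Defaults to
        niches being predicted for the composition's own cell ordering; must
        be provided as a Series aligned on cell ids.
    regularization
        L2 penalty strength (inverse of sklearn's C).
    """
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    if labels is None:
        raise ValueError("labels are required")
    labels = labels.reindex(composition.cell_ids)
    if labels.isna().any():
        raise ValueError("labels missing for some cells in the composition")

    isolated = set(composition.isolated)
    mask = np.array([c not in isolated for c in composition.cell_ids])
    X = composition.matrix[mask]
    y = labels.to_numpy()[mask].astype(str)

    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 cell types to fit the classifier")
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        raise ValueError(
            f"every type needs >= {folds} cells; too rare: "
            f"{list(counts[counts < folds].index)}"
        )

    zero_var = X.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance niche features: {list(np.array(composition.cell_types)[zero_var])}"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    coef_sum = np.zeros((classes.size, X.shape[1]))
    y_pred = np.empty(y.size, dtype=object)
    for train, test in skf.split(X, y):
        clf = LogisticRegression(
            C=1.0 / regularization,  # L2 penalty (sklearn default)
            solver="lbfgs",
            max_iter=2000,
            class_weight="balanced",
        )
        clf.fit(X[train], y[train])
        W = clf.coef_
        if W.shape[0] == 1 and clf.classes_.size == 2:
            # binary fit returns one row; expand to the symmetric softmax form
            W = np.vstack([-W[0] / 2, W[0] / 2])
        coef = pd.DataFrame(W, index=clf.classes_, columns=composition.cell_types)
        coef_sum += coef.reindex(index=classes).to_numpy()
        y_pred[test] = clf.predict(X[test])

    coefficients = pd.DataFrame(coef_sum / folds, index=classes, columns=composition.cell_types)
    # square the matrix over the common vocabulary
    vocab = [t for t in composition.cell_types if t in set(classes)]
    coefficients = coefficients.reindex(index=vocab, columns=composition.cell_types)

    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(y_pred.astype(str), name="predicted"), dropna=False
    ).reindex(index=classes, columns=classes, fill_value=0)
    per_class = pd.Series(
        {c: confusion.loc[c, c] / max(confusion.loc[c].sum(), 1) for c in classes}
    )
    overall = float((y_pred == y).mean())
    return InteractionMap(
        coefficients=coefficients,
        per_class_accuracy=per_class,
        confusion=confusion,
        overall_accuracy=overall,
        regularization=regularization,
        folds=folds,
        seed=seed,
        n_cells_used=int(mask.sum()),
    )


def extract_network(imap: InteractionMap, threshold: float = 0.14) -> pd.DataFrame:
    """Directed interaction edges (niche type -> central type) above threshold.

    Returns a table (source, target, weight) with one row per coefficient
    strictly greater than ``threshold``; source is the niche type, target the
    central type whose identity it predicts.
    """
    rows = []
    coef = imap.coefficients
    for central in coef.index:
        for niche in coef.columns:
            w = coef.loc[central, niche]
            if np.isfinite(w) and w > threshold:
                rows.append({"source": niche, "target": central, "weight": float(w)})
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
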