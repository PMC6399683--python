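"""Combined predictive logistic models (CombLR) and accuracy-vs-k traces.

Every data block produces, as a by-product of its local tests, a logistic
model for the target on the currently selected features.  Because blocks
are equal-sized random splits, the per-block coefficient vectors are
combined by their plain arithmetic mean (weighted least squares with equal
weights), yielding a global predictive model at no extra fitting cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["CombinedModel", "combine_local_models", "predict_and_score", "accuracy_trace"]


@dataclass
class CombinedModel:
    """Average of per-block logistic coefficient vectors (intercept first)."""

    coefficients: np.ndarray
    n_components: int
    feature_labels: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_labels": list(self.feature_labels),
                "coefficients": [float(c) for c in self.coefficients],
                "n_components": self.n_components,
            },
            indent=2,
        )


def combine_local_models(coefficient_vectors, feature_labels=None) -> CombinedModel:
    """Element-wise mean of N coefficient vectors of identical length/order."""
    vecs = [np.asarray(v, dtype=float) for v in coefficient_vectors]
    if not vecs:
        raise ValueError("need at least one component model")
    p = vecs[0].size
    if any(v.size != p for v in vecs):
        raise ValueError("component coefficient vectors differ in length")
    mean = np.mean(np.vstack(vecs), axis=0)
    return CombinedModel(
        coefficients=mean,
        n_components=len(vecs),
        feature_labels=list(feature_labels) if feature_labels is not None else [],
    )


def predict_and_score(model: CombinedModel, rows, labels=None):
    """Logistic-link probabilities and, when labels are given, 0.5-threshold accuracy.

    ``rows`` must carry the model's features in ``feature_labels`` order
    (no intercept column).  Returns ``(probabilities, accuracy)``;
    ``accuracy`` is None when no labels are supplied.
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    k = len(model.coefficients) - 1
    if X.shape[1] != k:
        raise ValueError(
            f"model expects {k} feature columns, got {X.shape[1]}"
        )
    eta = model.coefficients[0] + X @ model.coefficients[1:]
    probs = expit(eta)
    if labels is None:
        return probs, None
    y = np.asarray(labels, dtype=float).ravel()
    acc = float(np.mean((probs >= 0.5) == (y == 1.0)))
    return probs, acc


def accuracy_trace(per_iteration_models, holdout_rows, holdout_labels, feature_index):
    """Holdout accuracy of the cached combined model of each forward Iteration.

    ``feature_index`` maps a feature label to its column in
    ``holdout_rows``.  No refitting happens: the curve reuses the models
    cached while selecting.  Returns a list of ``(k_selected, accuracy)``
    pairs, one per completed forward Iteration.
    """
    X = np.asarray(holdout_rows, dtype=float)
    y = np.asarray(holdout_labels, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty holdout")
    curve = []
    for model in per_iteration_models:
        cols = [feature_index[f] for f in model.feature_labels]
        _, acc = predict_and_score(model, X[:, cols], y)
        curve.append((len(model.feature_labels), acc))
    return curve
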