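"""Loss functions: mean squared error for regression, cross-entropy for
classification, with a numerically stable softmax."""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError

_EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shifted by the row max for stability."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mse(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error over all elements."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if p.shape != t.shape:
        raise ConfigurationError(f"shape mismatch: predictions {p.shape} vs targets {t.shape}")
    return float(np.mean((p - t) ** 2))


def cross_entropy(probabilities: np.ndarray, class_indices: np.ndarray) -> float:
    """Mean negative log-probability of the true class."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(class_indices, dtype=np.int64)
    if p.ndim != 2 or y.shape != (p.shape[0],):
        raise ConfigurationError(
            f"expected probabilities (n, C) and labels (n,), got {p.shape} and {y.shape}"
        )
    return float(-np.mean(np.log(p[np.arange(len(y)), y] + _EPS)))


def loss(predictions: np.ndarray, labels: np.ndarray, task: str) -> float:
    """Task-dispatching loss: MSE for regression, cross-entropy on
    probabilities for classification."""
    if task == "regression":
        return mse(predictions, labels)
    if task == "classification":
        return cross_entropy(predictions, labels)
    raise ConfigurationError(f"unknown task {task!r}; expected 'regression' or 'classification'")
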