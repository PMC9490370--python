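"""Leave-one-out cross-validation and the two model-selection statistics.

RMSECV = sqrt( sum_i (y_i - y~_i)^2 / m ) and PRESS = sum_i (y_i - y^_i)^2,
where m is the calibration-set size and the predictions are leave-one-out:
each sample is predicted by a model fitted on the remaining m-1 samples.
The two are linked by PRESS = m * RMSECV^2 on the same vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CVResult", "rmsecv", "press", "loo_predictions", "loo_rmsecv", "loo_press"]


@dataclass
class CVResult:
    """Leave-one-out predictions with one summary statistic."""

    predicted: np.ndarray
    statistic_name: str  # "RMSECV" | "PRESS"
    value: float
    m: int


def _check_pair(actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ValueError(f"length mismatch: {a.size} vs {p.size}")
    if a.size == 0:
        raise ValueError("need at least one sample")
    return a, p


def rmsecv(actual, predicted) -> float:
    """Root mean squared error of cross-validation (m in the denominator)."""
    a, p = _check_pair(actual, predicted)
    return float(np.sqrt(np.mean((a - p) ** 2)))


def press(actual, predicted) -> float:
    """Predicted residual error sum of squares."""
    a, p = _check_pair(actual, predicted)
    return float(np.sum((a - p) ** 2))


def loo_predictions(
    fit_fn: Callable, predict_fn: Callable, X_like, y
) -> np.ndarray:
    """Leave-one-out predictions: element i comes from a model fitted without i.

    ``X_like`` is any array indexed by sample along axis 0 (a contour matrix
    or a three-way cube).  Inputs are not modified.  A failing fold raises
    with the fold index named.
    """
    X = np.asarray(X_like, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y disagree on the number of samples")
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 samples")
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = fit_fn(X[keep], y[keep])
            pred = predict_fn(model, X[i : i + 1])
        except Exception as exc:
            raise RuntimeError(f"leave-one-out fold {i} failed: {exc}") from exc
        out[i] = float(np.asarray(pred).ravel()[0])
    return out


def loo_rmsecv(fit_fn, predict_fn, X_like, y) -> CVResult:
    y = np.asarray(y, dtype=float).ravel()
    pred = loo_predictions(fit_fn, predict_fn, X_like, y)
    return CVResult(pred, "RMSECV", rmsecv(y, pred), y.size)


def loo_press(fit_fn, predict_fn, X_like, y) -> CVResult:
    y = np.asarray(y, dtype=float).ravel()
    pred = loo_predictions(fit_fn, predict_fn, X_like, y)
    return CVResult(pred, "PRESS", press(y, pred), y.size)
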