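"""Lasso regression (LAR) on contour vectors.

The model is the affine sparse formula C = b0 + sum_lambda coef(lambda) *
V_lambda over the emission-wavelength contour values, fitted by minimizing

    (1/2m) ||y - b0 - X beta||^2 + penalty * ||beta||_1

with cyclic coordinate descent.  Predictors are internally centered (and by
default scaled to unit variance) and the solution is back-transformed, so
reported coefficients live on the raw intensity scale.  Convergence requires
both a max coefficient change <= 1e-10 per sweep and a duality gap <= 1e-8.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_selection import loo_predictions, rmsecv

__all__ = ["LARModel", "lar_fit", "lar_predict", "select_penalty", "penalty_max"]

_GAP_TOL = 1e-8
_COEF_TOL = 1e-10


@dataclass
class LARModel:
    """Fitted lasso model; only nonzero coefficients appear in the map."""

    intercept: float
    coefficients: dict[float, float]  # emission wavelength (nm) -> raw-scale weight
    penalty: float
    wavelengths: np.ndarray  # the full variable universe, in order
    analyte: str | None = None

    @property
    def n_active(self) -> int:
        return len(self.coefficients)

    def coefficient_vector(self) -> np.ndarray:
        beta = np.zeros(len(self.wavelengths))
        lookup = {float(w): i for i, w in enumerate(self.wavelengths)}
        for lam, c in self.coefficients.items():
            beta[lookup[float(lam)]] = c
        return beta

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": "lar",
                "analyte": self.analyte,
                "intercept": self.intercept,
                "penalty": self.penalty,
                "wavelengths": [float(w) for w in self.wavelengths],
                "coefficients": {f"{lam:g}": c for lam, c in self.coefficients.items()},
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "LARModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            coefficients={float(k): v for k, v in d["coefficients"].items()},
            penalty=d["penalty"],
            wavelengths=np.array(d["wavelengths"], dtype=float),
            analyte=d.get("analyte"),
        )


def _duality_gap(Xs: np.ndarray, yc: np.ndarray, beta: np.ndarray, lam: float) -> float:
    m = yc.size
    r = yc - Xs @ beta
    primal = r @ r / (2 * m) + lam * np.abs(beta).sum()
    dual_norm = np.abs(Xs.T @ r).max() if beta.size else 0.0
    s = 1.0 if dual_norm <= m * lam or dual_norm == 0 else m * lam / dual_norm
    dual = s * (r @ yc) / m - s**2 * (r @ r) / (2 * m)
    return primal - dual


def _cd_solve(
    Xs: np.ndarray,
    yc: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 10000,
    gap_tol: float = _GAP_TOL,
) -> np.ndarray:
    """Cyclic coordinate descent for (1/2m)||yc - Xs b||^2 + lam ||b||_1.

    Uses covariance (Gram) updates: residual correlations are maintained
    through G @ beta rather than the residual vector itself.  Converged when
    the max coefficient change per sweep is <= 1e-10 or the duality gap
    drops below ``gap_tol``.
    """
    m, p = Xs.shape
    G = Xs.T @ Xs / m
    c = Xs.T @ yc / m
    d = np.diag(G).copy()
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    Gb = G @ beta
    for sweep in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if d[j] == 0.0:
                continue
            rho = c[j] - Gb[j] + d[j] * beta[j]
            bj_new = np.sign(rho) * max(abs(rho) - lam, 0.0) / d[j]
            delta = bj_new - beta[j]
            if delta != 0.0:
                Gb += G[:, j] * delta
                beta[j] = bj_new
                max_delta = max(max_delta, abs(delta))
        if max_delta <= _COEF_TOL:
            break  # no further numerical progress possible
        if lam > 0.0 and sweep % 10 == 9 and _duality_gap(Xs, yc, beta, lam) <= gap_tol:
            break
    return beta


def penalty_max(X, y, standardize: bool = True) -> float:
    """Smallest penalty at which every coefficient is zero."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        Xc = np.divide(Xc, np.where(sd == 0, 1.0, sd))
    return float(np.abs(Xc.T @ yc).max() / y.size)


def lar_fit(
    X,
    y,
    penalty: float,
    standardize: bool = True,
    analyte: str | None = None,
    wavelengths=None,
    max_iter: int = 10000,
) -> LARModel:
    """Fit the lasso at a fixed penalty.

    ``X`` is samples x emission variables (contour values); ``wavelengths``
    labels the columns in nm (defaults to 0..p-1).  A constant ``y`` yields
    the null model (intercept = y, empty coefficient map), as does any
    penalty at or above :func:`penalty_max`.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be samples x variables with one y per row")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    m, p = X.shape
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if wl.size != p:
        raise ValueError("wavelengths must label every column of X")

    y_mean = y.mean()
    yc = y - y_mean
    mu = X.mean(axis=0)
    Xc = X - mu
    if standardize:
        sd = X.std(axis=0)
        scale = np.where(sd == 0, 1.0, sd)
    else:
        scale = np.ones(p)
    Xs = Xc / scale

    # warm-started path from penalty_max down to the target penalty
    lam_hi = float(np.abs(Xs.T @ yc).max() / m)
    beta_s = np.zeros(p)
    if penalty > 0 and lam_hi > penalty:
        for lam in np.geomspace(lam_hi, penalty, 5)[:-1]:
            beta_s = _cd_solve(Xs, yc, lam, beta0=beta_s, max_iter=200, gap_tol=1e-6)
    beta_s = _cd_solve(Xs, yc, penalty, beta0=beta_s, max_iter=max_iter)
    beta = beta_s / scale
    intercept = y_mean - mu @ beta
    coefs = {float(wl[j]): float(beta[j]) for j in range(p) if beta[j] != 0.0}
    return LARModel(
        intercept=float(intercept),
        coefficients=coefs,
        penalty=float(penalty),
        wavelengths=wl,
        analyte=analyte,
    )


def lar_predict(model: LARModel, contours) -> np.ndarray:
    """Apply the affine sparse formula; negative predictions are kept as-is."""
    C = np.atleast_2d(np.asarray(contours, dtype=float))
    if C.shape[1] != model.wavelengths.size:
        raise ValueError(
            f"contour length {C.shape[1]} does not match the model's "
            f"{model.wavelengths.size} wavelengths"
        )
    pred = model.intercept + C @ model.coefficient_vector()
    if (pred < 0).any():
        warnings.warn("negative predicted concentration(s); reported as-is", stacklevel=2)
    return pred


def select_penalty(
    X,
    y,
    grid_size: int = 30,
    n_decades: float = 4.0,
    standardize: bool = True,
    rule: str = "min",
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty by leave-one-out RMSECV over a log-spaced grid.

    The grid runs from the full-data ``penalty_max`` down ``n_decades``
    decades.  Per fold, the path is solved from large to small penalty with
    warm starts.  ``rule="min"`` returns the RMSECV minimizer (ties resolve
    to the larger, sparser penalty); ``rule="1se"`` returns the largest
    penalty whose CV mean squared error is within one standard error of the
    minimum — the usual guard against chasing noise in a flat CV curve.
    Returns the winning penalty and the full CV curve.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m = y.size
    lam_hi = penalty_max(X, y, standardize=standardize)
    if lam_hi == 0.0:  # constant y: every penalty gives the null model
        lams = np.zeros(grid_size)
    else:
        lams = np.logspace(np.log10(lam_hi), np.log10(lam_hi) - n_decades, grid_size)
    preds = np.empty((grid_size, m))
    for i in range(m):
        keep = np.arange(m) != i
        Xtr, ytr = X[keep], y[keep]
        y_mean = ytr.mean()
        mu = Xtr.mean(axis=0)
        if standardize:
            sd = Xtr.std(axis=0)
            scale = np.where(sd == 0, 1.0, sd)
        else:
            scale = np.ones(X.shape[1])
        Xs = (Xtr - mu) / scale
        beta_s = np.zeros(X.shape[1])
        for g, lam in enumerate(lams):
            # relaxed tolerance along the CV path; RMSECV is insensitive at 1e-5
            beta_s = _cd_solve(Xs, ytr - y_mean, lam, beta0=beta_s, max_iter=300, gap_tol=1e-5)
            beta = beta_s / scale
            preds[g, i] = y_mean + (X[i] - mu) @ beta
    sq = (preds - y) ** 2
    cvm = sq.mean(axis=1)
    cvsd = sq.std(axis=1, ddof=1) / np.sqrt(m)
    curve = pd.DataFrame({"penalty": lams, "rmsecv": np.sqrt(cvm), "mse_se": cvsd})
    i_min = int(np.argmin(cvm))  # first min = largest penalty on the descending grid
    if rule == "min":
        best = i_min
    else:
        within = np.nonzero(cvm <= cvm[i_min] + cvsd[i_min])[0]
        best = int(within[0])
    return float(lams[best]), curve
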