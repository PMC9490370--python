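"""Trilinear N-PLS (tri-PLS1) regression on the EEM cube.

Each latent variable carries a unit-norm emission weight w_J and excitation
weight w_K obtained as the leading singular pair of the y-weighted covariance
matrix Z[j,k] = sum_i y_res[i] * X_res[i,j,k].  Sample scores are
t_i = sum_jk X_res[i,j,k] w_J[j] w_K[k]; y is regressed on all scores
collected so far, then both X and y are deflated.  Data are centered across
the sample mode only (mean slab / mean y), with no scaling.  The SVD sign
ambiguity is fixed by making the largest-magnitude element of w_J positive
(flipping w_K along with it), so fitting is fully deterministic.

The number of latent variables is selected by leave-one-out PRESS, either at
the global minimum (default) or at the first local minimum of the curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model_selection import press

__all__ = ["NPLSModel", "npls_fit", "npls_predict", "select_lv_by_press"]


@dataclass
class NPLSModel:
    """Fitted tri-PLS1 model."""

    n_lv: int
    w_emission: np.ndarray  # J x F, unit-norm columns
    w_excitation: np.ndarray  # K x F, unit-norm columns
    coef_steps: list[np.ndarray]  # coef_steps[f]: regression coefs on scores 1..f+1
    mean_slab: np.ndarray  # J x K training mean
    y_mean: float
    scores: np.ndarray  # n x F training scores
    press_curve: np.ndarray | None = None
    lv_rule: str | None = None
    analyte: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": "npls",
                "analyte": self.analyte,
                "n_lv": self.n_lv,
                "w_emission": self.w_emission.tolist(),
                "w_excitation": self.w_excitation.tolist(),
                "coef_steps": [b.tolist() for b in self.coef_steps],
                "mean_slab": self.mean_slab.tolist(),
                "y_mean": self.y_mean,
                "press_curve": None if self.press_curve is None else self.press_curve.tolist(),
                "lv_rule": self.lv_rule,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "NPLSModel":
        d = json.loads(text)
        return cls(
            n_lv=d["n_lv"],
            w_emission=np.array(d["w_emission"], dtype=float),
            w_excitation=np.array(d["w_excitation"], dtype=float),
            coef_steps=[np.array(b, dtype=float) for b in d["coef_steps"]],
            mean_slab=np.array(d["mean_slab"], dtype=float),
            y_mean=d["y_mean"],
            scores=np.zeros((0, d["n_lv"])),
            press_curve=None if d["press_curve"] is None else np.array(d["press_curve"]),
            lv_rule=d.get("lv_rule"),
            analyte=d.get("analyte"),
        )


def npls_fit(cube, y, n_lv: int, analyte: str | None = None) -> NPLSModel:
    """Fit tri-PLS1 with ``n_lv`` latent variables.

    Degenerate data (zero centered cube or zero residual) truncates the
    factor count; a fully degenerate model predicts mean(y) everywhere.
    """
    X = np.asarray(cube, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 3 or X.shape[0] != y.size:
        raise ValueError("cube must be (samples, emission, excitation) matching y")
    n, J, K = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= n_lv <= n - 1:
        raise ValueError(f"n_lv must be in [1, n_samples-1] = [1, {n - 1}]")

    mean_slab = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - mean_slab
    yc = y - y_mean
    yr = yc.copy()
    eps = 1e-12 * max(1.0, float(np.abs(Xr).max()) * float(np.abs(yc).max() or 1.0))

    Wj, Wk, T = [], [], []
    coef_steps: list[np.ndarray] = []
    for _ in range(n_lv):
        Z = np.einsum("i,ijk->jk", yr, Xr)
        if np.linalg.norm(Z) <= eps:
            break
        U, _, Vt = np.linalg.svd(Z, full_matrices=False)
        wj = U[:, 0]
        wk = Vt[0]
        if wj[int(np.argmax(np.abs(wj)))] < 0:  # deterministic sign convention
            wj, wk = -wj, -wk
        t = np.einsum("ijk,j,k->i", Xr, wj, wk)
        Wj.append(wj)
        Wk.append(wk)
        T.append(t)
        Tm = np.column_stack(T)
        b, *_ = np.linalg.lstsq(Tm, yc, rcond=None)
        coef_steps.append(b)
        Xr = Xr - np.einsum("i,j,k->ijk", t, wj, wk)
        yr = yc - Tm @ b

    F = len(Wj)
    return NPLSModel(
        n_lv=F,
        w_emission=np.column_stack(Wj) if F else np.zeros((J, 0)),
        w_excitation=np.column_stack(Wk) if F else np.zeros((K, 0)),
        coef_steps=coef_steps,
        mean_slab=mean_slab,
        y_mean=y_mean,
        scores=np.column_stack(T) if F else np.zeros((n, 0)),
        analyte=analyte,
    )


def _scores(model: NPLSModel, cube: np.ndarray, n_lv: int) -> np.ndarray:
    Xr = cube - model.mean_slab
    out = np.empty((cube.shape[0], n_lv))
    for f in range(n_lv):
        wj = model.w_emission[:, f]
        wk = model.w_excitation[:, f]
        t = np.einsum("ijk,j,k->i", Xr, wj, wk)
        out[:, f] = t
        Xr = Xr - np.einsum("i,j,k->ijk", t, wj, wk)
    return out


def npls_predict(model: NPLSModel, cube, n_lv: int | None = None) -> np.ndarray:
    """Predict concentrations for new samples through the stored pipeline."""
    X = np.asarray(cube, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1:] != model.mean_slab.shape:
        raise ValueError("cube emission/excitation axes do not match the model")
    a = model.n_lv if n_lv is None else min(n_lv, model.n_lv)
    if a == 0:
        return np.full(X.shape[0], model.y_mean)
    T = _scores(model, X, a)
    return model.y_mean + T @ model.coef_steps[a - 1]


def select_lv_by_press(
    cube, y, max_lv: int = 8, rule: str = "global"
) -> tuple[int, np.ndarray]:
    """Choose the LV count by leave-one-out PRESS.

    ``rule="global"`` takes the curve minimum (ties to fewer LVs);
    ``rule="local"`` takes the first local minimum — the first count whose
    PRESS is below the next candidate's.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if rule not in ("global", "local"):
        raise ValueError("rule must be 'global' or 'local'")
    X = np.asarray(cube, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("PRESS selection needs at least 3 samples")
    a_max = min(max_lv, n - 2)  # each training fold has n-1 samples
    preds = np.empty((a_max, n))
    for i in range(n):
        keep = np.arange(n) != i
        model = npls_fit(X[keep], y[keep], a_max)
        for a in range(1, a_max + 1):
            preds[a - 1, i] = npls_predict(model, X[i : i + 1], n_lv=a)[0]
    curve = np.array([press(y, preds[a - 1]) for a in range(1, a_max + 1)])
    if rule == "global":
        n_lv = int(np.argmin(curve)) + 1
    else:
        n_lv = a_max
        for a in range(1, a_max):
            if curve[a - 1] < curve[a]:
                n_lv = a
                break
    return n_lv, curve
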