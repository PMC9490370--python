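"""Interval PLS: equal-width subintervals, local PLS1 models, RMSECV selection.

The emission-wavelength variables are partitioned into contiguous intervals
of near-equal width (the remainder widens the trailing intervals).  A local
PLS1 model is cross-validated on each interval for every candidate component
count; the (interval, components) pair with the minimum leave-one-out RMSECV
is kept, ties resolving to fewer components and then the lower interval
index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_selection import rmsecv

__all__ = [
    "IntervalScheme",
    "PLS1Model",
    "IPLSModel",
    "make_intervals",
    "pls1_fit",
    "pls1_predict",
    "ipls_select",
    "ipls_predict",
]


@dataclass
class IntervalScheme:
    """Contiguous, disjoint, exhaustive half-open index intervals."""

    n_variables: int
    n_intervals: int
    bounds: list[tuple[int, int]]

    def widths(self) -> list[int]:
        return [e - s for s, e in self.bounds]


def make_intervals(n_variables: int, n_intervals: int) -> IntervalScheme:
    """Partition ``n_variables`` into ``n_intervals`` of near-equal width.

    Base width is floor(n/k); the remainder r widens the last r intervals by
    one, so (41, 8) gives seven intervals of 5 and a final one of 6.
    """
    if not 1 <= n_intervals <= n_variables:
        raise ValueError("need 1 <= n_intervals <= n_variables")
    base, r = divmod(n_variables, n_intervals)
    sizes = [base] * (n_intervals - r) + [base + 1] * r
    bounds = []
    start = 0
    for w in sizes:
        bounds.append((start, start + w))
        start += w
    return IntervalScheme(n_variables, n_intervals, bounds)


@dataclass
class PLS1Model:
    """PLS1 (NIPALS) on centered data, with per-component coefficient history."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A
    loadings: np.ndarray  # p x A
    y_loadings: np.ndarray  # A
    coef_history: list[np.ndarray]  # coef_history[a-1]: regression vector with a comps
    n_components: int  # effective count (may be below the request on degenerate data)

    @property
    def coef(self) -> np.ndarray:
        if self.n_components == 0:
            return np.zeros_like(self.x_mean)
        return self.coef_history[self.n_components - 1]


def pls1_fit(X, y, n_components: int) -> PLS1Model:
    """NIPALS PLS1 on mean-centered X and y.

    Requires n_components <= min(n_samples - 1, n_variables).  Zero-variance
    y (or exhausted deflation) truncates to an intercept-only model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be samples x variables with one y per row")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, min(n_samples-1, n_variables)] = "
            f"[1, {min(n - 1, p)}]"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    W, P, Q = [], [], []
    history: list[np.ndarray] = []
    eps = 1e-12 * max(1.0, float(np.abs(Xr).max()), float(np.abs(yr).max()))
    for _ in range(n_components):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw <= eps:
            break
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt <= eps**2:
            break
        pvec = Xr.T @ t / tt
        q = float(yr @ t / tt)
        Xr = Xr - np.outer(t, pvec)
        yr = yr - q * t
        W.append(w)
        P.append(pvec)
        Q.append(q)
        Wm = np.column_stack(W)
        Pm = np.column_stack(P)
        history.append(Wm @ np.linalg.solve(Pm.T @ Wm, np.array(Q)))
    return PLS1Model(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=np.column_stack(W) if W else np.zeros((p, 0)),
        loadings=np.column_stack(P) if P else np.zeros((p, 0)),
        y_loadings=np.array(Q),
        coef_history=history,
        n_components=len(W),
    )


def pls1_predict(model: PLS1Model, X, n_components: int | None = None) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError("variable count does not match the fitted model")
    a = model.n_components if n_components is None else min(n_components, model.n_components)
    coef = model.coef_history[a - 1] if a >= 1 else np.zeros(model.x_mean.size)
    return model.y_mean + (X - model.x_mean) @ coef


@dataclass
class IPLSModel:
    """Selected interval + component count with the full RMSECV table."""

    scheme: IntervalScheme
    selected_interval: int
    n_components: int
    local: PLS1Model
    rmsecv_table: pd.DataFrame  # rows: interval index, cols: component count
    wavelength_range: tuple[float, float] | None = None
    analyte: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": "ipls",
                "analyte": self.analyte,
                "selected_interval": self.selected_interval,
                "n_components": self.n_components,
                "wavelength_range": self.wavelength_range,
                "bounds": self.scheme.bounds,
                "x_mean": self.local.x_mean.tolist(),
                "y_mean": self.local.y_mean,
                "coef": self.local.coef.tolist(),
            },
            sort_keys=True,
        )


def ipls_select(
    X,
    y,
    n_intervals: int = 8,
    max_components: int = 10,
    scheme: IntervalScheme | None = None,
    wavelengths=None,
    analyte: str | None = None,
) -> IPLSModel:
    """Exhaustive (interval, components) search by leave-one-out RMSECV.

    Component counts per interval run up to min(max_components, interval
    width, m - 2) so that every training fold retains a valid model.  The
    returned model is refitted on the full data at the winning pair.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m, p = X.shape
    if m < 3:
        raise ValueError("interval selection needs at least 3 samples")
    if scheme is None:
        scheme = make_intervals(p, n_intervals)
    elif scheme.n_variables != p:
        raise ValueError("scheme does not match the number of variables")

    a_cap_global = min(max_components, m - 2)
    table = np.full((scheme.n_intervals, a_cap_global), np.nan)
    for idx, (s, e) in enumerate(scheme.bounds):
        Xi = X[:, s:e]
        a_max = min(a_cap_global, e - s)
        preds = np.empty((a_max, m))
        for i in range(m):
            keep = np.arange(m) != i
            local = pls1_fit(Xi[keep], y[keep], a_max)
            for a in range(1, a_max + 1):
                preds[a - 1, i] = pls1_predict(local, Xi[i : i + 1], n_components=a)[0]
        for a in range(1, a_max + 1):
            table[idx, a - 1] = rmsecv(y, preds[a - 1])

    rmsecv_table = pd.DataFrame(
        table,
        index=pd.RangeIndex(scheme.n_intervals, name="interval"),
        columns=pd.Index(range(1, a_cap_global + 1), name="n_components"),
    )
    # argmin with ties -> fewer components, then lower interval index
    best = None
    for a in range(1, a_cap_global + 1):
        for idx in range(scheme.n_intervals):
            v = table[idx, a - 1]
            if np.isnan(v):
                continue
            if best is None or v < best[0]:
                best = (v, a, idx)
    if best is None:
        raise RuntimeError("every (interval, components) evaluation failed")
    _, a_best, idx_best = best
    s, e = scheme.bounds[idx_best]
    local = pls1_fit(X[:, s:e], y, a_best)
    wl_range = None
    if wavelengths is not None:
        wl = np.asarray(wavelengths, dtype=float)
        wl_range = (float(wl[s]), float(wl[e - 1]))
    return IPLSModel(
        scheme=scheme,
        selected_interval=idx_best,
        n_components=a_best,
        local=local,
        rmsecv_table=rmsecv_table,
        wavelength_range=wl_range,
        analyte=analyte,
    )


def ipls_predict(model: IPLSModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.scheme.n_variables:
        raise ValueError("variable count does not match the interval scheme")
    s, e = model.scheme.bounds[model.selected_interval]
    return pls1_predict(model.local, X[:, s:e])
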