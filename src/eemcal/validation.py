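"""Model-quality statistics, spike recovery, and the cross-method report.

Rc/Rp are Pearson correlations between actual and calculated concentrations
on the calibration and prediction sets; RMSEC/RMSEP use the same
m-denominator root-mean-square formula as RMSECV.  Spike recovery is
100 * (Con1 - Con0) / Cons: the fraction of a known added amount recovered
by the calibrated model on a spiked/unspiked sample pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationReport",
    "RecoveryResult",
    "correlation_r",
    "rmse",
    "recovery",
    "average_replicates",
    "evaluate_model",
    "compare_methods",
    "plot_actual_vs_predicted",
]


def correlation_r(actual, predicted) -> float:
    """Pearson product-moment correlation between actual and calculated values."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("correlation needs at least 2 samples")
    if a.std() == 0 or p.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(a, p)[0, 1])


def rmse(actual, predicted) -> float:
    """Root mean squared error with m in the denominator (RMSEC/RMSEP)."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.size != p.size:
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((a - p) ** 2)))


@dataclass
class RecoveryResult:
    """One spike-recovery measurement for one analyte/method pair."""

    sample_id: str
    analyte: str
    con0: float  # predicted concentration, unspiked (ug/ml)
    con1: float  # predicted concentration, spiked (ug/ml)
    cons: float  # spike amount (ug/ml)
    recovery_pct: float


def recovery(con1: float, con0: float, cons: float, sample_id: str = "", analyte: str = "") -> RecoveryResult:
    """recovery% = 100 * (Con1 - Con0) / Cons; out-of-range values kept as-is."""
    if cons <= 0:
        raise ValueError("spike amount must be > 0")
    return RecoveryResult(
        sample_id=sample_id,
        analyte=analyte,
        con0=float(con0),
        con1=float(con1),
        cons=float(cons),
        recovery_pct=float(100.0 * (con1 - con0) / cons),
    )


def average_replicates(groups, actual, predicted) -> tuple[np.ndarray, np.ndarray]:
    """Average actual and predicted values over replicate measurements.

    Replicates of one physical sample (identical group label) are averaged
    on the concentration scale before metrics are computed.
    """
    df = pd.DataFrame({"g": list(groups), "a": np.asarray(actual, float), "p": np.asarray(predicted, float)})
    agg = df.groupby("g", sort=False).mean()
    return agg["a"].to_numpy(), agg["p"].to_numpy()


@dataclass
class ValidationReport:
    """Rc/RMSEC/Rp/RMSEP with the underlying per-sample pairs."""

    analyte: str
    method: str
    rc: float
    rmsec: float
    rp: float | None
    rmsep: float | None
    cal_actual: np.ndarray
    cal_predicted: np.ndarray
    pred_actual: np.ndarray
    pred_predicted: np.ndarray
    flags: list[str] = field(default_factory=list)


def _default_predict(model, X) -> np.ndarray:
    from . import ipls as _ipls
    from . import lar as _lar
    from . import npls as _npls

    if isinstance(model, _lar.LARModel):
        return _lar.lar_predict(model, X)
    if isinstance(model, _ipls.IPLSModel):
        return _ipls.ipls_predict(model, X)
    if isinstance(model, _npls.NPLSModel):
        return _npls.npls_predict(model, X)
    if callable(getattr(model, "predict", None)):
        return np.asarray(model.predict(X)).ravel()
    raise TypeError(f"do not know how to predict with {type(model).__name__}")


def evaluate_model(
    model,
    cal: tuple,
    pred: tuple | None,
    analyte: str,
    method: str | None = None,
    predict_fn=None,
    cal_replicates=None,
    pred_replicates=None,
) -> ValidationReport:
    """Compute Rc/RMSEC on the calibration set and Rp/RMSEP on the prediction set.

    ``cal`` and ``pred`` are (representation, concentrations) pairs — contour
    matrices for LAR/iPLS, cubes for N-PLS.  An empty prediction set yields a
    calibration-only report carrying a flag.  Optional replicate labels
    average repeated measurements of one physical sample before metrics.
    """
    predict = predict_fn or _default_predict
    method = method or type(model).__name__.replace("Model", "").lower()
    X_cal, y_cal = cal
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    p_cal = np.asarray(predict(model, X_cal)).ravel()
    if cal_replicates is not None:
        y_cal, p_cal = average_replicates(cal_replicates, y_cal, p_cal)
    flags: list[str] = []
    rc = correlation_r(y_cal, p_cal)
    rmsec = rmse(y_cal, p_cal)
    if pred is None or len(np.asarray(pred[1]).ravel()) == 0:
        flags.append("no-prediction-set")
        y_pred = np.array([])
        p_pred = np.array([])
        rp = rmsep = None
    else:
        X_pred, y_pred = pred
        y_pred = np.asarray(y_pred, dtype=float).ravel()
        p_pred = np.asarray(predict(model, X_pred)).ravel()
        if pred_replicates is not None:
            y_pred, p_pred = average_replicates(pred_replicates, y_pred, p_pred)
        rp = correlation_r(y_pred, p_pred)
        rmsep = rmse(y_pred, p_pred)
    if (p_cal < 0).any() or (p_pred < 0).any():
        flags.append("negative-predictions")
    return ValidationReport(
        analyte=analyte,
        method=method,
        rc=rc,
        rmsec=rmsec,
        rp=rp,
        rmsep=rmsep,
        cal_actual=y_cal,
        cal_predicted=p_cal,
        pred_actual=y_pred,
        pred_predicted=p_pred,
        flags=flags,
    )


def compare_methods(
    reports: list[ValidationReport],
    recoveries: list[tuple[str, RecoveryResult]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format comparison tables.

    Returns (statistics, recoveries): statistics has one row per method x
    analyte x statistic (Rc, RMSEC, Rp, RMSEP); recoveries one row per
    (method, spiked sample, analyte).
    """
    if not reports:
        raise ValueError("need at least one report")
    stat_rows = []
    for r in reports:
        for name, value in (("Rc", r.rc), ("RMSEC", r.rmsec), ("Rp", r.rp), ("RMSEP", r.rmsep)):
            stat_rows.append(
                {"method": r.method, "analyte": r.analyte, "statistic": name, "value": value}
            )
    stats = pd.DataFrame(stat_rows, columns=["method", "analyte", "statistic", "value"])
    rec_rows = []
    for method, rec in recoveries or []:
        rec_rows.append(
            {
                "sample_id": rec.sample_id,
                "method": method,
                "analyte": rec.analyte,
                "spike_ug_ml": rec.cons,
                "con0": rec.con0,
                "con1": rec.con1,
                "recovery_pct": rec.recovery_pct,
            }
        )
    rec = pd.DataFrame(
        rec_rows,
        columns=["sample_id", "method", "analyte", "spike_ug_ml", "con0", "con1", "recovery_pct"],
    )
    return stats, rec


def plot_actual_vs_predicted(reports: list[ValidationReport], path) -> None:
    """Scatter plots of actual vs calculated concentrations per analyte/set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    analytes = sorted({r.analyte for r in reports})
    fig, axes = plt.subplots(len(analytes), 2, figsize=(9, 4 * len(analytes)), squeeze=False)
    for row, analyte in enumerate(analytes):
        for col, which in enumerate(("calibration", "prediction")):
            ax = axes[row][col]
            for r in reports:
                if r.analyte != analyte:
                    continue
                a, p = (
                    (r.cal_actual, r.cal_predicted)
                    if which == "calibration"
                    else (r.pred_actual, r.pred_predicted)
                )
                if len(a):
                    ax.plot(a, p, "o", label=r.method, alpha=0.7)
            lim = ax.get_xlim()
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_xlabel("actual (ug/ml)")
            ax.set_ylabel("calculated (ug/ml)")
            ax.set_title(f"{analyte} — {which}")
            ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
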