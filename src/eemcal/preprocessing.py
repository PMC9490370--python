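"""Scatter excision/infilling, contour extraction, and calibration splitting.

Rayleigh and Raman scatter carry no concentration information, so cells on
the scatter ridges are excised and refilled by interpolation consistent with
the surrounding landscape: a 1-D cubic-spline fit through the unmasked cells
of each emission column and of each excitation row, averaged where both are
available (constant extrapolation beyond the outermost anchors; linear fit
when fewer than four anchors exist).  The spline recovers band curvature
when an excision band crosses a spectral peak, where linear infilling
systematically truncates the band.  The physically non-fluorescent triangle
(emission below excitation, outside the scatter bands) is zeroed before
interpolation, which makes the operation idempotent.

Contour vectors — the emission spectrum at one fixed excitation wavelength —
are the reduced representation used by the lasso and interval-PLS models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .eem_io import EEMDataset, EEMLandscape, WavelengthGrid
from .synthetic_data import RAMAN_SHIFT_CM1, raman_emission

__all__ = [
    "ScatterMask",
    "ContourVector",
    "build_scatter_mask",
    "excise_and_interpolate",
    "extract_contour",
    "choose_max_energy_excitation",
    "extract_contours",
    "split_calibration",
]

_TOL = 1e-9  # widths are exact decimals in nm; tolerance only absorbs float repr


@dataclass
class ScatterMask:
    """Boolean excision mask with its per-ridge components.

    ``components`` holds the individual first-order Rayleigh, second-order
    Rayleigh, and Raman masks; ``mask`` is their union.  A ridge with width 0
    still masks the cells lying exactly on the ridge line.
    """

    grid: WavelengthGrid
    mask: np.ndarray
    components: dict[str, np.ndarray]
    widths: dict[str, float]

    def __post_init__(self) -> None:
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must match grid (emission x excitation)")


@dataclass
class ContourVector:
    """Emission-wavelength intensity vector at one fixed excitation."""

    values: np.ndarray
    excitation_used: float
    sample_id: str = "sample"


def build_scatter_mask(
    grid: WavelengthGrid,
    w1: float = 15.0,
    w2: float = 15.0,
    wR: float = 10.0,
    raman_shift_cm1: float = RAMAN_SHIFT_CM1,
) -> ScatterMask:
    """Mask cells within half-width w1 of the first-order Rayleigh ridge
    (lambda_em = lambda_ex), w2 of the second-order ridge (lambda_em =
    2*lambda_ex), and wR of the Raman line."""
    for name, w in (("w1", w1), ("w2", w2), ("wR", wR)):
        if w < 0:
            raise ValueError(f"{name} must be >= 0")
    em = grid.emission[:, None]
    ex = grid.excitation[None, :]
    first = np.abs(em - ex) <= w1 + _TOL
    second = np.abs(em - 2 * ex) <= w2 + _TOL
    raman = np.abs(em - raman_emission(ex, raman_shift_cm1)) <= wR + _TOL
    return ScatterMask(
        grid=grid,
        mask=first | second | raman,
        components={"first_order": first, "second_order": second, "raman": raman},
        widths={"w1": w1, "w2": w2, "wR": wR},
    )


def _interp_1d(x_good: np.ndarray, y_good: np.ndarray, x_bad: np.ndarray) -> np.ndarray:
    """Cubic-spline interpolation with constant extrapolation at the ends.

    Falls back to linear when fewer than four anchors exist; both variants
    reproduce affine data exactly.
    """
    if x_good.size >= 4:
        out = CubicSpline(x_good, y_good)(x_bad)
        out = np.where(x_bad < x_good[0], y_good[0], out)
        out = np.where(x_bad > x_good[-1], y_good[-1], out)
        return out
    return np.interp(x_bad, x_good, y_good)


def excise_and_interpolate(
    landscape: EEMLandscape, mask: ScatterMask, zero_below_diagonal: bool = True
) -> EEMLandscape:
    """Replace masked cells by spline interpolation from the unmasked cells.

    Each masked cell is refilled with the average of a 1-D interpolation
    along its emission column and along its excitation row (whichever of the
    two has anchors; zero fill with a warning if neither does).  With
    ``zero_below_diagonal`` the unmasked part of the non-fluorescent
    triangle (emission < excitation) is set to zero first, so interpolation
    anchors are identical on repeated application (idempotence).
    """
    if mask.grid != landscape.grid:
        raise ValueError("mask grid does not match landscape grid")
    em = landscape.grid.emission
    ex = landscape.grid.excitation
    M = mask.mask
    intensity = landscape.intensity.astype(float).copy()
    if zero_below_diagonal:
        triangle = (em[:, None] < ex[None, :]) & ~M
        intensity[triangle] = 0.0
    by_col = np.full(intensity.shape, np.nan)
    by_row = np.full(intensity.shape, np.nan)
    for k in range(ex.size):
        col_mask = M[:, k]
        if col_mask.any() and not col_mask.all():
            good = ~col_mask
            by_col[col_mask, k] = _interp_1d(em[good], intensity[good, k], em[col_mask])
    for j in range(em.size):
        row_mask = M[j, :]
        if row_mask.any() and not row_mask.all():
            good = ~row_mask
            by_row[j, row_mask] = _interp_1d(ex[good], intensity[j, good], ex[row_mask])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells handled below
        fill = np.nanmean(np.stack([by_col, by_row]), axis=0)
    orphan = M & np.isnan(fill)
    if orphan.any():
        warnings.warn(
            f"{int(orphan.sum())} masked cell(s) have no unmasked anchors in "
            "either direction; zero-filled",
            stacklevel=2,
        )
        fill[orphan] = 0.0
    intensity[M] = fill[M]
    return EEMLandscape(landscape.grid, intensity, landscape.sample_id)


def extract_contour(landscape: EEMLandscape, excitation_nm: float) -> ContourVector:
    """Emission vector at a fixed excitation wavelength (must lie on the grid)."""
    ex = landscape.grid.excitation
    hits = np.nonzero(np.isclose(ex, excitation_nm, rtol=0, atol=_TOL))[0]
    if hits.size == 0:
        raise ValueError(f"excitation {excitation_nm} nm is not on the grid")
    k = int(hits[0])
    return ContourVector(
        values=landscape.intensity[:, k].copy(),
        excitation_used=float(ex[k]),
        sample_id=landscape.sample_id,
    )


def choose_max_energy_excitation(landscapes) -> float:
    """Excitation column with the largest total intensity over the given samples."""
    landscapes = list(landscapes)
    if not landscapes:
        raise ValueError("need at least one landscape")
    grid = landscapes[0].grid
    total = np.zeros(grid.n_excitation)
    for ls in landscapes:
        if ls.grid != grid:
            raise ValueError("landscapes must share one grid")
        total += ls.intensity.sum(axis=0)
    return float(grid.excitation[int(np.argmax(total))])


def extract_contours(
    dataset: EEMDataset,
    policy: str | float = "max_energy",
    calibration_ids=None,
) -> tuple[pd.DataFrame, float]:
    """Contour table (samples x emission wavelengths) under one shared policy.

    ``policy`` is either an excitation wavelength in nm (fixed policy) or
    "max_energy", which picks the excitation with the largest summed
    intensity over ``calibration_ids`` only (all samples if omitted) so that
    held-out samples never influence the choice.  Every sample then uses the
    same excitation.
    """
    if isinstance(policy, str):
        if policy != "max_energy":
            raise ValueError(f"unknown contour policy {policy!r}")
        ids = list(calibration_ids) if calibration_ids is not None else dataset.sample_ids
        excitation = choose_max_energy_excitation(dataset.subset(ids).landscapes())
    else:
        excitation = float(policy)
    rows = [extract_contour(ls, excitation).values for ls in dataset.landscapes()]
    table = pd.DataFrame(
        np.vstack(rows),
        index=dataset.concentrations.index,
        columns=[f"{lam:g}" for lam in dataset.grid.emission],
    )
    return table, excitation


def split_calibration(
    dataset: EEMDataset, cal_fraction: float = 0.75, analyte: str | None = None
) -> tuple[EEMDataset, EEMDataset]:
    """Concentration-stratified deterministic split into calibration/prediction.

    The calibration size is round-half-up(cal_fraction * n), clamped to
    [1, n-1]; a three-quarter split of 21 samples therefore yields 16 + 5.
    Samples are ranked by the target analyte's concentration (first analyte
    column by default) and every ``n // n_pred``-th rank goes to the
    prediction set — rank-based systematic sampling, deterministic for a
    given dataset order.
    """
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must be in (0, 1)")
    n = dataset.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_cal = int(np.floor(cal_fraction * n + 0.5))
    n_cal = min(max(n_cal, 1), n - 1)
    n_pred = n - n_cal
    analyte = analyte or dataset.analytes[0]
    order = np.argsort(dataset.concentrations[analyte].to_numpy(), kind="stable")
    stride = n // n_pred
    pred_ranks = [i * stride - 1 for i in range(1, n_pred + 1)]
    pred_pos = sorted(int(order[r]) for r in pred_ranks)
    ids = dataset.sample_ids
    pred_ids = [ids[p] for p in pred_pos]
    cal_ids = [s for s in ids if s not in set(pred_ids)]
    return (
        dataset.subset(cal_ids, role="calibration"),
        dataset.subset(pred_ids, role="prediction"),
    )
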