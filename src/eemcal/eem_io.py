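"""Wavelength grids, EEM landscapes, and the three-way sample cube.

An excitation-emission matrix (EEM) records fluorescence intensity at every
(excitation, emission) wavelength pair for one sample.  A set of samples is
stacked into a three-way cube aligned with a concentration table; the cube is
stored sample-major, i.e. indexed (sample, emission, excitation).

On-disk format is a plain CSV dialect: cell (1,1) holds the literal ``em\\ex``,
the first row carries excitation wavelengths in nm, the first column emission
wavelengths in nm, and the body the intensities.  A separate concentration
manifest CSV carries ``sample_id``, ``role`` and one column per analyte in
ug/ml.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CORNER_LABEL = "em\\ex"

__all__ = [
    "FormatError",
    "GridMismatchError",
    "AlignmentError",
    "WavelengthGrid",
    "EEMLandscape",
    "EEMDataset",
    "read_eem_csv",
    "write_eem_csv",
    "read_concentration_manifest",
    "write_concentration_manifest",
    "assemble_cube",
]


class FormatError(ValueError):
    """Malformed EEM CSV (bad header, ragged rows, non-numeric cells)."""


class GridMismatchError(ValueError):
    """Landscapes with incompatible wavelength grids cannot be combined."""


class AlignmentError(ValueError):
    """Sample ids of landscapes and concentration table do not match."""


@dataclass(frozen=True, eq=False)
class WavelengthGrid:
    """Excitation and emission wavelength axes in nm.

    Both axes must be strictly increasing with constant spacing.  Grid
    equality is exact (no tolerance): two grids are equal iff every
    wavelength matches bit-for-bit.
    """

    excitation: np.ndarray
    emission: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitation, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        for name, axis in (("excitation", ex), ("emission", em)):
            if axis.ndim != 1 or axis.size < 2:
                raise ValueError(f"{name} axis must be a vector of >= 2 wavelengths")
            d = np.diff(axis)
            if np.any(d <= 0):
                raise ValueError(f"{name} axis must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
                raise ValueError(f"{name} axis must have constant spacing")
        object.__setattr__(self, "excitation", ex)
        object.__setattr__(self, "emission", em)

    @classmethod
    def default(cls, start: float = 200.0, stop: float = 600.0, step: float = 10.0) -> "WavelengthGrid":
        """The instrument grid: 200-600 nm in 10 nm steps, 41 points per axis."""
        axis = np.arange(start, stop + step / 2, step, dtype=float)
        return cls(excitation=axis, emission=axis.copy())

    @property
    def n_excitation(self) -> int:
        return self.excitation.size

    @property
    def n_emission(self) -> int:
        return self.emission.size

    @property
    def shape(self) -> tuple[int, int]:
        """(emission points, excitation points) — the landscape shape."""
        return (self.n_emission, self.n_excitation)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.excitation, other.excitation) and np.array_equal(
            self.emission, other.emission
        )

    def __hash__(self) -> int:
        return hash((self.excitation.tobytes(), self.emission.tobytes()))


@dataclass
class EEMLandscape:
    """One sample's EEM: intensity[j, k] at emission j, excitation k."""

    grid: WavelengthGrid
    intensity: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.grid.shape:
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grid "
                f"(emission x excitation) {self.grid.shape}"
            )

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.intensity).all())

    def copy(self) -> "EEMLandscape":
        return EEMLandscape(self.grid, self.intensity.copy(), self.sample_id)


@dataclass
class EEMDataset:
    """Three-way cube (sample, emission, excitation) + concentration table.

    ``concentrations`` is indexed by sample_id with one column per analyte
    (ug/ml); ``roles`` tags each sample as calibration / prediction / real /
    spiked.  ``spike_amounts`` (optional) records, for spiked/unspiked pairs,
    the amount added per analyte, indexed by the unspiked sample's id.
    """

    cube: np.ndarray
    grid: WavelengthGrid
    concentrations: pd.DataFrame
    roles: pd.Series
    spike_amounts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError("cube must be 3-way (sample, emission, excitation)")
        if self.cube.shape[1:] != self.grid.shape:
            raise ValueError("cube slab shape does not match grid")
        if self.cube.shape[0] != len(self.concentrations):
            raise ValueError("cube first dimension must equal the concentration table length")
        if (self.concentrations.to_numpy(dtype=float) < 0).any():
            raise ValueError("concentrations must be >= 0")
        self.roles = pd.Series(self.roles, index=self.concentrations.index, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.cube.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)

    def landscape(self, i: int | str) -> EEMLandscape:
        if isinstance(i, str):
            i = self.sample_ids.index(i)
        return EEMLandscape(self.grid, self.cube[i].copy(), self.sample_ids[i])

    def landscapes(self) -> list[EEMLandscape]:
        return [self.landscape(i) for i in range(self.n_samples)]

    def subset(self, ids: Sequence[str], role: str | None = None) -> "EEMDataset":
        ids = list(ids)
        pos = [self.sample_ids.index(s) for s in ids]
        roles = self.roles.loc[ids].copy()
        if role is not None:
            roles[:] = role
        return EEMDataset(
            cube=self.cube[pos].copy(),
            grid=self.grid,
            concentrations=self.concentrations.loc[ids].copy(),
            roles=roles,
            spike_amounts=self.spike_amounts,
        )

    def with_cube(self, cube: np.ndarray) -> "EEMDataset":
        return EEMDataset(cube, self.grid, self.concentrations.copy(), self.roles.copy(), self.spike_amounts)


def _parse_cell(text: str, row: int, col: int, path: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(
            f"{path}: non-numeric cell {text!r} at row {row + 1}, column {col + 1}"
        ) from exc


def read_eem_csv(path: str | os.PathLike) -> EEMLandscape:
    """Read one EEM landscape from the package CSV dialect."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or len(rows) < 2:
        raise FormatError(f"{path}: file has no data rows")
    header = rows[0]
    if not header or header[0].strip() != CORNER_LABEL:
        raise FormatError(f"{path}: first cell must be {CORNER_LABEL!r}, got {header[:1]!r}")
    if len(header) < 3:
        raise FormatError(f"{path}: header must list >= 2 excitation wavelengths")
    excitation = np.array([_parse_cell(c, 0, j + 1, str(path)) for j, c in enumerate(header[1:])])
    n_cols = len(header)
    emission = []
    body = []
    for r, row in enumerate(rows[1:], start=1):
        if len(row) != n_cols:
            raise FormatError(
                f"{path}: row {r + 1} has {len(row)} columns, expected {n_cols}"
            )
        emission.append(_parse_cell(row[0], r, 0, str(path)))
        body.append([_parse_cell(c, r, j + 1, str(path)) for j, c in enumerate(row[1:])])
    try:
        grid = WavelengthGrid(excitation=excitation, emission=np.array(emission))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed wavelength axes ({exc})") from exc
    return EEMLandscape(grid=grid, intensity=np.array(body), sample_id=path.stem)


def write_eem_csv(landscape: EEMLandscape, path: str | os.PathLike) -> None:
    """Write a landscape in the CSV dialect; values keep >= 12 significant digits."""
    path = Path(path)
    fmt = "{:.12g}".format
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([CORNER_LABEL] + [fmt(x) for x in landscape.grid.excitation])
        for j, lam in enumerate(landscape.grid.emission):
            w.writerow([fmt(lam)] + [fmt(x) for x in landscape.intensity[j]])


def read_concentration_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read the manifest CSV: sample_id, role, one column per analyte (ug/ml)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: manifest must have a sample_id column")
    df = df.set_index("sample_id")
    if "role" not in df.columns:
        df.insert(0, "role", "calibration")
    return df


def write_concentration_manifest(
    concentrations: pd.DataFrame, roles: pd.Series, path: str | os.PathLike
) -> None:
    out = concentrations.copy()
    out.insert(0, "role", roles.loc[out.index])
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.12g")


def assemble_cube(
    landscapes: Iterable[EEMLandscape], concentration_table: pd.DataFrame
) -> EEMDataset:
    """Stack landscapes into a cube aligned with the concentration table rows.

    The table must be indexed by sample_id (a ``sample_id`` column is also
    accepted); an optional ``role`` column sets per-sample roles, otherwise
    every sample defaults to "calibration".  Landscapes are reordered to the
    table's row order.
    """
    landscapes = list(landscapes)
    if not landscapes:
        raise ValueError("cannot assemble a cube from an empty landscape list")
    table = concentration_table.copy()
    if "sample_id" in table.columns:
        table = table.set_index("sample_id")
    by_id = {}
    for ls in landscapes:
        if ls.sample_id in by_id:
            raise AlignmentError(f"duplicate sample_id {ls.sample_id!r}")
        by_id[ls.sample_id] = ls
    missing = [s for s in table.index if s not in by_id]
    extra = [s for s in by_id if s not in set(table.index)]
    if missing or extra:
        raise AlignmentError(
            f"sample ids do not match: missing landscapes {missing}, "
            f"landscapes without table rows {extra}"
        )
    grid = landscapes[0].grid
    for ls in landscapes[1:]:
        if ls.grid != grid:
            raise GridMismatchError(
                f"landscape {ls.sample_id!r} has a different wavelength grid"
            )
    cube = np.stack([by_id[s].intensity for s in table.index])
    if "role" in table.columns:
        roles = table["role"].astype(object)
        conc = table.drop(columns=["role"])
    else:
        roles = pd.Series("calibration", index=table.index, dtype=object)
        conc = table
    return EEMDataset(cube=cube, grid=grid, concentrations=conc.astype(float), roles=roles)
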