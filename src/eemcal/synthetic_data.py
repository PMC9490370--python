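"""Synthetic EEM generator with the structure the calibration methods assume.

The generator produces trilinear fluorescence signals — each analyte
contributes ``concentration x sensitivity x (emission profile ⊗ excitation
profile)`` — plus first/second-order Rayleigh and Raman scatter ridges and
additive Gaussian noise.  The default design emulates a two-fluorophore
system with heavily overlapping spectra (emission-profile Pearson r >= 0.8),
concentration ranges 0.002-1.020 and 0.009-4.000 ug/ml sampled log-uniformly,
21 mixture samples, and optional spiked/unspiked pairs standing in for real
herbal-extract samples.

All randomness flows from the design seed; regenerating with the same design
is bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eem_io import EEMDataset, EEMLandscape, WavelengthGrid

__all__ = [
    "SpectralProfile",
    "AnalyteSpec",
    "ScatterSpec",
    "SimulationDesign",
    "SpikePlan",
    "make_gaussian_profile",
    "raman_emission",
    "scatter_field",
    "clean_signal",
    "simulate_eem",
    "generate_dataset",
    "default_design",
    "default_spike_plan",
]

#: Raman shift of the aqueous solvent band, in wavenumbers (cm^-1).
RAMAN_SHIFT_CM1 = 3400.0


@dataclass
class SpectralProfile:
    """Non-negative spectral profile on one grid axis, scaled to unit maximum."""

    axis: str  # "emission" | "excitation"
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in ("emission", "excitation"):
            raise ValueError("axis must be 'emission' or 'excitation'")
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("profile values must be >= 0")
        if not np.isclose(v.max(), 1.0, rtol=0, atol=1e-9):
            raise ValueError("profile must be scaled to unit maximum")
        self.values = v


@dataclass
class AnalyteSpec:
    """One fluorophore: its spectral profiles and sensitivity (intensity per ug/ml)."""

    name: str
    emission_profile: SpectralProfile
    excitation_profile: SpectralProfile
    sensitivity: float

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")


@dataclass
class ScatterSpec:
    """Amplitudes (intensity units) and Gaussian widths (nm) of the scatter ridges.

    The first-order Rayleigh ridge sits along lambda_em = lambda_ex, the
    second-order ridge along lambda_em = 2*lambda_ex, and the Raman ridge at a
    fixed wavenumber shift below the excitation line.
    """

    rayleigh1_amplitude: float
    rayleigh2_amplitude: float
    raman_amplitude: float
    rayleigh_width: float = 5.0
    raman_width: float = 5.0
    raman_shift_cm1: float = RAMAN_SHIFT_CM1


@dataclass
class SimulationDesign:
    """Everything needed to generate one synthetic EEM dataset."""

    grid: WavelengthGrid
    analytes: list[AnalyteSpec]
    concentration_ranges: dict[str, tuple[float, float]]
    n_samples: int = 21
    noise_sd: float = 0.01  # fraction of the per-sample max clean signal
    scatter: ScatterSpec | None = None
    interferent: AnalyteSpec | None = None
    interferent_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for a in self.analytes:
            lo, hi = self.concentration_ranges[a.name]
            if lo < 0 or hi <= lo:
                raise ValueError(f"invalid concentration range for {a.name}: ({lo}, {hi})")
        if self.interferent is not None and self.interferent_range is None:
            raise ValueError("interferent_range required when an interferent is present")


@dataclass
class SpikePlan:
    """Spiked/unspiked real-sample pairs: base ranges and per-pair spike amounts."""

    amounts: dict[str, Sequence[float]]  # analyte -> spike per pair (ug/ml)
    base_ranges: dict[str, tuple[float, float]]

    @property
    def n_pairs(self) -> int:
        return len(next(iter(self.amounts.values())))

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.amounts.values()}
        if len(lengths) != 1:
            raise ValueError("all analytes must list the same number of spike amounts")
        for name, amts in self.amounts.items():
            if any(a <= 0 for a in amts):
                raise ValueError(f"spike amounts must be > 0 ({name})")


def make_gaussian_profile(
    center_nm: float, width_nm: float, axis: str, grid: WavelengthGrid
) -> SpectralProfile:
    """Gaussian band exp(-(lambda-center)^2 / (2 width^2)), unit maximum."""
    if width_nm <= 0:
        raise ValueError("width_nm must be > 0")
    lam = grid.emission if axis == "emission" else grid.excitation
    v = np.exp(-((lam - center_nm) ** 2) / (2.0 * width_nm**2))
    return SpectralProfile(axis=axis, values=v / v.max())


def raman_emission(lambda_ex_nm: np.ndarray | float, shift_cm1: float = RAMAN_SHIFT_CM1):
    """Emission wavelength of the Raman line for a given excitation (nm)."""
    # 1/lambda_em = 1/lambda_ex - shift;  cm^-1 -> nm^-1 is a factor 1e-7
    return 1.0 / (1.0 / np.asarray(lambda_ex_nm, dtype=float) - shift_cm1 * 1e-7)


def scatter_field(grid: WavelengthGrid, scatter: ScatterSpec) -> np.ndarray:
    """Deterministic scatter contribution on the grid (emission x excitation)."""
    em = grid.emission[:, None]
    ex = grid.excitation[None, :]
    w = scatter.rayleigh_width
    out = scatter.rayleigh1_amplitude * np.exp(-((em - ex) ** 2) / (2 * w**2))
    out += scatter.rayleigh2_amplitude * np.exp(-((em - 2 * ex) ** 2) / (2 * w**2))
    lam_r = raman_emission(ex, scatter.raman_shift_cm1)
    out += scatter.raman_amplitude * np.exp(
        -((em - lam_r) ** 2) / (2 * scatter.raman_width**2)
    )
    return out


def _all_analytes(design: SimulationDesign) -> list[AnalyteSpec]:
    specs = list(design.analytes)
    if design.interferent is not None:
        specs.append(design.interferent)
    return specs


def clean_signal(concentrations: Mapping[str, float], design: SimulationDesign) -> np.ndarray:
    """Noise- and scatter-free trilinear signal for one sample."""
    out = np.zeros(design.grid.shape)
    for spec in _all_analytes(design):
        c = float(concentrations[spec.name])
        if c < 0:
            raise ValueError(f"negative concentration for {spec.name}")
        out += (
            c
            * spec.sensitivity
            * np.outer(spec.emission_profile.values, spec.excitation_profile.values)
        )
    return out


def simulate_eem(
    concentrations: Mapping[str, float],
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
) -> EEMLandscape:
    """Simulate one landscape: trilinear signal + scatter ridges + noise.

    Noise is i.i.d. Gaussian with sd = design.noise_sd times the max of the
    clean signal of this sample.  With ``rng=None`` a generator is derived
    from the design seed, so repeated calls with identical arguments return
    identical matrices.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    signal = clean_signal(concentrations, design)
    if design.scatter is not None:
        signal = signal + scatter_field(design.grid, design.scatter)
    if design.noise_sd > 0:
        sd = design.noise_sd * clean_signal(concentrations, design).max()
        if sd > 0:
            signal = signal + rng.normal(0.0, sd, size=signal.shape)
    return EEMLandscape(grid=design.grid, intensity=signal, sample_id=sample_id)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    if lo <= 0:
        raise ValueError("log-uniform sampling requires lo > 0")
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def generate_dataset(
    design: SimulationDesign, spike_plan: SpikePlan | None = None
) -> EEMDataset:
    """Generate a full dataset: mixture standards plus optional real/spiked pairs.

    Mixture-standard concentrations are drawn independently per analyte,
    log-uniform over the configured (lo, hi) — the calibration ranges span
    close to three orders of magnitude, so uniform sampling would starve the
    low end.  Roles default to "calibration"; spiked pairs are tagged
    "real" (base) and "spiked" (base + spike), with the spiked sample's id
    equal to the base id plus ``_spiked``.
    """
    rng = np.random.default_rng(design.seed)
    names = [a.name for a in _all_analytes(design)]
    n = design.n_samples

    conc = {}
    for spec in design.analytes:
        lo, hi = design.concentration_ranges[spec.name]
        conc[spec.name] = _log_uniform(rng, lo, hi, n)
    if design.interferent is not None:
        lo, hi = design.interferent_range  # type: ignore[misc]
        conc[design.interferent.name] = _log_uniform(rng, lo, hi, n)

    ids = [f"S{i + 1:02d}" for i in range(n)]
    roles = ["calibration"] * n
    rows = [dict(zip(names, (conc[a][i] for a in names))) for i in range(n)]

    spikes = None
    if spike_plan is not None:
        base = {
            a: _log_uniform(rng, *spike_plan.base_ranges[a], spike_plan.n_pairs)
            for a in spike_plan.amounts
        }
        spike_rows = []
        for p in range(spike_plan.n_pairs):
            base_row = {a: 0.0 for a in names}
            base_row.update({a: base[a][p] for a in spike_plan.amounts})
            if design.interferent is not None:
                lo, hi = design.interferent_range  # type: ignore[misc]
                base_row[design.interferent.name] = _log_uniform(rng, lo, hi, 1)[0]
            spiked_row = dict(base_row)
            for a, amts in spike_plan.amounts.items():
                spiked_row[a] = base_row[a] + amts[p]
            pid = f"R{p + 1}"
            ids += [pid, f"{pid}_spiked"]
            roles += ["real", "spiked"]
            rows += [base_row, spiked_row]
            spike_rows.append({a: spike_plan.amounts[a][p] for a in spike_plan.amounts})
        spikes = pd.DataFrame(spike_rows, index=[f"R{p + 1}" for p in range(spike_plan.n_pairs)])

    table = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))[names]
    cube = np.stack(
        [
            simulate_eem(row, design, rng=rng, sample_id=sid).intensity
            for sid, row in zip(ids, rows)
        ]
    )
    return EEMDataset(
        cube=cube,
        grid=design.grid,
        concentrations=table,
        roles=pd.Series(roles, index=table.index, dtype=object),
        spike_amounts=spikes,
    )


def default_design(
    seed: int = 0,
    n_samples: int = 21,
    noise_sd: float = 0.01,
    with_scatter: bool = True,
    grid: WavelengthGrid | None = None,
) -> SimulationDesign:
    """Two heavily overlapping coumarin-like fluorophores on the default grid.

    Aesculin-like band: emission 340/35 nm, excitation 300/30 nm, sensitivity
    1000 per ug/ml; aesculetin-like band: emission 360/40 nm, excitation
    310/35 nm, sensitivity 250 per ug/ml.  Scatter amplitudes default to 50%
    (first-order Rayleigh), 25% (second-order) and 5% (Raman) of the maximum
    single-analyte signal at the top of its calibration range.
    """
    grid = grid or WavelengthGrid.default()
    a = AnalyteSpec(
        name="aesculin",
        emission_profile=make_gaussian_profile(340, 35, "emission", grid),
        excitation_profile=make_gaussian_profile(300, 30, "excitation", grid),
        sensitivity=1000.0,
    )
    b = AnalyteSpec(
        name="aesculetin",
        emission_profile=make_gaussian_profile(360, 40, "emission", grid),
        excitation_profile=make_gaussian_profile(310, 35, "excitation", grid),
        sensitivity=250.0,
    )
    ranges = {"aesculin": (0.002, 1.020), "aesculetin": (0.009, 4.000)}
    scatter = None
    if with_scatter:
        ref = max(spec.sensitivity * ranges[spec.name][1] for spec in (a, b))
        scatter = ScatterSpec(
            rayleigh1_amplitude=0.5 * ref,
            rayleigh2_amplitude=0.25 * ref,
            raman_amplitude=0.05 * ref,
        )
    return SimulationDesign(
        grid=grid,
        analytes=[a, b],
        concentration_ranges=ranges,
        n_samples=n_samples,
        noise_sd=noise_sd,
        scatter=scatter,
        seed=seed,
    )


def default_spike_plan(design: SimulationDesign | None = None) -> SpikePlan:
    """Six real/spiked pairs with bench-scale spike amounts.

    Base (unspiked) levels are drawn log-uniform over (hi/40, hi/4) of each
    analyte's calibration range so that base + spike stays inside the
    calibrated range.
    """
    design = design or default_design()
    amounts = {
        "aesculin": (0.48, 0.50, 0.48, 0.48, 0.25, 0.40),
        "aesculetin": (2.00, 2.30, 2.00, 2.00, 1.00, 1.50),
    }
    amounts = {a: v for a, v in amounts.items() if a in design.concentration_ranges}
    base_ranges = {
        a: (design.concentration_ranges[a][1] / 40, design.concentration_ranges[a][1] / 4)
        for a in amounts
    }
    return SpikePlan(amounts=amounts, base_ranges=base_ranges)
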