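"""End-to-end orchestration: simulate -> preprocess -> fit -> validate -> report.

A single run is driven by a :class:`RunConfig` (constructible from YAML).
The global seed fans out to per-stage child seeds derived by hashing the
stage name, so adding a stage never perturbs earlier stages' randomness, and
rerunning an identical config reproduces byte-identical outputs.  All numeric
output is serialized at 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lar as _lar
from . import ipls as _ipls
from . import npls as _npls
from .eem_io import EEMDataset, write_concentration_manifest, write_eem_csv
from .preprocessing import build_scatter_mask, excise_and_interpolate, extract_contours, split_calibration
from .synthetic_data import default_design, default_spike_plan, generate_dataset
from .validation import ValidationReport, compare_methods, evaluate_model, recovery

log = logging.getLogger("eemcal")

FLOAT_FMT = "%.12g"

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


@dataclass
class RunConfig:
    """Parameters of one end-to-end run."""

    seed: int = 0
    # simulation
    n_samples: int = 21
    noise_sd: float = 0.01
    with_scatter: bool = True
    spiked_pairs: bool = True
    # preprocessing
    mask_w1: float = 15.0
    mask_w2: float = 15.0
    mask_wR: float = 10.0
    contour_policy: str | float = "max_energy"
    cal_fraction: float = 0.75
    # methods
    methods: tuple[str, ...] = ("lar", "ipls", "npls")
    lar_grid_size: int = 30
    ipls_n_intervals: int = 8
    ipls_max_components: int = 10
    npls_max_lv: int = 8
    npls_lv_rule: str = "global"
    # output
    outdir: str = "eemcal_run"
    log_level: str = "INFO"
    write_spectra: bool = True

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("method list must be non-empty")
        unknown = set(self.methods) - {"lar", "ipls", "npls"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        self.methods = tuple(self.methods)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    def science_dict(self) -> dict:
        """Config without output-location/logging fields: what the results depend on."""
        d = self.to_dict()
        for k in ("outdir", "log_level"):
            d.pop(k)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.science_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _write_df(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, float_format=FLOAT_FMT, index=index)


def preprocess_dataset(dataset: EEMDataset, config: RunConfig) -> EEMDataset:
    """Mask scatter ridges and infill every landscape in the dataset."""
    mask = build_scatter_mask(dataset.grid, config.mask_w1, config.mask_w2, config.mask_wR)
    cube = np.stack(
        [excise_and_interpolate(ls, mask).intensity for ls in dataset.landscapes()]
    )
    return dataset.with_cube(cube)


def _fit_one(method: str, analyte: str, config: RunConfig, contours_cal, y_cal, cube_cal):
    """Fit one method for one analyte; returns (model, diagnostics dict)."""
    if method == "lar":
        penalty, curve = _lar.select_penalty(
            contours_cal.to_numpy(), y_cal, grid_size=config.lar_grid_size
        )
        model = _lar.lar_fit(
            contours_cal.to_numpy(),
            y_cal,
            penalty,
            analyte=analyte,
            wavelengths=[float(c) for c in contours_cal.columns],
        )
        return model, {"penalty": penalty, "n_active": model.n_active, "curve": curve}
    if method == "ipls":
        model = _ipls.ipls_select(
            contours_cal.to_numpy(),
            y_cal,
            n_intervals=config.ipls_n_intervals,
            max_components=config.ipls_max_components,
            wavelengths=[float(c) for c in contours_cal.columns],
            analyte=analyte,
        )
        return model, {
            "selected_interval": model.selected_interval,
            "n_components": model.n_components,
            "wavelength_range": model.wavelength_range,
            "curve": model.rmsecv_table,
        }
    if method == "npls":
        max_lv = min(config.npls_max_lv, len(y_cal) - 2)
        n_lv, curve = _npls.select_lv_by_press(
            cube_cal, y_cal, max_lv=max_lv, rule=config.npls_lv_rule
        )
        model = _npls.npls_fit(cube_cal, y_cal, n_lv, analyte=analyte)
        model.press_curve = curve
        model.lv_rule = config.npls_lv_rule
        return model, {
            "n_lv": n_lv,
            "curve": pd.DataFrame({"n_lv": np.arange(1, len(curve) + 1), "press": curve}),
        }
    raise ValueError(f"unknown method {method!r}")


def _representation(method: str, contours: pd.DataFrame, dataset: EEMDataset, ids):
    if method == "npls":
        pos = [dataset.sample_ids.index(s) for s in ids]
        return dataset.cube[pos]
    return contours.loc[list(ids)].to_numpy()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts under config.outdir."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "init"
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        log.info("simulating dataset (seed=%d)", config.seed)
        design = default_design(
            seed=stage_seed(config.seed, "simulate"),
            n_samples=config.n_samples,
            noise_sd=config.noise_sd,
            with_scatter=config.with_scatter,
        )
        plan = default_spike_plan(design) if config.spiked_pairs else None
        dataset = generate_dataset(design, spike_plan=plan)
        if config.write_spectra:
            raw_dir = out / "raw"
            raw_dir.mkdir(exist_ok=True)
            for ls in dataset.landscapes():
                write_eem_csv(ls, raw_dir / f"{ls.sample_id}.csv")
            write_concentration_manifest(
                dataset.concentrations, dataset.roles, raw_dir / "manifest.csv"
            )

        # --- preprocess ---------------------------------------------------
        stage = "preprocess"
        log.info("masking scatter and infilling")
        processed = preprocess_dataset(dataset, config)
        std_ids = [s for s, r in processed.roles.items() if r == "calibration"]
        standards = processed.subset(std_ids)
        cal, pred = split_calibration(standards, config.cal_fraction)
        contours, excitation_used = extract_contours(
            processed, policy=config.contour_policy, calibration_ids=cal.sample_ids
        )
        if config.write_spectra:
            proc_dir = out / "processed"
            proc_dir.mkdir(exist_ok=True)
            for ls in processed.landscapes():
                write_eem_csv(ls, proc_dir / f"{ls.sample_id}.csv")
        _write_df(contours.rename_axis("sample_id"), out / "contours.csv")
        split = pd.Series("other", index=processed.concentrations.index, name="split")
        split.loc[cal.sample_ids] = "calibration"
        split.loc[pred.sample_ids] = "prediction"
        _write_df(split.rename_axis("sample_id").to_frame(), out / "split.csv")
        write_concentration_manifest(
            processed.concentrations, processed.roles, out / "manifest.csv"
        )

        # --- fit + validate ----------------------------------------------
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        reports: list[ValidationReport] = []
        recovery_rows = []
        real_ids = [s for s, r in processed.roles.items() if r == "real"]
        for analyte in processed.analytes:
            y_cal = cal.concentrations[analyte].to_numpy()
            y_pred = pred.concentrations[analyte].to_numpy()
            cube_cal = _representation("npls", contours, processed, cal.sample_ids)
            for method in config.methods:
                stage = f"fit:{method}:{analyte}"
                log.info("fitting %s for %s", method, analyte)
                model, diag = _fit_one(
                    method, analyte, config, contours.loc[cal.sample_ids], y_cal, cube_cal
                )
                (models_dir / f"{method}_{analyte}.json").write_text(model.to_json())
                curve = diag.pop("curve", None)
                if curve is not None:
                    _write_df(curve, models_dir / f"{method}_{analyte}_curve.csv")
                stage = f"validate:{method}:{analyte}"
                report = evaluate_model(
                    model,
                    cal=(_representation(method, contours, processed, cal.sample_ids), y_cal),
                    pred=(_representation(method, contours, processed, pred.sample_ids), y_pred),
                    analyte=analyte,
                    method=method,
                )
                reports.append(report)
                for rid in real_ids:
                    sid = f"{rid}_spiked"
                    amounts = processed.spike_amounts
                    if amounts is None or analyte not in amounts.columns:
                        continue
                    con0 = _predict_sample(model, method, contours, processed, rid)
                    con1 = _predict_sample(model, method, contours, processed, sid)
                    rec = recovery(
                        con1, con0, float(amounts.loc[rid, analyte]), sample_id=rid, analyte=analyte
                    )
                    recovery_rows.append((method, rec))

        # --- report -------------------------------------------------------
        stage = "report"
        stats, recs = compare_methods(reports, recovery_rows)
        _write_df(stats, out / "comparison.csv", index=False)
        _write_df(recs, out / "recoveries.csv", index=False)
        summary_lines = [
            f"eemcal run (config hash {config.config_hash()}, seed {config.seed})",
            f"samples: {config.n_samples} standards -> {cal.n_samples} calibration "
            f"+ {pred.n_samples} prediction; {len(real_ids)} real/spiked pairs",
            f"contour excitation: {excitation_used:g} nm",
            "",
            stats.to_string(index=False, float_format=lambda v: f"{v:.6g}"),
        ]
        if len(recs):
            summary_lines += ["", recs.to_string(index=False, float_format=lambda v: f"{v:.6g}")]
        (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
        manifest = {
            "config": config.science_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "contour_excitation_nm": excitation_used,
            "n_calibration": cal.n_samples,
            "n_prediction": pred.n_samples,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    except Exception as exc:
        (out / "error.txt").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {
        "outdir": str(out),
        "reports": reports,
        "recoveries": recovery_rows,
        "comparison": stats,
        "contour_excitation_nm": excitation_used,
        "calibration": cal,
        "prediction": pred,
    }


def _predict_sample(model, method: str, contours: pd.DataFrame, dataset: EEMDataset, sid: str) -> float:
    X = _representation(method, contours, dataset, [sid])
    if method == "lar":
        return float(_lar.lar_predict(model, X)[0])
    if method == "ipls":
        return float(_ipls.ipls_predict(model, X)[0])
    return float(_npls.npls_predict(model, X)[0])
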