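"""End-to-end orchestration: design -> simulate -> fit -> validate ->
diagnostics, with file output and a JSON run report."""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from chemcal import io
from chemcal.cls_model import fit_cls, moving_window_select, predict_cls
from chemcal.datasets import AbsorbanceMatrix, ConcentrationTable, WavelengthGrid
from chemcal.design import (
    FactorRange,
    ModelSpec,
    d_optimal_select,
    design_diagnostics,
    enumerate_candidates,
    generate_brereton_design,
)
from chemcal.diagnostics import ambiguity_bands, ejcr
from chemcal.fom import PredictionSet, fom_record
from chemcal.mcr import ConstraintSet, fit_mcr_als, mcr_quantify
from chemcal.pls_model import fit_pls, rmsecv_curve, select_lv
from chemcal.spectra import (
    NoiseModel,
    default_component_library,
    library_spectra,
    simulate_mixtures,
)
from chemcal.validation import CrossValidationPlan

DEFAULT_SEED = 20231201


@dataclass
class RunConfig:
    """Configuration of a full synthetic calibration run."""

    ranges: tuple = ((4.0, 20.0), (3.0, 15.0), (1.0, 5.0))
    analytes: tuple = ("CIN", "DOM", "BNZ")
    n_levels: int = 5
    grid_start: float = 220.0
    grid_end: float = 300.0
    grid_step: float = 1.0
    validation_size: int = 13
    design_model: str = "quadratic"
    design_starts: int = 20
    noise_sd: float = 0.003
    baseline_offset: float = 0.0
    seed: int = DEFAULT_SEED
    cls_intercept: bool = True
    cls_window_search: bool = False
    pls_max_lv: int = 10
    cv_scheme: str = "venetian"
    cv_splits: int = 5
    mcr_init: str = "efa"
    mcr_rel_tol: float = 0.20
    mcr_max_iter: int = 50
    mcr_reference_weight: float = 0.5  # 0 disables the correlation constraint
    alpha_levels: tuple = (0.05, 0.01)
    ambiguity_starts: int = 6
    run_ambiguity: bool = True
    out_dir: str | None = None

    @property
    def factors(self) -> list[FactorRange]:
        return [
            FactorRange(name, lo, hi, self.n_levels)
            for name, (lo, hi) in zip(self.analytes, self.ranges)
        ]

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.grid_start, self.grid_end, self.grid_step)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.ranges = tuple(tuple(r) for r in cfg.ranges)
        cfg.analytes = tuple(cfg.analytes)
        cfg.alpha_levels = tuple(cfg.alpha_levels)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class StageRecord:
    stage: str
    seconds: float
    ok: bool
    error: str | None = None


def run_end_to_end(config: RunConfig) -> dict:
    """Execute all stages in order and return the JSON-serialisable report.

    Identical config and seeds give identical reports (timings aside).
    A stage failure truncates the report with a structured error record.
    """
    report: dict = {"config": asdict(config), "stages": [], "models": {}}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    for name, fn in (
        ("design", _stage_design),
        ("simulate", _stage_simulate),
        ("fit", _stage_fit),
        ("validate", _stage_validate),
        ("diagnostics", _stage_diagnostics),
    ):
        t0 = time.perf_counter()
        try:
            fn(config, state, report, out)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            report["stages"].append(
                asdict(StageRecord(name, time.perf_counter() - t0, False,
                                   f"{type(exc).__name__}: {exc}"))
            )
            report["failed_stage"] = name
            break
        report["stages"].append(
            asdict(StageRecord(name, time.perf_counter() - t0, True))
        )
    if out:
        _strip = {k: v for k, v in report.items() if k != "stages"}
        io.write_json(_strip, out / "report.json")
    return report


def _stage_design(config, state, report, out):
    factors = config.factors
    coded, calib = generate_brereton_design(factors)
    candidates = enumerate_candidates(factors)
    spec = ModelSpec.from_name(config.design_model)
    result = d_optimal_select(
        candidates,
        config.validation_size,
        spec,
        n_starts=config.design_starts,
        seed=config.seed,
    )
    state["calib"] = ConcentrationTable(
        calib.matrix, [f.name for f in factors]
    )
    state["valid"] = ConcentrationTable(
        result.design.matrix, [f.name for f in factors]
    )
    report["design"] = {
        "n_calibration": calib.n_runs,
        "n_validation": int(len(result.indices)),
        "log10_det": result.log10_det,
        "diagnostics_calibration": _json_diag(design_diagnostics(calib)),
        "diagnostics_validation": _json_diag(design_diagnostics(result.design)),
    }
    if out:
        io.write_concentrations(state["calib"], out / "calibration_design.csv")
        io.write_concentrations(state["valid"], out / "validation_design.csv")


def _stage_simulate(config, state, report, out):
    grid = config.grid
    library = default_component_library(grid)
    noise = NoiseModel(sd=config.noise_sd,
                       baseline_offset=config.baseline_offset,
                       seed=config.seed + 1)
    stacked = ConcentrationTable(
        np.vstack([state["calib"].values, state["valid"].values]),
        list(config.analytes),
    )
    sim = simulate_mixtures(stacked, library, noise, grid)
    n_cal = state["calib"].n_samples
    state["sim"] = sim
    state["library"] = library
    state["S_true"] = library_spectra(library, grid)
    state["A_cal"] = AbsorbanceMatrix(sim.absorbance.values[:n_cal], grid)
    state["A_val"] = AbsorbanceMatrix(sim.absorbance.values[n_cal:], grid)
    report["simulate"] = {
        "grid_points": grid.n_points,
        "noise_sd": config.noise_sd,
        "seed": noise.seed,
    }
    if out:
        io.write_spectra(sim.absorbance, out / "spectra.csv")


def _stage_fit(config, state, report, out):
    cv = CrossValidationPlan(config.cv_scheme, config.cv_splits)
    A_cal, calib = state["A_cal"], state["calib"]

    if config.cls_window_search:
        _, cls_model, cls_curve = moving_window_select(
            A_cal, calib, cv=cv, intercept=config.cls_intercept
        )
    else:
        cls_model, cls_curve = fit_cls(
            A_cal, calib, intercept=config.cls_intercept
        ), None
    state["cls"] = cls_model

    curve = rmsecv_curve(A_cal, calib, range(1, config.pls_max_lv + 1), cv)
    n_lv = select_lv(curve)
    pls_model = fit_pls(A_cal, calib, n_lv)
    pls_model.rmsecv_curve = curve
    state["pls"] = pls_model

    D_aug = state["sim"].absorbance
    init = state["S_true"] if config.mcr_init == "reference" else config.mcr_init
    refs = {}
    if config.mcr_reference_weight > 0:
        refs = {
            j: (state["S_true"][j], config.mcr_reference_weight)
            for j in range(len(config.analytes))
        }
    mcr_model = fit_mcr_als(
        D_aug,
        n_components=len(config.analytes),
        init=init,
        constraints=ConstraintSet(
            nonneg_conc=True, nonneg_spec=True, reference_spectra=refs
        ),
        rel_tol=config.mcr_rel_tol,
        max_iter=config.mcr_max_iter,
        seed=config.seed,
    )
    state["mcr"] = mcr_model
    report["models"]["fit"] = {
        "cls": {"window_nm": cls_model.window_nm, "rmsecv_curve": cls_curve},
        "pls": {"n_lv": n_lv, "rmsecv_curve": curve},
        "mcr": {
            "iterations": mcr_model.iterations,
            "converged": mcr_model.converged,
            "explained_variance_pct": mcr_model.explained_variance,
            "lack_of_fit_pct": mcr_model.lack_of_fit,
        },
    }


def _model_predictions(config, state):
    """Predicted concentrations per model for calibration and validation."""
    A_cal, A_val = state["A_cal"], state["A_val"]
    calib = state["calib"]
    n_cal = calib.n_samples
    n_val = state["valid"].n_samples
    preds = {}
    preds["cls"] = (
        predict_cls(state["cls"], A_cal).values,
        predict_cls(state["cls"], A_val).values,
    )
    preds["pls"] = (
        state["pls"].predict(A_cal).values,
        state["pls"].predict(A_val).values,
    )
    rows = np.arange(n_cal + n_val)
    mcr_cal = mcr_quantify(
        state["mcr"], calib, rows[:n_cal], rows[:n_cal], state["S_true"]
    )
    mcr_val = mcr_quantify(
        state["mcr"], calib, rows[:n_cal], rows[n_cal:], state["S_true"]
    )
    preds["mcr"] = (mcr_cal.values, mcr_val.values)
    return preds


def _regression_vectors(state):
    """Per-analyte spectrum-to-concentration vectors used for NAS limits."""
    out = {}
    K = state["cls"].K
    out["cls"] = np.linalg.solve(K @ K.T, K)       # analytes x wavelengths
    out["pls"] = state["pls"].B.T
    # MCR: resolved-C projector scaled by the quantification slope
    mcr, calib = state["mcr"], state["calib"]
    S = mcr.S
    proj = np.linalg.solve(S @ S.T, S)             # components x wavelengths
    from chemcal.mcr import match_components

    assignment = match_components(S, state["S_true"])
    rows = []
    n_cal = calib.n_samples
    for a, comp in enumerate(assignment):
        slope = np.polyfit(mcr.C[:n_cal, comp], calib.values[:, a], 1)[0]
        rows.append(slope * proj[comp])
    out["mcr"] = np.vstack(rows)
    return out


def _stage_validate(config, state, report, out):
    preds = _model_predictions(config, state)
    b_vectors = _regression_vectors(state)
    state["preds"] = preds
    records = {}
    for model_name, (cal_pred, val_pred) in preds.items():
        records[model_name] = {}
        for j, analyte in enumerate(config.analytes):
            val_set = PredictionSet(
                state["valid"].values[:, j], val_pred[:, j], analyte
            )
            cal_set = PredictionSet(
                state["calib"].values[:, j], cal_pred[:, j], analyte,
                label="calibration",
            )
            rec = fom_record(
                analyte,
                val_set,
                calibration=cal_set,
                b_vector=b_vectors[model_name][j],
                noise_sd=config.noise_sd,
                alphas=config.alpha_levels,
            )
            records[model_name][analyte] = rec.to_dict()
    report["figures_of_merit"] = records


def _stage_diagnostics(config, state, report, out):
    diag = {"ejcr": {}}
    for model_name, (_, val_pred) in state["preds"].items():
        diag["ejcr"][model_name] = {}
        for j, analyte in enumerate(config.analytes):
            res = ejcr(
                PredictionSet(state["valid"].values[:, j], val_pred[:, j]),
                alpha=config.alpha_levels[0],
            )
            diag["ejcr"][model_name][analyte] = {
                "slope": res.slope,
                "intercept": res.intercept,
                "contains_ideal": res.contains_ideal,
                "area": res.area,
            }
    mcr = state["mcr"]
    diag["mcr_spectral_cosines"] = {
        name: _resolved_cosine(mcr, state["S_true"], j)
        for j, name in enumerate(config.analytes)
    }
    if config.run_ambiguity:
        amb = ambiguity_bands(
            mcr,
            grid=config.grid,
            n_starts=config.ambiguity_starts,
            seed=config.seed,
            method="optimize",
        )
        diag["ambiguity"] = {
            "mean_afs_pct": amb.mean_afs_pct,
            "sd_afs_pct": amb.sd_afs_pct,
            "components": [asdict(c) for c in amb.components],
        }
    report["diagnostics"] = diag


def _resolved_cosine(mcr, S_true, analyte_idx):
    from chemcal.diagnostics import cosine_similarity
    from chemcal.mcr import match_components

    assignment = match_components(mcr.S, S_true)
    return cosine_similarity(mcr.S[assignment[analyte_idx]], S_true[analyte_idx])


def _json_diag(diag: dict) -> dict:
    return {
        "correlations": {
            f"{a}|{b}": v for (a, b), v in diag["correlations"].items()
        },
        "level_counts": {
            k: {str(lv): c for lv, c in v.items()}
            for k, v in diag["level_counts"].items()
        },
        "coverage": diag["coverage"],
    }
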