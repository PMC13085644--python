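"""Classical least squares (K-matrix) calibration with optional intercept
and cross-validated moving-average window selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chemcal.datasets import AbsorbanceMatrix, ConcentrationTable, WavelengthGrid
from chemcal.exceptions import (
    AlignmentError,
    CollinearityError,
    ConfigurationError,
    DomainError,
)
from chemcal.validation import CrossValidationPlan


@dataclass
class CLSModel:
    """Direct calibration A ~ [1|C] [intercept; K] per wavelength."""

    K: np.ndarray                      # components x wavelengths
    intercept: np.ndarray | None       # wavelength vector, or None
    analytes: list[str]
    grid: WavelengthGrid
    window_nm: float | None = None     # smoothing window used at fit time
    residual_rms: float = 0.0

    @property
    def has_intercept(self) -> bool:
        return self.intercept is not None


def smooth_moving_average(values: np.ndarray, width_points: int) -> np.ndarray:
    """Moving-average smooth along the wavelength axis (edge-replicated)."""
    if width_points < 1 or width_points % 2 == 0:
        raise ConfigurationError("window width must be a positive odd point count")
    if width_points == 1:
        return np.asarray(values, float).copy()
    if width_points > values.shape[-1]:
        raise ConfigurationError("window wider than the spectrum")
    half = width_points // 2
    padded = np.pad(np.asarray(values, float), [(0, 0), (half, half)], mode="edge")
    kernel = np.ones(width_points) / width_points
    return np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), 1, padded
    )


def _design_matrix(C: np.ndarray, intercept: bool) -> np.ndarray:
    if intercept:
        return np.column_stack([np.ones(C.shape[0]), C])
    return C


def fit_cls(
    A: AbsorbanceMatrix,
    C: ConcentrationTable,
    intercept: bool = True,
    window_nm: float | None = None,
) -> CLSModel:
    """Least-squares K-matrix fit, one regression per wavelength."""
    if A.n_samples != C.n_samples:
        raise DomainError("absorbance and concentration sample counts differ")
    values = A.values
    if window_nm is not None:
        values = smooth_moving_average(
            values, _width_points(window_nm, A.grid.step)
        )
    X = _design_matrix(C.values, intercept)
    n, p = X.shape
    if n <= p:
        raise DomainError(
            f"need more than {p} samples to fit {p} coefficients"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending concentration columns for the caller
        bad = [
            C.analytes[j]
            for j in range(C.values.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j + int(intercept), axis=1))
            == rank
        ]
        raise CollinearityError(
            f"concentration matrix is rank-deficient (columns {bad})", bad
        )
    B, _, _, _ = np.linalg.lstsq(X, values, rcond=None)
    if intercept:
        icpt, K = B[0], B[1:]
    else:
        icpt, K = None, B
    resid = values - X @ B
    return CLSModel(
        K=K,
        intercept=icpt,
        analytes=list(C.analytes),
        grid=A.grid,
        window_nm=window_nm,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def predict_cls(model: CLSModel, A: AbsorbanceMatrix) -> ConcentrationTable:
    """Project unknown spectra onto the K rows by least squares."""
    if A.grid != model.grid:
        raise AlignmentError("wavelength grid does not match the training grid")
    values = A.values
    if model.window_nm is not None:
        values = smooth_moving_average(
            values, _width_points(model.window_nm, model.grid.step)
        )
    if model.has_intercept:
        values = values - model.intercept
    # solve K' c = a per sample
    conc, _, _, _ = np.linalg.lstsq(model.K.T, values.T, rcond=None)
    if not np.all(np.isfinite(conc)):
        raise DomainError("non-finite predictions")
    return ConcentrationTable(
        conc.T, list(model.analytes), list(A.sample_ids)
    )


def _width_points(width_nm: float, step_nm: float) -> int:
    pts = width_nm / step_nm
    rounded = int(round(pts))
    if abs(pts - rounded) > 1e-9 or rounded % 2 == 0:
        raise ConfigurationError(
            f"window of {width_nm} nm is not an odd number of {step_nm} nm points"
        )
    return rounded


def moving_window_select(
    A: AbsorbanceMatrix,
    C: ConcentrationTable,
    widths_nm=None,
    cv: CrossValidationPlan | None = None,
    intercept: bool = True,
) -> tuple[float, CLSModel, dict]:
    """Pick the moving-average width (5-30 nm by default) minimising the
    pooled cross-validated RMSE; ties go to the smaller width."""
    cv = cv or CrossValidationPlan()
    if widths_nm is None:
        step = A.grid.step
        widths_nm = [w * step for w in range(5, 31, 2) if w * step <= 30]
    curve = {}
    for w in widths_nm:
        _width_points(w, A.grid.step)  # validate early
        errors = []
        for train, test in cv.splits(A.n_samples):
            sub_A = AbsorbanceMatrix(A.values[train], A.grid)
            sub_C = ConcentrationTable(C.values[train], list(C.analytes))
            model = fit_cls(sub_A, sub_C, intercept=intercept, window_nm=w)
            pred = predict_cls(
                model, AbsorbanceMatrix(A.values[test], A.grid)
            )
            errors.append((pred.values - C.values[test]).ravel())
        curve[w] = float(np.sqrt(np.mean(np.concatenate(errors) ** 2)))
    best = min(curve, key=lambda w: (round(curve[w], 12), w))
    model = fit_cls(A, C, intercept=intercept, window_nm=best)
    return best, model, curve
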