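"""Inverse calibration by NIPALS partial least squares (PLS2) with
cross-validated latent-variable selection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from chemcal.datasets import AbsorbanceMatrix, ConcentrationTable
from chemcal.exceptions import AlignmentError, DomainError
from chemcal.validation import CrossValidationPlan


@dataclass
class PLSModel:
    n_lv: int
    B: np.ndarray                 # wavelengths x analytes regression matrix
    intercept: np.ndarray         # per-analyte intercept
    x_mean: np.ndarray
    y_mean: np.ndarray
    scores: np.ndarray            # samples x n_lv
    loadings: np.ndarray          # wavelengths x n_lv
    weights: np.ndarray           # wavelengths x n_lv
    y_loadings: np.ndarray        # analytes x n_lv
    analytes: list[str] = field(default_factory=list)
    rmsecv_curve: dict | None = None

    def predict(self, A: AbsorbanceMatrix) -> ConcentrationTable:
        if A.values.shape[1] != self.B.shape[0]:
            raise AlignmentError("wavelength count does not match model")
        pred = (A.values - self.x_mean) @ self.B + self.y_mean
        return ConcentrationTable(pred, list(self.analytes), list(A.sample_ids))


def _nipals(X, Y, n_lv, tol=1e-12, max_iter=1000):
    """Deterministic NIPALS PLS2 on centred data.

    The score iteration starts from the response column with the largest
    variance, so repeated fits are bit-identical.
    """
    n, m = X.shape
    T = np.zeros((n, n_lv))
    P = np.zeros((m, n_lv))
    W = np.zeros((m, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    Xr, Yr = X.copy(), Y.copy()
    for a in range(n_lv):
        u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
        if np.allclose(u, 0):
            u = Yr.sum(axis=1)
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = Xr.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise DomainError("degenerate spectral data (zero variance)")
            w /= nw
            t = Xr @ w
            q = Yr.T @ t / (t @ t)
            nq = np.linalg.norm(q)
            if nq == 0:
                break
            u = Yr @ q / (q @ q)
            if np.linalg.norm(t - t_old) < tol * max(1.0, np.linalg.norm(t)):
                break
            t_old = t
        p = Xr.T @ t / (t @ t)
        Xr = Xr - np.outer(t, p)
        Yr = Yr - np.outer(t, q)
        T[:, a], P[:, a], W[:, a], Q[:, a] = t, p, w, q
    return T, P, W, Q


def fit_pls(
    A: AbsorbanceMatrix, C: ConcentrationTable, n_lv: int
) -> PLSModel:
    """Mean-centred NIPALS PLS2 fit with ``n_lv`` latent variables."""
    X, Y = A.values, C.values
    if X.shape[0] != Y.shape[0]:
        raise DomainError("sample counts differ")
    max_lv = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_lv <= max_lv:
        raise DomainError(f"n_lv must be in [1, {max_lv}]")
    if np.allclose(X.std(axis=0), 0):
        raise DomainError("degenerate spectral data (zero variance)")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    T, P, W, Q = _nipals(X - x_mean, Y - y_mean, n_lv)
    # B = W (P'W)^-1 Q' maps centred spectra to centred concentrations
    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSModel(
        n_lv=n_lv,
        B=B,
        intercept=y_mean - x_mean @ B,
        x_mean=x_mean,
        y_mean=y_mean,
        scores=T,
        loadings=P,
        weights=W,
        y_loadings=Q,
        analytes=list(C.analytes),
    )


def rmsecv_curve(
    A: AbsorbanceMatrix,
    C: ConcentrationTable,
    lv_range=range(1, 11),
    cv: CrossValidationPlan | None = None,
) -> dict[int, float]:
    """Pooled cross-validated RMSE per latent-variable count.

    Folds too small for the requested count are capped at their own
    maximum; the cap is recorded in the returned curve keys unchanged.
    """
    cv = cv or CrossValidationPlan()
    lv_range = list(lv_range)
    if not lv_range:
        raise DomainError("empty LV range")
    sq_errors = {k: [] for k in lv_range}
    for train, test in cv.splits(A.n_samples):
        fold_cap = min(len(train) - 1, A.values.shape[1])
        sub_A = AbsorbanceMatrix(A.values[train], A.grid)
        sub_C = ConcentrationTable(C.values[train], list(C.analytes))
        for k in lv_range:
            model = fit_pls(sub_A, sub_C, min(k, fold_cap))
            pred = model.predict(AbsorbanceMatrix(A.values[test], A.grid))
            sq_errors[k].append(((pred.values - C.values[test]) ** 2).ravel())
    return {
        k: float(np.sqrt(np.mean(np.concatenate(v)))) for k, v in sq_errors.items()
    }


def select_lv(
    curve: dict[int, float],
    rule: str = "global-min",
    alpha: float = 0.25,
    n_samples: int | None = None,
) -> int:
    """Pick the latent-variable count from an RMSECV curve.

    ``global-min`` takes the argmin (ties resolved toward fewer LVs);
    ``parsimonious-F`` takes the smallest count whose PRESS ratio to the
    minimum is not significant at the given F quantile.
    """
    if not curve:
        raise DomainError("empty RMSECV curve")
    ks = sorted(curve)
    if rule == "global-min":
        return min(ks, key=lambda k: (round(curve[k], 12), k))
    if rule == "parsimonious-F":
        if n_samples is None:
            raise DomainError("parsimonious-F needs n_samples")
        best = min(curve.values())
        f_crit = stats.f.ppf(1 - alpha, n_samples, n_samples)
        for k in ks:
            if best == 0:
                if curve[k] == 0:
                    return k
                continue
            if (curve[k] / best) ** 2 <= f_crit:
                return k
        return ks[-1]
    raise DomainError(f"unknown selection rule {rule!r}")
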