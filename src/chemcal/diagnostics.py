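"""Model-quality diagnostics: elliptical joint confidence region,
cosine similarity, rotational-ambiguity feasible bands and local rank."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from chemcal.datasets import AbsorbanceMatrix, WavelengthGrid
from chemcal.exceptions import ConfigurationError, DomainError
from chemcal.fom import PredictionSet
from chemcal.mcr import ConstraintSet, MCRModel


@dataclass
class EjcrResult:
    """Joint confidence ellipse for (intercept, slope) of predicted vs true."""

    intercept: float
    slope: float
    shape_matrix: np.ndarray      # X'X of the regression, 2x2
    radius: float                 # 2 s^2 F(2, n-2, 1-alpha)
    alpha: float
    contains_ideal: bool
    area: float
    boundary: np.ndarray          # m x 2 points (intercept, slope)


def ejcr(p: PredictionSet, alpha: float = 0.05, n_boundary: int = 200) -> EjcrResult:
    """F-based elliptical joint confidence region of the OLS line fitted
    through (true, predicted) pairs.

    The region is {beta : (beta - beta_hat)' X'X (beta - beta_hat)
    <= 2 s^2 F(2, n-2, 1-alpha)} with X = [1, E]; the method is judged
    unbiased when (intercept, slope) = (0, 1) lies inside.
    """
    if p.n < 4:
        raise DomainError("EJCR needs at least 4 samples")
    if np.ptp(p.true) == 0:
        raise DomainError("constant truth")
    X = np.column_stack([np.ones(p.n), p.true])
    beta, res, _, _ = np.linalg.lstsq(X, p.predicted, rcond=None)
    rss = float(np.sum((p.predicted - X @ beta) ** 2))
    s2 = rss / (p.n - 2)
    M = X.T @ X
    radius = 2.0 * s2 * stats.f.ppf(1 - alpha, 2, p.n - 2)
    ideal = np.array([0.0, 1.0])
    q = float((ideal - beta) @ M @ (ideal - beta))
    contains = q <= radius + 1e-12
    area = float(np.pi * radius / np.sqrt(np.linalg.det(M)))
    if radius > 0:
        L = np.linalg.cholesky(M)
        theta = np.linspace(0, 2 * np.pi, n_boundary, endpoint=False)
        circle = np.vstack([np.cos(theta), np.sin(theta)])
        boundary = (
            beta[:, None] + np.sqrt(radius) * np.linalg.solve(L.T, circle)
        ).T
    else:
        boundary = np.tile(beta, (n_boundary, 1))
    return EjcrResult(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        shape_matrix=M,
        radius=float(radius),
        alpha=alpha,
        contains_ideal=bool(contains),
        area=area,
        boundary=boundary,
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(theta) = (a . b) / (||a|| ||b||), in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DomainError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


@dataclass
class ComponentAmbiguity:
    component: int
    f_min: float
    f_max: float
    afs_pct: float
    max_rfs: float
    avg_rfs: float
    critical_wavelength: float
    selectivity_index: float
    resolved: bool = True


@dataclass
class AmbiguityResult:
    components: list[ComponentAmbiguity]
    mean_afs_pct: float
    sd_afs_pct: float
    details: dict = field(default_factory=dict)


def _normalise_profiles(C: np.ndarray, S: np.ndarray):
    norms = np.linalg.norm(S, axis=1)
    if np.any(norms == 0):
        raise DomainError("zero spectral profile")
    return C * norms, S / norms[:, None]


def _rotate(C, S, T):
    Tinv = np.linalg.inv(T)
    return C @ T, Tinv @ S


def _feasibility_penalty(Cr, Sr, constraints: ConstraintSet, refs=None):
    pen = 0.0
    if constraints.nonneg_conc:
        pen += float(np.sum(np.minimum(Cr, 0.0) ** 2))
    if constraints.nonneg_spec:
        pen += float(np.sum(np.minimum(Sr, 0.0) ** 2))
    for j, (ref, min_cos) in (refs or {}).items():
        nrm = np.linalg.norm(Sr[j])
        if nrm == 0:
            pen += 1.0
            continue
        c = float(ref @ Sr[j] / (np.linalg.norm(ref) * nrm))
        pen += max(0.0, min_cos - c) ** 2
    return pen


def _signal_fraction(Cr, Sr, comp, total):
    return float(
        np.linalg.norm(Cr[:, comp]) * np.linalg.norm(Sr[comp]) / total
    )


def _off_diagonal_T(x, k):
    T = np.eye(k)
    T[~np.eye(k, dtype=bool)] = x
    return T


def ambiguity_bands(
    model: MCRModel,
    constraints: ConstraintSet | None = None,
    grid: WavelengthGrid | None = None,
    reference_constraints: dict | None = None,
    n_starts: int = 20,
    seed: int = 0,
    method: str = "auto",
    grid_points: int = 100,
    grid_span: float = 1.5,
    grid_refine: int = 3,
    penalty_tol: float = 1e-9,
) -> AmbiguityResult:
    """Feasible-band extrema of the per-component signal contribution.

    For each component c the relative contribution
    f_c(T) = ||(C T)_c|| ||(T^-1 S)_c|| / ||C S||_F is minimised and
    maximised over invertible transforms T (diagonal fixed at 1) whose
    rotated profiles satisfy the active constraints.  ``method`` is
    "optimize" (penalised multi-start Nelder-Mead/SLSQP), "grid"
    (dense search, k <= 2 only) or "auto".

    ``reference_constraints`` maps component -> (reference spectrum,
    minimum cosine) correlation constraints.
    """
    constraints = constraints or model.constraints
    grid = grid or WavelengthGrid()
    C, S = _normalise_profiles(model.C.copy(), model.S.copy())
    k = S.shape[0]
    total = float(np.linalg.norm(C @ S))
    refs = reference_constraints or {}

    if method == "auto":
        method = "grid" if k <= 2 else "optimize"
    if method == "grid" and k > 2:
        raise ConfigurationError("grid search supported for k <= 2 only")

    if k == 1:
        # only scaling ambiguity remains; normalisation removes it
        comp = ComponentAmbiguity(0, 1.0, 1.0, 0.0, 0.0, 0.0,
                                  float(grid.values[0]), 1.0)
        return AmbiguityResult([comp], 0.0, 0.0)

    if method == "grid":
        extrema, spectra_sets = _grid_band_search(
            C, S, constraints, refs, total, grid_points, grid_span, penalty_tol,
            refine=grid_refine,
        )
    else:
        extrema, spectra_sets = _optimize_band_search(
            C, S, constraints, refs, total, n_starts, seed, penalty_tol
        )

    comps = []
    afs = []
    lam = grid.values
    for c in range(k):
        f_min, f_max, resolved = extrema[c]
        spectra = np.array(spectra_sets[c])
        widths = spectra.max(axis=0) - spectra.min(axis=0)
        crit = float(lam[int(np.argmax(widths))]) if len(lam) == len(widths) else np.nan
        a = 100.0 * (f_max - f_min)
        afs.append(a)
        sel = 1.0 - (f_max - f_min) / f_max if f_max > 0 else 0.0
        comps.append(
            ComponentAmbiguity(
                component=c,
                f_min=f_min,
                f_max=f_max,
                afs_pct=a,
                max_rfs=float(widths.max()),
                avg_rfs=float(widths.mean()),
                critical_wavelength=crit,
                selectivity_index=float(np.clip(sel, 0.0, 1.0)),
                resolved=resolved,
            )
        )
    afs = np.asarray(afs)
    return AmbiguityResult(
        comps, float(afs.mean()), float(afs.std(ddof=1)) if k > 1 else 0.0
    )


def _grid_band_search(C, S, constraints, refs, total, n_pts, span, tol,
                      refine=0):
    """Dense search over T = [[1, a], [b, 1]] for two-component systems.

    ``refine`` extra passes re-grid around each extremal point with a
    shrunken span, sharpening boundary extrema without an O(n^2) blowup.
    """
    f_id = [_signal_fraction(C, S, c, total) for c in range(2)]
    best = {c: [f_id[c], f_id[c]] for c in range(2)}
    arg = {c: [S[c].copy(), S[c].copy()] for c in range(2)}
    at = {c: [(0.0, 0.0), (0.0, 0.0)] for c in range(2)}

    def sweep(a_grid, b_grid):
        for a, b in itertools.product(a_grid, b_grid):
            if abs(1.0 - a * b) < 1e-9:
                continue
            T = np.array([[1.0, a], [b, 1.0]])
            Cr, Sr = _rotate(C, S, T)
            if _feasibility_penalty(Cr, Sr, constraints, refs) > tol:
                continue
            for c in range(2):
                f = _signal_fraction(Cr, Sr, c, total)
                sc = Sr[c] / np.linalg.norm(Sr[c])
                if f < best[c][0]:
                    best[c][0], arg[c][0], at[c][0] = f, sc, (a, b)
                if f > best[c][1]:
                    best[c][1], arg[c][1], at[c][1] = f, sc, (a, b)

    sweep(np.linspace(-span, span, n_pts), np.linspace(-span, span, n_pts))
    width = 2.0 * span / (n_pts - 1)
    for _ in range(refine):
        points = {p for c in range(2) for p in at[c]}
        for a0, b0 in points:
            sweep(
                np.linspace(a0 - 2 * width, a0 + 2 * width, n_pts),
                np.linspace(b0 - 2 * width, b0 + 2 * width, n_pts),
            )
        width = 4.0 * width / (n_pts - 1)

    extrema, spectra_sets = {}, {0: [S[0]], 1: [S[1]]}
    for c in range(2):
        extrema[c] = (best[c][0], best[c][1], True)
        spectra_sets[c].extend(arg[c])
    return extrema, spectra_sets


def _optimize_band_search(C, S, constraints, refs, total, n_starts, seed, tol):
    k = S.shape[0]
    n_free = k * k - k
    rng = np.random.default_rng(seed)
    penalty_weight = 1e6

    def objective(x, comp, sign):
        T = _off_diagonal_T(x, k)
        if abs(np.linalg.det(T)) < 1e-9:
            return 1e9
        Cr, Sr = _rotate(C, S, T)
        pen = _feasibility_penalty(Cr, Sr, constraints, refs)
        return sign * _signal_fraction(Cr, Sr, comp, total) + penalty_weight * pen

    extrema, spectra_sets = {}, {}
    for comp in range(k):
        found = {1: [], -1: []}
        spectra_sets[comp] = [S[comp].copy()]
        for sign in (1, -1):
            starts = [np.zeros(n_free)]
            starts += [rng.normal(0, 0.3, n_free) for _ in range(n_starts - 1)]
            for x0 in starts:
                res = optimize.minimize(
                    objective, x0, args=(comp, sign), method="Nelder-Mead",
                    options={"maxiter": 400 * n_free, "xatol": 1e-8,
                             "fatol": 1e-10},
                )
                T = _off_diagonal_T(res.x, k)
                if abs(np.linalg.det(T)) < 1e-9:
                    continue
                Cr, Sr = _rotate(C, S, T)
                if _feasibility_penalty(Cr, Sr, constraints, refs) > max(tol, 1e-8):
                    continue
                f = _signal_fraction(Cr, Sr, comp, total)
                found[sign].append(f)
                spectra_sets[comp].append(Sr[comp] / np.linalg.norm(Sr[comp]))
        f_id = _signal_fraction(C, S, comp, total)
        resolved = bool(found[1] or found[-1])
        f_min = min(found[1] + [f_id])
        f_max = max(found[-1] + [f_id])
        extrema[comp] = (f_min, f_max, resolved)
    return extrema, spectra_sets


def local_rank_map(
    D: AbsorbanceMatrix,
    window_nm: float,
    log10_threshold: float = -4.0,
) -> dict:
    """Sliding-window effective rank along the wavelength axis.

    Each window's eigenvalues are normalised to the global largest and
    thresholded with the same log10 convention as EFA.
    """
    step = D.grid.step
    w_pts = int(round(window_nm / step))
    if w_pts < 3:
        raise DomainError("window must span at least 3 grid points")
    n_wl = D.values.shape[1]
    if w_pts > n_wl:
        raise ConfigurationError("window exceeds the spectral grid")
    top = np.linalg.svd(D.values, compute_uv=False)[0] ** 2
    if top == 0:
        raise DomainError("all-zero data")
    centers, ranks = [], []
    lam = D.grid.values
    for start in range(n_wl - w_pts + 1):
        sub = D.values[:, start : start + w_pts]
        sv = np.linalg.svd(sub, compute_uv=False)
        with np.errstate(divide="ignore"):
            logs = np.log10(sv**2 / top)
        ranks.append(int(np.sum(logs > log10_threshold)))
        centers.append(float(lam[start + w_pts // 2]))
    return {"center_nm": np.asarray(centers), "rank": np.asarray(ranks)}
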