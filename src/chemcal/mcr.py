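"""Multivariate curve resolution by alternating least squares (MCR-ALS)
with evolving-factor-analysis initialisation and chemical constraints.

The bilinear model is D = C S + E with C (samples x components) and
S (components x wavelengths).  The alternating updates solve constrained
least squares for one mode with the other fixed, until the relative
change in the residual standard deviation drops below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from chemcal.datasets import AbsorbanceMatrix, ConcentrationTable
from chemcal.exceptions import AssignmentError, DomainError

_CONSTRAINT_TOL = 1e-10


@dataclass
class ConstraintSet:
    """Chemical constraints applied during the ALS updates.

    ``selectivity`` maps a component index to a boolean mask over
    wavelengths marking regions where that component is known absent
    (its spectrum is forced to zero there).  ``reference_spectra`` maps
    a component index to a (spectrum, weight) pair; the resolved
    spectrum is shrunk toward the reference with the given weight in
    [0, 1] (a correlation constraint).
    """

    nonneg_conc: bool = True
    nonneg_spec: bool = True
    closure: float | None = None
    unimodal_spec: bool = False
    unimodal_tol: float = 1.0
    selectivity: dict[int, np.ndarray] = field(default_factory=dict)
    reference_spectra: dict[int, tuple[np.ndarray, float]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        if self.closure is not None and self.closure <= 0:
            raise DomainError("closure total must be positive")


@dataclass
class MCRModel:
    C: np.ndarray
    S: np.ndarray
    E: np.ndarray
    iterations: int
    converged: bool
    change_trajectory: list[float]
    sd_trajectory: list[float]
    explained_variance: float
    lack_of_fit: float
    constraints: ConstraintSet
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.C.shape[1]


def _growing_svals(D: np.ndarray) -> np.ndarray:
    """Singular values of growing leading row-submatrices, padded with nan."""
    n = D.shape[0]
    k_max = min(n, D.shape[1])
    out = np.full((n, k_max), np.nan)
    for i in range(1, n + 1):
        sv = np.linalg.svd(D[:i], compute_uv=False)
        out[i - 1, : len(sv)] = sv
    return out


def efa(
    D: AbsorbanceMatrix | np.ndarray, log10_threshold: float = -4.0
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Evolving factor analysis: rank estimate and concentration windows.

    Eigenvalues (squared singular values) are normalised to the largest
    eigenvalue of the full matrix before log-thresholding.  Returns
    (rank, forward trace, backward trace, initial C estimate); the
    traces hold log10 normalised eigenvalues, rows = submatrix size.
    """
    M = D.values if hasattr(D, "values") else np.asarray(D, float)
    if M.shape[0] < 2:
        raise DomainError("EFA needs at least 2 samples")
    fwd_sv = _growing_svals(M)
    bwd_sv = _growing_svals(M[::-1])[::-1]
    top = np.nanmax(fwd_sv) ** 2
    if top == 0:
        raise DomainError("EFA on an all-zero matrix")
    with np.errstate(divide="ignore", invalid="ignore"):
        fwd = np.log10(fwd_sv**2 / top)
        bwd = np.log10(bwd_sv**2 / top)
    full = fwd[-1]
    rank = int(np.sum(full[~np.isnan(full)] > log10_threshold))
    C0 = _efa_concentration_windows(fwd, bwd, rank, log10_threshold)
    return rank, fwd, bwd, C0


def _efa_concentration_windows(fwd, bwd, rank, threshold):
    """Classic EFA envelope: component j appears with the j-th forward
    eigenvalue and disappears with the (rank-j)-th backward one."""
    n = fwd.shape[0]
    if rank == 0:
        return np.zeros((n, 0))
    C0 = np.zeros((n, rank))
    floor = threshold
    for j in range(rank):
        f = np.where(np.isnan(fwd[:, j]), floor, fwd[:, j])
        b = np.where(np.isnan(bwd[:, rank - 1 - j]), floor, bwd[:, rank - 1 - j])
        env = np.minimum(f, b)
        C0[:, j] = np.clip(env - floor, 0.0, None)
    # degenerate all-zero columns fall back to a flat profile
    for j in range(rank):
        if not C0[:, j].any():
            C0[:, j] = 1.0
    return C0


def _nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A X - B|| with X >= 0, column by column."""
    X = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j], _ = nnls(A, B[:, j])
    return X


def _enforce_unimodal(row: np.ndarray) -> np.ndarray:
    """Flatten secondary maxima so the profile rises then falls once."""
    out = row.copy()
    m = int(np.argmax(out))
    for i in range(m + 1, len(out)):
        out[i] = min(out[i], out[i - 1])
    for i in range(m - 1, -1, -1):
        out[i] = min(out[i], out[i + 1])
    return out


def _apply_spectral_constraints(S: np.ndarray, constraints: ConstraintSet):
    if constraints.nonneg_spec:
        S = np.clip(S, 0.0, None)
    for j, (ref, w) in constraints.reference_spectra.items():
        ref = np.asarray(ref, float)
        scale = (S[j] @ ref) / (ref @ ref) if ref.any() else 0.0
        S[j] = (1 - w) * S[j] + w * scale * ref
        if constraints.nonneg_spec:
            S[j] = np.clip(S[j], 0.0, None)
    for j, mask in constraints.selectivity.items():
        S[j, np.asarray(mask, bool)] = 0.0
    if constraints.unimodal_spec:
        for j in range(S.shape[0]):
            S[j] = _enforce_unimodal(S[j])
    return S


def _apply_conc_constraints(C: np.ndarray, constraints: ConstraintSet):
    if constraints.nonneg_conc:
        C = np.clip(C, 0.0, None)
    if constraints.closure is not None:
        totals = C.sum(axis=1, keepdims=True)
        nonzero = totals[:, 0] > 0
        C[nonzero] = C[nonzero] / totals[nonzero] * constraints.closure
    return C


def fit_mcr_als(
    D: AbsorbanceMatrix | np.ndarray,
    n_components: int | None = None,
    init="efa",
    constraints: ConstraintSet | None = None,
    rel_tol: float = 0.20,
    max_iter: int = 50,
    log10_threshold: float = -4.0,
    seed: int | None = None,
) -> MCRModel:
    """Constrained alternating least squares resolution of D = C S + E.

    ``init`` is "efa", "random", or an explicit initial estimate: an
    (n_components x n_wavelengths) spectra array or an
    (n_samples x n_components) concentration array.  ``rel_tol`` is the
    convergence threshold in percent relative change of the residual
    standard deviation between consecutive iterations.
    """
    M = D.values if hasattr(D, "values") else np.asarray(D, float)
    constraints = constraints or ConstraintSet()
    n, w = M.shape

    C = S = None
    if isinstance(init, str):
        if init == "efa":
            rank, _, _, C0 = efa(M, log10_threshold)
            k = n_components or rank
            if C0.shape[1] >= k and k > 0:
                C = C0[:, :k]
            else:  # degenerate EFA windows: seeded random fallback
                init = "random"
                n_components = k
        if init == "random":
            if not n_components:
                raise DomainError("random init needs an explicit n_components")
            rng = np.random.default_rng(seed)
            S = rng.random((n_components, w))
    else:
        arr = np.asarray(init, float)
        if arr.ndim != 2:
            raise DomainError("init array must be 2-D")
        if arr.shape[1] == w and arr.shape[0] != n:
            S = arr.copy()
        elif arr.shape[0] == n:
            C = arr.copy()
        else:
            raise DomainError("init shape matches neither C nor S")
    k = (C.shape[1] if C is not None else S.shape[0])
    if n_components and k != n_components:
        raise DomainError("init shape disagrees with n_components")
    if k < 1:
        raise DomainError("need at least one component")

    norm_D = np.linalg.norm(M)
    sd_prev = None
    changes, sds = [], []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if C is not None:
            # S update with C fixed
            if constraints.nonneg_spec:
                S = _nnls_columns(C, M)
            else:
                S, _, _, _ = np.linalg.lstsq(C, M, rcond=None)
            S = _apply_spectral_constraints(S, constraints)
            # guard against collapsed components
            dead = ~S.any(axis=1)
            if dead.any():
                rng = np.random.default_rng(seed or 0)
                S[dead] = rng.random((dead.sum(), w)) * 1e-3
        # C update with S fixed
        if constraints.nonneg_conc:
            C = _nnls_columns(S.T, M.T).T
        else:
            C = np.linalg.lstsq(S.T, M.T, rcond=None)[0].T
        C = _apply_conc_constraints(C, constraints)

        E = M - C @ S
        sd = float(np.std(E))
        sds.append(sd)
        if sd_prev is not None:
            change = (
                100.0 * abs(sd_prev - sd) / sd_prev if sd_prev > 0 else 0.0
            )
            changes.append(change)
            if change < rel_tol:
                converged = True
                break
        sd_prev = sd

    E = M - C @ S
    ss_res = float(np.sum(E**2))
    ev = 100.0 * (1.0 - ss_res / norm_D**2) if norm_D > 0 else 100.0
    lof = 100.0 * np.sqrt(ss_res) / norm_D if norm_D > 0 else 0.0
    return MCRModel(
        C=C,
        S=S,
        E=E,
        iterations=it,
        converged=converged,
        change_trajectory=changes,
        sd_trajectory=sds,
        explained_variance=ev,
        lack_of_fit=lof,
        constraints=constraints,
        seed=seed,
    )


def match_components(
    S_resolved: np.ndarray, S_reference: np.ndarray, tie_tol: float = 1e-9
) -> list[int]:
    """Map each reference analyte to the resolved component with maximal
    cosine similarity; ambiguous (tied or duplicated) maps raise."""
    from chemcal.diagnostics import cosine_similarity

    k_ref, k_res = S_reference.shape[0], S_resolved.shape[0]
    if k_ref > k_res:
        raise AssignmentError("more analytes than resolved components")
    cos = np.array(
        [
            [cosine_similarity(S_reference[i], S_resolved[j]) for j in range(k_res)]
            for i in range(k_ref)
        ]
    )
    assignment = []
    for i in range(k_ref):
        order = np.argsort(cos[i])[::-1]
        if k_res > 1 and cos[i, order[0]] - cos[i, order[1]] < tie_tol:
            raise AssignmentError(
                f"analyte {i} matches components {order[0]} and {order[1]} "
                "equally well"
            )
        assignment.append(int(order[0]))
    if len(set(assignment)) != k_ref:
        raise AssignmentError("two analytes map to the same component")
    return assignment


def mcr_quantify(
    model: MCRModel,
    calib_conc: ConcentrationTable,
    calib_rows: np.ndarray,
    test_rows: np.ndarray,
    reference_spectra: np.ndarray,
) -> ConcentrationTable:
    """Quantify test rows of an augmented-matrix MCR fit.

    Components are matched to analytes by cosine similarity against the
    reference spectra; the scale of each resolved concentration profile
    is fixed by regressing the known calibration concentrations on the
    resolved values (slope + intercept), then applied to the test rows.
    """
    calib_rows = np.asarray(calib_rows)
    test_rows = np.asarray(test_rows)
    if len(calib_rows) < 2:
        raise DomainError("need at least 2 calibration rows")
    assignment = match_components(model.S, np.asarray(reference_spectra, float))
    preds = np.empty((len(test_rows), len(assignment)))
    for a, comp in enumerate(assignment):
        x = model.C[calib_rows, comp]
        y = calib_conc.values[:, a]
        if np.std(x) == 0:
            raise DomainError(f"resolved profile {comp} is constant")
        slope, intercept = np.polyfit(x, y, 1)
        preds[:, a] = slope * model.C[test_rows, comp] + intercept
    return ConcentrationTable(preds, list(calib_conc.analytes))
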