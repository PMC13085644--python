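"""Experimental design: multilevel calibration sets, D-optimal row
exchange, design diagnostics and solution-preparation arithmetic."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from chemcal.exceptions import (
    ConfigurationError,
    DomainError,
    InfeasibleDesignError,
    NumericalRankError,
    UnsupportedDesignError,
)

# Canonical cyclic generators for the multilevel multifactor construction.
# Column j of the coded design is the generator cyclically advanced by j,
# prefixed with the all-centre first run.  The 5-level generator is the
# 24-run sequence of the reference three-factor calibration table; the
# 3-level one was found by exhaustive search over balanced sequences with
# zero cyclic autocorrelation at the lags needed for f <= L-1 factors.
_GENERATORS = {
    3: (0, -1, -1, 1, 0, 1, 1, -1),
    5: (0, -2, -2, 2, -1, 2, 0, -1, -1, 1, 2, 1,
        0, 2, 2, -2, 1, -2, 0, 1, 1, -1, -2, -1),
}


@dataclass(frozen=True)
class FactorRange:
    """Concentration range of one analyte, discretised into levels."""

    name: str
    c_min: float
    c_max: float
    n_levels: int = 5

    def __post_init__(self):
        if not self.c_min < self.c_max:
            raise DomainError(f"{self.name}: c_min must be < c_max")
        if self.n_levels < 2:
            raise DomainError(f"{self.name}: need at least 2 levels")

    @property
    def step(self) -> float:
        return (self.c_max - self.c_min) / (self.n_levels - 1)

    @property
    def midpoint(self) -> float:
        return (self.c_max + self.c_min) / 2.0

    @property
    def levels(self) -> np.ndarray:
        return self.c_min + self.step * np.arange(self.n_levels)

    @property
    def coded_levels(self) -> np.ndarray:
        h = (self.n_levels - 1) / 2.0
        return np.arange(self.n_levels) - h


@dataclass
class CodedDesign:
    """Runs x factors matrix of coded levels (e.g. -2..+2 for 5 levels)."""

    matrix: np.ndarray
    factor_names: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DomainError("coded design must be 2-D")
        if self.matrix.shape[1] != len(self.factor_names):
            raise DomainError("factor names do not match column count")

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ConcentrationDesign:
    """Runs x factors matrix in ug/mL plus the ranges used for decoding."""

    matrix: np.ndarray
    factors: list[FactorRange]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.factors):
            raise DomainError("factor list does not match column count")

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_runs(self) -> int:
        return self.matrix.shape[0]

    def to_coded(self) -> CodedDesign:
        cols = []
        for j, f in enumerate(self.factors):
            cols.append((self.matrix[:, j] - f.midpoint) / f.step)
        return CodedDesign(np.column_stack(cols), self.factor_names)


@dataclass(frozen=True)
class ModelSpec:
    """Term set of the regression model behind the information matrix."""

    intercept: bool = True
    linear: bool = True
    interactions: bool = True
    quadratics: bool = True

    def n_terms(self, n_factors: int) -> int:
        p = int(self.intercept)
        if self.linear:
            p += n_factors
        if self.interactions:
            p += n_factors * (n_factors - 1) // 2
        if self.quadratics:
            p += n_factors
        if p < 1:
            raise DomainError("model spec selects no terms")
        return p

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        name = name.lower()
        if name == "quadratic":
            return cls()
        if name == "interaction":
            return cls(quadratics=False)
        if name == "linear":
            return cls(interactions=False, quadratics=False)
        raise ConfigurationError(f"unknown model spec name {name!r}")


@dataclass
class CandidateGrid:
    """Full-factorial candidate matrix in coded units."""

    matrix: np.ndarray
    factors: list[FactorRange]

    @property
    def n_candidates(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ExchangeResult:
    """Outcome of a multi-start D-optimal row-exchange search."""

    indices: np.ndarray
    design: ConcentrationDesign
    log10_det: float
    n_iterations: int
    n_starts: int
    seed: int
    start_log10_dets: list[float] = field(default_factory=list)


def generate_brereton_design(
    factors: list[FactorRange],
) -> tuple[CodedDesign, ConcentrationDesign]:
    """Cyclic multilevel multifactor calibration design with L^2 runs.

    Run 1 is the all-centre run; each factor column is the canonical
    level generator cyclically advanced by one run relative to the
    previous column.  Columns are balanced (each level appears L times)
    and mutually orthogonal in coded units.
    """
    if not factors:
        raise ConfigurationError("factor list is empty")
    L = factors[0].n_levels
    if any(f.n_levels != L for f in factors):
        raise ConfigurationError("all factors must share the same level count")
    if L % 2 == 0:
        raise ConfigurationError("level count must be odd (centre run required)")
    if len(factors) > L - 1:
        raise UnsupportedDesignError(
            f"at most {L - 1} factors supported at {L} levels"
        )
    if L not in _GENERATORS:
        raise UnsupportedDesignError(
            f"no cyclic generator available for {L} levels "
            f"(supported: {sorted(_GENERATORS)})"
        )
    gen = _GENERATORS[L]
    cols = []
    for j in range(len(factors)):
        rolled = gen[j:] + gen[:j]
        cols.append((0,) + rolled)
    coded = CodedDesign(
        np.array(cols, dtype=float).T, [f.name for f in factors]
    )
    return coded, code_to_concentration(coded, factors)


def code_to_concentration(
    coded: CodedDesign, factors: list[FactorRange]
) -> ConcentrationDesign:
    """Decode coded levels to ug/mL: concentration = midpoint + level*step."""
    if coded.matrix.shape[1] != len(factors):
        raise DomainError("factor list does not match design width")
    cols = []
    for j, f in enumerate(factors):
        lv = coded.matrix[:, j]
        h = (f.n_levels - 1) / 2.0
        if np.any(lv < -h - 1e-9) or np.any(lv > h + 1e-9):
            raise DomainError(
                f"coded level out of range for factor {f.name!r}"
            )
        cols.append(f.midpoint + lv * f.step)
    return ConcentrationDesign(np.column_stack(cols), list(factors))


def build_model_matrix(design, spec: ModelSpec) -> np.ndarray:
    """Expand a design into the model matrix X (runs x p).

    Column order is intercept, linear terms, two-factor interactions
    (in combination order), then pure quadratics.
    """
    M = design.matrix if hasattr(design, "matrix") else np.asarray(design, float)
    if M.ndim != 2 or M.shape[0] == 0:
        raise DomainError("design must be a non-empty 2-D matrix")
    n, f = M.shape
    cols = []
    if spec.intercept:
        cols.append(np.ones(n))
    if spec.linear:
        cols.extend(M[:, j] for j in range(f))
    if spec.interactions:
        for i, j in itertools.combinations(range(f), 2):
            cols.append(M[:, i] * M[:, j])
    if spec.quadratics:
        cols.extend(M[:, j] ** 2 for j in range(f))
    if not cols:
        raise DomainError("model spec selects no terms")
    return np.column_stack(cols)


def enumerate_candidates(factors: list[FactorRange]) -> CandidateGrid:
    """Full factorial grid of coded level combinations, lexicographic."""
    if not factors:
        raise ConfigurationError("factor list is empty")
    grids = [f.coded_levels for f in factors]
    rows = np.array(list(itertools.product(*grids)), dtype=float)
    return CandidateGrid(rows, list(factors))


def _log10_det_xtx(X: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(X.T @ X)
    if sign <= 0:
        return -np.inf
    return logdet / np.log(10.0)


def d_optimal_select(
    candidates: CandidateGrid,
    n_select: int,
    spec: ModelSpec | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> ExchangeResult:
    """Fedorov-type best-improvement row exchange maximising det(X'X).

    Each start draws a seeded random non-singular subset and repeatedly
    applies the single (selected, candidate) swap with the largest
    determinant gain until no swap improves; the best start wins.  Ties
    are broken toward the lowest candidate index.
    """
    spec = spec or ModelSpec()
    F = candidates.matrix
    n_cand = F.shape[0]
    X_all = build_model_matrix(F, spec)
    p = X_all.shape[1]
    if n_select < p:
        raise InfeasibleDesignError(
            f"n_select={n_select} below the {p} model parameters"
        )
    if n_select > n_cand:
        raise InfeasibleDesignError("n_select exceeds candidate count")

    rng = np.random.default_rng(seed)
    best = None
    start_logs = []
    total_iters = 0
    any_nonsingular = False
    for _ in range(n_starts):
        sel = _nonsingular_start(X_all, n_select, rng)
        if sel is None:
            start_logs.append(-np.inf)
            continue
        any_nonsingular = True
        sel, logdet, iters = _exchange_one_start(X_all, sel)
        total_iters += iters
        start_logs.append(logdet)
        if best is None or logdet > best[1] + 1e-12:
            best = (sel, logdet)
    if not any_nonsingular or best is None:
        raise NumericalRankError(
            "every random start produced a singular design; increase "
            "n_select, simplify the model spec, or enlarge the candidate set"
        )
    sel, logdet = best
    conc = code_to_concentration(
        CodedDesign(F[sel], [f.name for f in candidates.factors]),
        candidates.factors,
    )
    return ExchangeResult(
        indices=np.asarray(sel),
        design=conc,
        log10_det=logdet,
        n_iterations=total_iters,
        n_starts=n_starts,
        seed=seed,
        start_log10_dets=start_logs,
    )


def _nonsingular_start(X_all, n_select, rng, max_tries=50):
    n_cand = X_all.shape[0]
    for _ in range(max_tries):
        sel = np.sort(rng.choice(n_cand, size=n_select, replace=False))
        if np.isfinite(_log10_det_xtx(X_all[sel])):
            return sel
    return None


def _exchange_one_start(X_all, sel, max_sweeps=200):
    """Best-improvement Fedorov exchange from one starting subset."""
    sel = list(sel)
    n_cand = X_all.shape[0]
    iters = 0
    for _ in range(max_sweeps):
        X = X_all[sel]
        Minv = np.linalg.inv(X.T @ X)
        # variance function d(x) = x' Minv x for candidates and selected rows
        H_cand = X_all @ Minv        # n_cand x p
        d_in = np.einsum("ij,ij->i", H_cand, X_all)
        d_out = np.einsum("ij,ij->i", X @ Minv, X)
        cross = H_cand @ X.T         # n_cand x n_sel, d(x_i, x_j)
        # Fedorov delta: det ratio - 1 for swapping selected j with cand i
        delta = (
            d_in[:, None]
            - (d_in[:, None] * d_out[None, :] - cross**2)
            - d_out[None, :]
        )
        # forbid no-op swaps (candidate already selected)
        delta[sel, :] = -np.inf
        i_best, j_best = np.unravel_index(np.argmax(delta), delta.shape)
        if delta[i_best, j_best] <= 1e-10:
            break
        # deterministic tie-break: lowest candidate index, then lowest slot
        tol = 1e-12 * max(1.0, abs(delta[i_best, j_best]))
        ties = np.argwhere(delta >= delta[i_best, j_best] - tol)
        i_best, j_best = min(map(tuple, ties))
        sel[j_best] = i_best
        iters += 1
    return np.sort(sel), _log10_det_xtx(X_all[np.sort(sel)]), iters


def design_diagnostics(design: ConcentrationDesign) -> dict:
    """Pairwise correlations, level counts and range coverage per factor."""
    M = design.matrix
    if M.shape[0] < 2:
        raise DomainError("need at least 2 runs for diagnostics")
    names = design.factor_names
    sd = M.std(axis=0)
    corr = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        key = (names[i], names[j])
        if sd[i] == 0 or sd[j] == 0:
            corr[key] = None  # undefined for a constant column
        else:
            corr[key] = float(np.corrcoef(M[:, i], M[:, j])[0, 1])
    level_counts = {}
    coverage = {}
    for j, f in enumerate(design.factors):
        vals, counts = np.unique(M[:, j], return_counts=True)
        level_counts[f.name] = dict(zip(vals.tolist(), counts.tolist()))
        observed = M[:, j].max() - M[:, j].min()
        coverage[f.name] = float(observed / (f.c_max - f.c_min))
    return {
        "correlations": corr,
        "level_counts": level_counts,
        "coverage": coverage,
    }


def solution_prep(steps: list[tuple]) -> float:
    """Chain dissolution/dilution steps to a final concentration in ug/mL.

    Steps: ("mass", mass_mg, final_volume_ml) dissolves a solid,
    ("stock", conc_ug_ml) starts from a stock solution, and
    ("dilute", aliquot_ml, final_volume_ml) transfers an aliquot.
    Arithmetic is exact (rational) until the final float conversion.
    """
    conc = None
    for step in steps:
        kind = step[0]
        if kind == "mass":
            _, mass_mg, vol_ml = step
            if vol_ml <= 0:
                raise DomainError("final volume must be positive")
            if mass_mg < 0:
                raise DomainError("mass must be non-negative")
            conc = Fraction(mass_mg).limit_denominator() * 1000 / Fraction(
                vol_ml
            ).limit_denominator()
        elif kind == "stock":
            conc = Fraction(step[1]).limit_denominator()
        elif kind == "dilute":
            _, aliquot_ml, vol_ml = step
            if conc is None:
                raise DomainError("dilution before any solution exists")
            if aliquot_ml <= 0 or vol_ml <= 0:
                raise DomainError("volumes must be positive")
            if aliquot_ml > vol_ml:
                raise DomainError("aliquot cannot exceed the final volume")
            conc = conc * Fraction(aliquot_ml).limit_denominator() / Fraction(
                vol_ml
            ).limit_denominator()
        else:
            raise ConfigurationError(f"unknown prep step kind {kind!r}")
    if conc is None:
        raise DomainError("no preparation steps given")
    return float(conc)
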