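"""Figures of merit for calibration and external validation sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from chemcal.exceptions import DomainError

LOD_MULTIPLIER = 3.3
LOQ_MULTIPLIER = 10.0


@dataclass
class PredictionSet:
    """Paired true/predicted concentrations for one analyte."""

    true: np.ndarray
    predicted: np.ndarray
    analyte: str = ""
    label: str = "validation"

    def __post_init__(self):
        self.true = np.asarray(self.true, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.true.shape != self.predicted.shape:
            raise DomainError("true and predicted lengths differ")
        if self.true.ndim != 1:
            raise DomainError("prediction set must be 1-D")

    @property
    def n(self) -> int:
        return len(self.true)

    @property
    def errors(self) -> np.ndarray:
        return self.true - self.predicted


@dataclass
class FomRecord:
    """Per-analyte figures of merit in the shape of a validation sheet."""

    analyte: str
    rmsec: float | None = None
    rmsecv: float | None = None
    rmsep: float | None = None
    bias: float | None = None
    sec: float | None = None
    rrmsep_pct: float | None = None
    bcrmsep: float | None = None
    slope: float | None = None
    intercept: float | None = None
    r2: float | None = None
    mean_recovery_pct: float | None = None
    recovery_sd: float | None = None
    rsd_pct: float | None = None
    lod: float | None = None
    loq: float | None = None
    t_exp: float | None = None
    t_crit: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["t_crit"] = {str(k): v for k, v in self.t_crit.items()}
        return d


def rmse(p: PredictionSet) -> float:
    """Root mean square error sqrt(sum (Ei - Ei_hat)^2 / n)."""
    if p.n < 1:
        raise DomainError("empty prediction set")
    return float(np.sqrt(np.mean(p.errors**2)))


def bias_sec(p: PredictionSet) -> tuple[float, float]:
    """Mean error and the n-1 standard error of errors about the bias."""
    if p.n < 2:
        raise DomainError("need at least 2 samples")
    e = p.errors
    bias = float(np.mean(e))
    sec = float(np.sqrt(np.sum((e - bias) ** 2) / (p.n - 1)))
    return bias, sec


def rrmsep(p: PredictionSet) -> float:
    """Relative RMSE of prediction in percent of the root sum of squares."""
    denom = float(np.sum(p.true**2))
    if denom <= 0:
        raise DomainError("all-zero truth")
    return float(100.0 * np.sqrt(np.sum(p.errors**2) / denom))


def bcrmsep(p: PredictionSet) -> float:
    """Bias-corrected RMSEP with an n denominator, so that
    bias^2 + BCRMSEP^2 = RMSEP^2 holds exactly."""
    if p.n < 2:
        raise DomainError("need at least 2 samples")
    e = p.errors
    return float(np.sqrt(np.mean((e - np.mean(e)) ** 2)))


def recovery_stats(p: PredictionSet) -> tuple[float, float, float]:
    """Mean recovery percent, its n-1 SD and the RSD percent."""
    if np.any(p.true <= 0):
        raise DomainError("recovery undefined for non-positive truth")
    r = 100.0 * p.predicted / p.true
    mean = float(np.mean(r))
    sd = float(np.std(r, ddof=1)) if p.n > 1 else 0.0
    rsd = 100.0 * sd / mean if mean != 0 else np.inf
    return mean, sd, float(rsd)


def bias_t_test(recoveries, alphas=(0.05, 0.01)) -> dict:
    """Student-t test of mean recovery against 100 %.

    t_exp = |100 - mean| * sqrt(n) / sd, compared against two-tailed
    critical values at n-1 degrees of freedom.
    """
    r = np.asarray(recoveries, dtype=float)
    n = len(r)
    if n < 2:
        raise DomainError("need at least 2 recoveries")
    sd = float(np.std(r, ddof=1))
    mean = float(np.mean(r))
    if sd == 0:
        t_exp = np.inf if mean != 100.0 else 0.0
        infinite = mean != 100.0
    else:
        t_exp = abs(100.0 - mean) * np.sqrt(n) / sd
        infinite = False
    out = {"t_exp": float(t_exp), "df": n - 1, "infinite_t": infinite}
    crit, sig = {}, {}
    for a in alphas:
        c = float(stats.t.ppf(1 - a / 2, n - 1))
        crit[a] = c
        sig[a] = bool(t_exp > c)
    out["critical"] = crit
    out["significant"] = sig
    return out


def t_critical(alpha: float, df: int) -> float:
    """Two-tailed Student-t critical value."""
    if df < 1:
        raise DomainError("df must be >= 1")
    return float(stats.t.ppf(1 - alpha / 2, df))


def lod_loq(b: np.ndarray, noise_sd: float) -> tuple[float, float]:
    """Net-analyte-signal detection limits from a regression vector.

    LOD = 3.3 * sd * ||b||, LOQ = 10 * sd * ||b||, so LOQ/LOD = 10/3.3.
    """
    norm = float(np.linalg.norm(np.asarray(b, dtype=float)))
    if norm == 0:
        raise DomainError("zero-norm regression vector")
    if noise_sd < 0:
        raise DomainError("noise sd must be non-negative")
    return LOD_MULTIPLIER * noise_sd * norm, LOQ_MULTIPLIER * noise_sd * norm


def linearity_stats(p: PredictionSet) -> tuple[float, float, float]:
    """OLS of predicted on true: slope, intercept, r^2."""
    if p.n < 3:
        raise DomainError("need at least 3 samples")
    if np.ptp(p.true) == 0:
        raise DomainError("constant truth")
    res = stats.linregress(p.true, p.predicted)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across recovery groups."""
    if len(groups) < 2:
        raise DomainError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise DomainError("each group needs at least 2 observations")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    f, pval = stats.f_oneway(*arrays)
    if np.isnan(f):  # identical groups: no between- or within-variance
        return 0.0, 1.0
    return float(f), float(pval)


def fom_record(
    analyte: str,
    validation: PredictionSet,
    calibration: PredictionSet | None = None,
    rmsecv: float | None = None,
    b_vector: np.ndarray | None = None,
    noise_sd: float | None = None,
    alphas=(0.05, 0.01),
) -> FomRecord:
    """Assemble a full figures-of-merit record for one analyte."""
    rec = FomRecord(analyte=analyte)
    rec.rmsep = rmse(validation)
    rec.bias, _ = bias_sec(validation)
    rec.bcrmsep = bcrmsep(validation)
    rec.rrmsep_pct = rrmsep(validation)
    mean_r, sd_r, rsd = recovery_stats(validation)
    rec.mean_recovery_pct, rec.recovery_sd, rec.rsd_pct = mean_r, sd_r, rsd
    recoveries = 100.0 * validation.predicted / validation.true
    t = bias_t_test(recoveries, alphas)
    rec.t_exp = t["t_exp"]
    rec.t_crit = t["critical"]
    rec.slope, rec.intercept, rec.r2 = linearity_stats(validation)
    if calibration is not None:
        rec.rmsec = rmse(calibration)
        _, rec.sec = bias_sec(calibration)
    rec.rmsecv = rmsecv
    if b_vector is not None and noise_sd is not None:
        rec.lod, rec.loq = lod_loq(b_vector, noise_sd)
    return rec
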