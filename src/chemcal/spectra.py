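"""Synthetic UV spectra: Gaussian-band pure components, bilinear
Beer-Lambert mixing with noise/baseline, and instrument perturbations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from chemcal.datasets import AbsorbanceMatrix, ConcentrationTable, WavelengthGrid
from chemcal.exceptions import ConfigurationError, DomainError


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band: centre (nm), width (nm, sd), amplitude
    (AU * mL/ug at the band centre)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise DomainError("band width must be positive")
        if self.amplitude < 0:
            raise DomainError("band amplitude must be non-negative")


@dataclass(frozen=True)
class BandModel:
    """Pure-component spectrum model as a sum of Gaussian bands."""

    name: str
    bands: tuple[GaussianBand, ...] = ()

    def evaluate(self, grid: WavelengthGrid) -> np.ndarray:
        lam = grid.values
        s = np.zeros_like(lam)
        for b in self.bands:
            s += b.amplitude * np.exp(-((lam - b.center) ** 2) / (2 * b.width**2))
        return s


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise plus an optional linear baseline."""

    sd: float = 0.003
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise DomainError("noise sd must be non-negative")


@dataclass
class SimulatedDataset:
    """Bilinear mixture dataset with stored ground truth."""

    absorbance: AbsorbanceMatrix
    concentrations: ConcentrationTable
    pure_spectra: np.ndarray  # components x wavelengths
    band_models: tuple[BandModel, ...]
    noise: NoiseModel
    seed: int


def pure_spectrum(bands: BandModel, grid: WavelengthGrid) -> np.ndarray:
    """Evaluate a band model on a grid; sum of Gaussians, non-negative."""
    return bands.evaluate(grid)


# Fixed band constants emulating the qualitative features of the three
# analytes: a dual peak in 240-260 nm with its maximum near 250 nm
# (CIN-like), maxima near 285 nm and 230 nm (DOM-like), and a single
# band near 250 nm (BNZ-like).  Amplitudes put mid-range mixtures around
# 0.5-1 AU.
_CIN_BANDS = (
    GaussianBand(243.0, 3.0, 0.038),
    GaussianBand(251.5, 3.4, 0.045),
    GaussianBand(228.0, 6.0, 0.020),
)
_DOM_BANDS = (
    GaussianBand(285.0, 7.0, 0.060),
    GaussianBand(230.0, 5.0, 0.048),
    # broad weak shoulder: keeps realistic overlap with the 250 nm band
    # of the other two components without moving the 285 nm maximum
    GaussianBand(252.0, 14.0, 0.022),
)
_BNZ_BANDS = (GaussianBand(250.0, 8.5, 0.180),)


def default_component_library(
    grid: WavelengthGrid | None = None,
) -> tuple[BandModel, BandModel, BandModel]:
    """Stand-in pure-component models for CIN, DOM and BNZ (in that order)."""
    return (
        BandModel("CIN", _CIN_BANDS),
        BandModel("DOM", _DOM_BANDS),
        BandModel("BNZ", _BNZ_BANDS),
    )


def library_spectra(
    library: tuple[BandModel, ...], grid: WavelengthGrid
) -> np.ndarray:
    """Stack pure spectra of a library into a components x wavelengths array."""
    return np.vstack([m.evaluate(grid) for m in library])


def simulate_mixtures(
    conc: ConcentrationTable,
    library: tuple[BandModel, ...],
    noise: NoiseModel | None = None,
    grid: WavelengthGrid | None = None,
) -> SimulatedDataset:
    """Beer-Lambert bilinear mixing D = C S_true + baseline + noise."""
    grid = grid or WavelengthGrid()
    noise = noise or NoiseModel(sd=0.0)
    names = [m.name for m in library]
    if conc.analytes != names:
        raise DomainError(
            f"concentration columns {conc.analytes} do not match library "
            f"components {names}"
        )
    if np.any(conc.values < 0):
        raise DomainError("concentrations must be non-negative")
    S = library_spectra(library, grid)
    D = conc.values @ S
    lam = grid.values
    D = D + noise.baseline_offset + noise.baseline_slope * (lam - lam[0])
    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        D = D + rng.normal(0.0, noise.sd, size=D.shape)
    return SimulatedDataset(
        absorbance=AbsorbanceMatrix(D, grid, sample_ids=list(conc.sample_ids)),
        concentrations=conc,
        pure_spectra=S,
        band_models=tuple(library),
        noise=noise,
        seed=noise.seed,
    )


def perturb_instrument(
    data: AbsorbanceMatrix,
    mode: str,
    magnitude: float,
    seed: int = 0,
) -> AbsorbanceMatrix:
    """Apply a small instrumental perturbation for robustness testing.

    ``interval``: resample onto a coarser axis of the given spacing (nm)
    and linearly interpolate back.  ``bandwidth``: Gaussian slit
    smoothing of the given sd (nm).  ``scan-speed``: seeded additive
    noise of the given sd (AU).  Zero magnitude is the identity.
    """
    if magnitude < 0:
        raise DomainError("perturbation magnitude must be non-negative")
    if magnitude == 0:
        return AbsorbanceMatrix(
            data.values.copy(), data.grid, list(data.sample_ids)
        )
    lam = data.grid.values
    if mode == "interval":
        coarse = np.arange(lam[0], lam[-1] + 1e-9, magnitude)
        out = np.empty_like(data.values)
        for i, row in enumerate(data.values):
            on_coarse = np.interp(coarse, lam, row)
            out[i] = np.interp(lam, coarse, on_coarse)
    elif mode == "bandwidth":
        sigma_pts = magnitude / data.grid.step
        out = gaussian_filter1d(
            data.values, sigma=sigma_pts, axis=1, mode="nearest"
        )
    elif mode == "scan-speed":
        rng = np.random.default_rng(seed)
        out = data.values + rng.normal(0.0, magnitude, size=data.values.shape)
    else:
        raise ConfigurationError(f"unsupported perturbation mode {mode!r}")
    return AbsorbanceMatrix(out, data.grid, list(data.sample_ids))
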