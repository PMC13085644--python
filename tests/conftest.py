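import numpy as np
import pytest

from chemcal.datasets import AbsorbanceMatrix, ConcentrationTable, WavelengthGrid
from chemcal.design import (
    FactorRange,
    ModelSpec,
    d_optimal_select,
    enumerate_candidates,
    generate_brereton_design,
)
from chemcal.spectra import (
    NoiseModel,
    default_component_library,
    library_spectra,
    simulate_mixtures,
)

ANALYTES = ["CIN", "DOM", "BNZ"]


@pytest.fixture(scope="session")
def factors():
    return [
        FactorRange("CIN", 4.0, 20.0, 5),
        FactorRange("DOM", 3.0, 15.0, 5),
        FactorRange("BNZ", 1.0, 5.0, 5),
    ]


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def library(grid):
    return default_component_library(grid)


@pytest.fixture(scope="session")
def pure_spectra(library, grid):
    return library_spectra(library, grid)


@pytest.fixture(scope="session")
def calib_design(factors):
    _, conc = generate_brereton_design(factors)
    return conc


@pytest.fixture(scope="session")
def valid_design(factors):
    res = d_optimal_select(
        enumerate_candidates(factors), 13, ModelSpec(), n_starts=10, seed=11
    )
    return res.design


@pytest.fixture(scope="session")
def calib_conc(calib_design):
    return ConcentrationTable(calib_design.matrix, ANALYTES)


@pytest.fixture(scope="session")
def valid_conc(valid_design):
    return ConcentrationTable(valid_design.matrix, ANALYTES)


@pytest.fixture(scope="session")
def noiseless(calib_conc, valid_conc, library, grid):
    """Noise-free calibration + validation simulation bundle."""
    stacked = ConcentrationTable(
        np.vstack([calib_conc.values, valid_conc.values]), ANALYTES
    )
    sim = simulate_mixtures(stacked, library, NoiseModel(sd=0.0), grid)
    n_cal = calib_conc.n_samples
    return {
        "sim": sim,
        "A_cal": AbsorbanceMatrix(sim.absorbance.values[:n_cal], grid),
        "A_val": AbsorbanceMatrix(sim.absorbance.values[n_cal:], grid),
        "C_cal": calib_conc,
        "C_val": valid_conc,
    }


@pytest.fixture(scope="session")
def noisy(calib_conc, valid_conc, library, grid):
    """Default-noise (sd 0.003) simulation bundle at a fixed seed."""
    stacked = ConcentrationTable(
        np.vstack([calib_conc.values, valid_conc.values]), ANALYTES
    )
    sim = simulate_mixtures(stacked, library, NoiseModel(sd=0.003, seed=17), grid)
    n_cal = calib_conc.n_samples
    return {
        "sim": sim,
        "A_cal": AbsorbanceMatrix(sim.absorbance.values[:n_cal], grid),
        "A_val": AbsorbanceMatrix(sim.absorbance.values[n_cal:], grid),
        "C_cal": calib_conc,
        "C_val": valid_conc,
    }
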