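"""CSV/JSON readers and writers for the package's domain objects.

CSV dialect: UTF-8, comma separator, dot decimal, header row required.
Designs and concentration tables use ``mix,<analyte>,...`` headers;
spectra use ``wavelength_nm`` followed by one column per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chemcal.datasets import AbsorbanceMatrix, ConcentrationTable, WavelengthGrid
from chemcal.exceptions import ParseError


def write_concentrations(table: ConcentrationTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_concentrations(path) -> ConcentrationTable:
    df = pd.read_csv(path)
    if df.columns[0] != "mix":
        raise ParseError(
            f"{path}: first column must be 'mix', got {df.columns[0]!r}"
        )
    analytes = list(df.columns[1:])
    if not analytes:
        raise ParseError(f"{path}: no analyte columns")
    return ConcentrationTable(
        df[analytes].to_numpy(dtype=float),
        analytes,
        sample_ids=df["mix"].tolist(),
    )


def write_spectra(matrix: AbsorbanceMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, index=False)


def read_spectra(path) -> AbsorbanceMatrix:
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ParseError(f"{path}: missing 'wavelength_nm' column")
    lam = df["wavelength_nm"].to_numpy(dtype=float)
    if len(lam) < 2:
        raise ParseError(f"{path}: need at least two wavelengths")
    steps = np.diff(lam)
    if not np.allclose(steps, steps[0]):
        raise ParseError(f"{path}: wavelength axis is not uniform")
    grid = WavelengthGrid(float(lam[0]), float(lam[-1]), float(steps[0]))
    samples = [c for c in df.columns if c != "wavelength_nm"]
    values = df[samples].to_numpy(dtype=float).T
    return AbsorbanceMatrix(values, grid, sample_ids=samples)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())
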