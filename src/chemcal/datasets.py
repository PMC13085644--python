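"""Core labelled-array containers used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chemcal.exceptions import AlignmentError, DomainError


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis in nm, endpoints inclusive.

    The default 220-300 nm axis at 1 nm spacing has 81 points.
    """

    start: float = 220.0
    end: float = 300.0
    step: float = 1.0

    def __post_init__(self):
        if self.end <= self.start:
            raise DomainError("grid end must exceed start")
        if self.step <= 0:
            raise DomainError("grid step must be positive")
        n = (self.end - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise DomainError(
                f"grid span {self.start}-{self.end} is not an integral "
                f"number of {self.step} nm steps"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end - self.start) / self.step)) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def __len__(self) -> int:
        return self.n_points


@dataclass
class ConcentrationTable:
    """Samples x analytes concentration matrix in ug/mL."""

    values: np.ndarray
    analytes: list[str]
    sample_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("concentration table must be 2-D")
        if self.values.shape[1] != len(self.analytes):
            raise DomainError("analyte names do not match column count")
        if self.sample_ids is None:
            self.sample_ids = list(range(1, self.values.shape[0] + 1))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        return self.values[:, self.analytes.index(analyte)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.analytes)
        df.insert(0, "mix", self.sample_ids)
        return df


@dataclass
class AbsorbanceMatrix:
    """Samples x wavelengths absorbance matrix (AU) on a WavelengthGrid."""

    values: np.ndarray
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    sample_ids: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("absorbance matrix must be 2-D")
        if self.values.shape[1] != self.grid.n_points:
            raise AlignmentError(
                f"matrix has {self.values.shape[1]} columns but grid has "
                f"{self.grid.n_points} points"
            )
        if self.sample_ids is None:
            self.sample_ids = list(range(1, self.values.shape[0] + 1))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values.T,
            columns=[str(s) for s in self.sample_ids],
        )
        df.insert(0, "wavelength_nm", self.grid.values)
        return df
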