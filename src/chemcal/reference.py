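"""Reference three-analyte designs shipped with the package.

The 25-run calibration table is the canonical five-level, three-factor
cyclic design over the CIN/DOM/BNZ working ranges; the 13-mixture
validation table is the published exchange-selected set.  Both are in
ug/mL with columns ordered (CIN, DOM, BNZ).
"""

from __future__ import annotations

import numpy as np

from chemcal.design import ConcentrationDesign, FactorRange

ANALYTES = ("CIN", "DOM", "BNZ")

FACTOR_RANGES = (
    FactorRange("CIN", 4.0, 20.0, 5),
    FactorRange("DOM", 3.0, 15.0, 5),
    FactorRange("BNZ", 1.0, 5.0, 5),
)

CALIBRATION_SET = np.array(
    [
        [12, 9, 3], [12, 3, 1], [4, 3, 5], [4, 15, 2], [20, 6, 5],
        [8, 15, 3], [20, 9, 2], [12, 6, 2], [8, 6, 4], [8, 12, 5],
        [16, 15, 4], [20, 12, 3], [16, 9, 5], [12, 15, 5], [20, 15, 1],
        [20, 3, 4], [4, 12, 1], [16, 3, 3], [4, 9, 4], [12, 12, 4],
        [16, 12, 2], [16, 6, 1], [8, 3, 2], [4, 6, 3], [8, 9, 1],
    ],
    dtype=float,
)

VALIDATION_SET = np.array(
    [
        [13, 6, 4], [13, 11, 3], [6, 5, 3], [14, 5, 2], [10, 12, 4],
        [5, 10, 1], [8, 14, 2], [10, 7, 1], [17, 3, 2], [18, 12, 4],
        [7, 14, 4], [20, 8, 3], [15, 9, 5],
    ],
    dtype=float,
)


def calibration_design() -> ConcentrationDesign:
    return ConcentrationDesign(CALIBRATION_SET.copy(), list(FACTOR_RANGES))


def validation_design() -> ConcentrationDesign:
    return ConcentrationDesign(VALIDATION_SET.copy(), list(FACTOR_RANGES))
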