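"""Cross-validation plans shared by the calibration engines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from chemcal.exceptions import ConfigurationError


@dataclass(frozen=True)
class CrossValidationPlan:
    """Partition of the sample index set into validation folds.

    ``venetian`` assigns sample i to fold i mod n_splits; ``loo`` leaves
    one sample out at a time.
    """

    scheme: str = "venetian"
    n_splits: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("venetian", "loo"):
            raise ConfigurationError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "venetian" and self.n_splits < 2:
            raise ConfigurationError("need at least 2 splits")

    def splits(self, n_samples: int):
        """Yield (train_idx, test_idx) pairs covering every sample once."""
        idx = np.arange(n_samples)
        k = n_samples if self.scheme == "loo" else min(self.n_splits, n_samples)
        for fold in range(k):
            test = idx[idx % k == fold] if self.scheme == "venetian" else idx[[fold]]
            train = np.setdiff1d(idx, test)
            yield train, test
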