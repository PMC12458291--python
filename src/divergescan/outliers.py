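"""Empirical-quantile outlier calling shared by the PBS and CNV scans."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OutlierSet:
    """Values strictly above the empirical ``q`` quantile.

    ``mask`` flags outliers among the *defined* (finite) input values,
    aligned with the original input order (NaN inputs are never
    outliers).
    """

    threshold: float
    q: float
    mask: np.ndarray
    values: np.ndarray

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def n_outliers(self) -> int:
        return int(self.mask.sum())


def quantile_outliers(values: np.ndarray, q: float = 0.99) -> OutlierSet:
    """Flag values strictly above the type-7 (linear-interpolation)
    empirical ``q`` quantile of the defined values.

    A constant vector therefore yields an empty outlier set: nothing
    exceeds its own quantile strictly.
    """
    values = np.asarray(values, dtype=float)
    defined = values[np.isfinite(values)]
    if defined.size == 0:
        raise ValueError("no defined values to take a quantile of")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    threshold = float(np.quantile(defined, q, method="linear"))
    mask = np.zeros(values.shape, dtype=bool)
    finite = np.isfinite(values)
    mask[finite] = values[finite] > threshold
    return OutlierSet(threshold, q, mask, values)
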