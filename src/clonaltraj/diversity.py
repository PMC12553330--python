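"""Effective diversity (Hill numbers) of a barcoded population over time.

The Hill number of order q,

    D_q = (sum_k f_k^q)^(1/(1-q)),

is the "effective number of barcodes": q = 0 counts unique barcodes
(richness), q -> 1 gives the exponential of Shannon entropy, larger q weight
abundant barcodes more, and q = infinity is the inverse of the largest
frequency (dominance). Zero-frequency barcodes are excluded from the power
sum (the standard convention; 0^0 would otherwise corrupt q = 0), and the
q = 1 and q = infinity cases are analytic limits, not numerical ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FrequencyMatrix

__all__ = ["DiversityProfile", "hill_number", "diversity_timeseries"]

DEFAULT_ORDERS: tuple[float, ...] = (0.0, 1.0, 2.0, np.inf)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DiversityProfile:
    """D_q(t) on an (order x timepoint) grid."""

    orders: tuple[float, ...]
    timepoints: np.ndarray
    values: np.ndarray  # shape (n_orders, n_timepoints); NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        """One row per timepoint, one ``D_q`` column per order."""
        cols = {"Time": self.timepoints}
        for i, q in enumerate(self.orders):
            name = "inf" if np.isinf(q) else format(q, "g")
            cols[f"D_{name}"] = self.values[i]
        return pd.DataFrame(cols)


def hill_number(f, q: float) -> float:
    """Effective diversity of order ``q`` for one frequency vector.

    ``f`` must be non-negative and sum to 1 (tolerance 1e-9); zero entries
    are excluded. ``q`` may be any real >= 0 or ``numpy.inf``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    total = f.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"frequencies must sum to 1 (got {total!r})")
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    f = f[f > 0]
    if np.isinf(q):
        return 1.0 / float(f.max())
    if q == 1.0:
        return float(np.exp(-np.sum(f * np.log(f))))
    return float(np.sum(f**q) ** (1.0 / (1.0 - q)))


def diversity_timeseries(
    fm: FrequencyMatrix, orders=DEFAULT_ORDERS
) -> DiversityProfile:
    """Column-wise Hill numbers of a frequency matrix.

    A timepoint whose column is all zero has undefined diversity: it is
    reported as NaN with a warning.
    """
    orders = tuple(float(q) for q in orders)
    values = np.full((len(orders), fm.n_timepoints), np.nan)
    for t in range(fm.n_timepoints):
        col = fm.freqs[:, t]
        if not np.any(col > 0):
            warnings.warn(
                f"timepoint {fm.timepoints[t]} has no detected barcode; "
                "diversity undefined",
                stacklevel=2,
            )
            continue
        for i, q in enumerate(orders):
            values[i, t] = hill_number(col, q)
    return DiversityProfile(orders, fm.timepoints, values)
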