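"""Noise-suppression filters applied before trajectory clustering.

Low-abundance and transient barcodes carry mostly sampling noise. Two
thresholds suppress them: a barcode must have arithmetic-mean frequency
(over *all* timepoints, zeros included) strictly above ``min_mean_frequency``,
and must be detected (strictly positive reads, i.e. frequency > 0) in at
least ``min_persistence`` timepoints. Survivors keep their population
fractions — frequencies are never renormalized after filtering, so cluster
abundances downstream remain fractions of the whole population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import FrequencyMatrix

__all__ = ["FilterSpec", "TrajectoryFilter", "apply_filters"]


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds of the pre-clustering filter.

    ``min_mean_frequency`` in [0, 1]; ``min_persistence`` in
    [0, ``n_timepoints``] (count of timepoints with detection).
    """

    min_mean_frequency: float
    min_persistence: int
    n_timepoints: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_mean_frequency <= 1.0:
            raise ValueError("min_mean_frequency must lie in [0, 1]")
        if not 0 <= self.min_persistence <= self.n_timepoints:
            raise ValueError("min_persistence must lie in [0, n_timepoints]")


class TrajectoryFilter(TransformerMixin, BaseEstimator):
    """Select barcode trajectories passing abundance and persistence thresholds.

    A scikit-learn transformer over a frequency matrix ``X`` of shape
    (n_barcodes, n_timepoints): rows are samples (barcodes), columns the
    shared timepoints.

    Parameters
    ----------
    min_mean_frequency : float, default=1e-4
        Keep barcode k only if ``mean_t f_k(t) > min_mean_frequency``
        (strict, zeros included in the mean).
    min_persistence : int, default=12
        Keep barcode k only if ``|{t : f_k(t) > 0}| >= min_persistence``.

    Attributes
    ----------
    support_ : ndarray of bool, shape (n_barcodes,)
        Survivor mask.
    mean_frequency_ : ndarray of float
        Per-barcode mean frequency.
    n_detected_ : ndarray of int
        Per-barcode count of timepoints with detection.
    """

    def __init__(self, min_mean_frequency: float = 1e-4, min_persistence: int = 12):
        self.min_mean_frequency = min_mean_frequency
        self.min_persistence = min_persistence

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=1)
        FilterSpec(self.min_mean_frequency, int(self.min_persistence), X.shape[1])
        self.n_features_in_ = X.shape[1]
        self.mean_frequency_ = X.mean(axis=1)
        self.n_detected_ = (X > 0).sum(axis=1)
        self.support_ = (self.mean_frequency_ > self.min_mean_frequency) & (
            self.n_detected_ >= self.min_persistence
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = check_array(X)
        if X.shape[0] != self.support_.size:
            raise ValueError("X has a different number of barcodes than fitted")
        return X[self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


def rejection_report(flt: TrajectoryFilter, barcode_ids: list[str]) -> pd.DataFrame:
    """One row per rejected barcode with the failed criterion (or criteria)."""
    check_is_fitted(flt, "support_")
    rows = []
    for i, bid in enumerate(barcode_ids):
        if flt.support_[i]:
            continue
        reasons = []
        if not flt.mean_frequency_[i] > flt.min_mean_frequency:
            reasons.append("mean_frequency")
        if not flt.n_detected_[i] >= flt.min_persistence:
            reasons.append("persistence")
        rows.append(
            {
                "ID": bid,
                "mean_frequency": flt.mean_frequency_[i],
                "n_detected": int(flt.n_detected_[i]),
                "failed": "+".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["ID", "mean_frequency", "n_detected", "failed"])


def apply_filters(
    fm: FrequencyMatrix, spec: FilterSpec
) -> tuple[FrequencyMatrix, pd.DataFrame]:
    """Apply the mean-frequency and persistence filters to a frequency matrix.

    Returns the matrix restricted to surviving barcodes (NOT renormalized)
    and the rejection report. Raises ``ValueError`` when ``spec.n_timepoints``
    disagrees with the matrix.
    """
    if spec.n_timepoints != fm.n_timepoints:
        raise ValueError(
            f"spec.n_timepoints={spec.n_timepoints} does not match the series "
            f"({fm.n_timepoints} timepoints)"
        )
    flt = TrajectoryFilter(spec.min_mean_frequency, spec.min_persistence).fit(fm.freqs)
    return fm.restrict(flt.support_), rejection_report(flt, fm.barcode_ids)
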