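"""Pairwise trajectory distances seeding hierarchical clustering.

Two dissimilarities between barcode frequency trajectories are supported:

* ``pearson`` — correlation distance ``1 - r``; shape-based and invariant to
  positive affine rescaling, so lineages with proportional dynamics are close
  and anti-correlated dynamics are maximally distant (2).
* ``dtw`` — classic dynamic time warping with local cost ``|x_i - y_j|``,
  symmetric steps {(1,0),(0,1),(1,1)} and no path-length normalization;
  an optional Sakoe-Chiba band of half-width ``window`` constrains warping.

Trajectories are compared either on the linear frequency scale or (default
downstream) as ``log10(max(f, floor))``, which emphasizes low-frequency but
persistent lineages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

from .core import FrequencyMatrix

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap

__all__ = [
    "TrajectoryDistanceMatrix",
    "TrajectoryDistance",
    "transform_trajectories",
    "pearson_distance",
    "dtw_distance",
    "build_distance_matrix",
]


@dataclass(frozen=True)
class TrajectoryDistanceMatrix:
    """Symmetric pairwise distances between barcode trajectories."""

    ids: list[str]
    d: np.ndarray
    metric: str  # "pearson" | "dtw"
    transform: str  # "linear" | "log10_floored"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.ids):
            raise ValueError("ids length must match matrix size")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "ids", list(self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)


def transform_trajectories(fm: FrequencyMatrix, transform: str = "log10_floored") -> np.ndarray:
    """Trajectory matrix on the requested scale.

    ``linear`` returns the frequencies unchanged; ``log10_floored`` returns
    ``log10(max(f, floor))`` using the matrix's detection floor.
    """
    if transform == "linear":
        return fm.freqs.copy()
    if transform == "log10_floored":
        return np.log10(np.maximum(fm.freqs, fm.floor))
    raise ValueError(f"unknown transform {transform!r}")


def pearson_distance(x, y) -> float:
    """Correlation distance ``1 - r`` in [0, 2].

    Both trajectories must have length >= 3 and nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("trajectories must be 1-D, equal length >= 3")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(
                f"trajectory {name} is constant; Pearson correlation is "
                "undefined (consider filtering it out)"
            )
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(xm @ ym / np.sqrt((xm @ xm) * (ym @ ym)))
    return 1.0 - r


@njit(cache=False)
def _dtw_dp(x, y, window):  # pragma: no cover - numba-compiled
    n, m = x.shape[0], y.shape[0]
    big = np.inf
    acc = np.full((n + 1, m + 1), big)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        lo = 1 if window < 0 else max(1, i - window)
        hi = m if window < 0 else min(m, i + window)
        for j in range(lo, hi + 1):
            c = abs(x[i - 1] - y[j - 1])
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = c + best
    return acc[n, m]


def dtw_distance(x, y, window: int | None = None) -> float:
    """Dynamic time warping distance (cumulative |difference| cost).

    ``window`` is the Sakoe-Chiba band half-width; it must admit at least
    one monotone path, i.e. ``window >= |len(x) - len(y)|``. ``None`` leaves
    warping unconstrained.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.size == 0 or y.size == 0:
        raise ValueError("trajectories must be non-empty 1-D arrays")
    if window is not None:
        if window < abs(x.size - y.size):
            raise ValueError(
                f"window {window} smaller than length difference "
                f"{abs(x.size - y.size)}; no warping path exists"
            )
        w = int(window)
    else:
        w = -1
    return float(_dtw_dp(x, y, w))


class TrajectoryDistance(TransformerMixin, BaseEstimator):
    """Transformer mapping a frequency matrix to pairwise trajectory distances.

    ``transform(X)`` returns the symmetric (n_barcodes x n_barcodes) distance
    matrix of the rows of ``X`` under the configured metric and scale. The
    floor for the log scale is a constructor parameter because a plain array
    carries no detection-floor metadata.

    Parameters
    ----------
    metric : {"pearson", "dtw"}, default="pearson"
    trajectory_transform : {"log10_floored", "linear"}, default="log10_floored"
    floor : float, default=1e-6
        Pseudo-frequency for zeros on the log scale.
    window : int or None, default=None
        Sakoe-Chiba half-width for DTW.
    """

    def __init__(self, metric: str = "pearson",
                 trajectory_transform: str = "log10_floored",
                 floor: float = 1e-6, window: int | None = None):
        self.metric = metric
        self.trajectory_transform = trajectory_transform
        self.floor = floor
        self.window = window

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = check_array(X)
        if self.trajectory_transform == "log10_floored":
            T = np.log10(np.maximum(X, self.floor))
        elif self.trajectory_transform == "linear":
            T = np.asarray(X, dtype=float)
        else:
            raise ValueError(f"unknown transform {self.trajectory_transform!r}")
        if self.metric == "pearson":
            return _pearson_matrix(T)
        if self.metric == "dtw":
            return _dtw_matrix(T, self.window)
        raise ValueError(f"unknown metric {self.metric!r}")

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def _pearson_matrix(T: np.ndarray, ids: list[str] | None = None) -> np.ndarray:
    sd = T.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = ids[bad[0]] if ids is not None else f"row {bad[0]}"
        raise ValueError(
            f"trajectory of {name} is constant; Pearson correlation is "
            "undefined (consider filtering it out)"
        )
    if T.shape[1] < 3:
        raise ValueError("Pearson distance requires >= 3 timepoints")
    r = np.corrcoef(T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return (d + d.T) / 2.0


def _dtw_matrix(T: np.ndarray, window: int | None) -> np.ndarray:
    n = T.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dtw_distance(T[i], T[j], window)
    return d


def build_distance_matrix(
    fm: FrequencyMatrix,
    metric: str = "pearson",
    transform: str = "log10_floored",
    window: int | None = None,
) -> TrajectoryDistanceMatrix:
    """Pairwise distance matrix over all barcode trajectories of ``fm``."""
    if fm.n_barcodes < 2:
        raise ValueError("need at least 2 barcodes to build a distance matrix")
    T = transform_trajectories(fm, transform)
    if metric == "pearson":
        d = _pearson_matrix(T, fm.barcode_ids)
    elif metric == "dtw":
        d = _dtw_matrix(T, window)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return TrajectoryDistanceMatrix(fm.barcode_ids, d, metric, transform)
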