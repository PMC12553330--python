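"""Locally weighted polynomial regression (LOESS) for consensus trajectories.

A cluster's consensus is the LOESS fit through the pooled (time, value)
points of all member trajectories, evaluated on the common timepoint grid.
Local degree 1 or 2 with tricube weights; the neighbourhood at each
evaluation point is the fraction ``span`` of the pooled points nearest in
time. Degenerate neighbourhoods (too few distinct times for the requested
degree) fall back to the weighted local mean; series with too few points for
any local window fall back to the pointwise mean with a warning.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

__all__ = ["loess_smooth", "loess_consensus"]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def loess_smooth(x, y, eval_x, span: float = 0.75, degree: int = 2) -> np.ndarray:
    """LOESS fit of scattered (x, y) evaluated at ``eval_x``.

    ``span`` in (0, 1] is the fraction of points in each local window;
    ``degree`` is 1 (local linear) or 2 (local quadratic).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    eval_x = np.asarray(eval_x, dtype=float).ravel()
    if x.size != y.size or x.size == 0:
        raise ValueError("x and y must be non-empty and equally sized")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")

    k = max(int(math.ceil(span * x.size)), degree + 1)
    k = min(k, x.size)
    out = np.empty(eval_x.size)
    for idx, x0 in enumerate(eval_x):
        dist = np.abs(x - x0)
        order = np.argsort(dist, kind="stable")[:k]
        h = dist[order[-1]]
        if h == 0:
            # all window points at x0 exactly
            out[idx] = y[order].mean()
            continue
        w = _tricube(dist[order] / h)
        pos = w > 0
        xs, ys, ws = x[order][pos], y[order][pos], w[pos]
        out[idx] = _weighted_polyfit_eval(xs, ys, ws, x0, degree)
    return out


def _weighted_polyfit_eval(xs, ys, ws, x0, degree) -> float:
    if np.unique(xs).size <= degree:
        return float(np.average(ys, weights=ws))
    # centre at x0 for conditioning; prediction is the constant coefficient
    A = np.vander(xs - x0, degree + 1, increasing=True)
    sw = np.sqrt(ws)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], ys * sw, rcond=None)
    return float(coef[0])


def loess_consensus(
    members: np.ndarray,
    timepoints: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Consensus trajectory of a cluster on its common timepoint grid.

    ``members`` is an (n_members, n_timepoints) matrix; all member points are
    pooled unweighted and smoothed. With fewer pooled points than a local
    polynomial needs, the pointwise mean is returned with a warning.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    timepoints = np.asarray(timepoints, dtype=float)
    if members.shape[1] != timepoints.size:
        raise ValueError("members and timepoints disagree on length")
    if members.size == 0:
        raise ValueError("consensus of an empty cluster is undefined")
    x = np.tile(timepoints, members.shape[0])
    y = members.ravel()
    if np.unique(timepoints).size <= degree:
        warnings.warn(
            "too few timepoints for the local polynomial; "
            "falling back to the pointwise mean",
            stacklevel=2,
        )
        return members.mean(axis=0)
    return loess_smooth(x, y, timepoints, span=span, degree=degree)
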