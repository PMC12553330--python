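"""Data model and I/O for barcode lineage time series.

A barcoded population is observed as a long-format table of
``(barcode ID, timepoint, read count)`` rows, typically produced by amplicon
sequencing of a chromosomal barcode locus over a serial-passaging experiment.
This module holds the two shared containers every downstream stage consumes:

``BarcodeTimeSeries``
    the integer count matrix on the full (barcode x timepoint) grid, and

``FrequencyMatrix``
    the column-normalized frequencies ``f_k(t)`` together with the
    pseudo-frequency *floor* substituted for zeros by log-space consumers
    (plots, log-scale trajectory distances). The floor is never applied to
    the stored frequencies themselves.

Absent (barcode, timepoint) pairs are treated as zero counts (sequencing
non-detection), not as missing data.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BarcodeTimeSeries",
    "FrequencyMatrix",
    "DEFAULT_COLUMNS",
    "read_barcode_table",
    "write_barcode_table",
    "to_frequencies",
]

#: Default header names for the long-format table: barcode ID, sample time, reads.
DEFAULT_COLUMNS = ("ID", "Time", "Reads")


class BarcodeTableError(ValueError):
    """Raised when a barcode table violates the input contract."""


@dataclass(frozen=True)
class BarcodeTimeSeries:
    """Read counts per barcode per timepoint on a dense grid.

    Parameters
    ----------
    barcode_ids : list of str
        Unique, opaque barcode identifiers (row order of ``counts``).
    timepoints : ndarray of float
        Strictly increasing sample times (generations or days; units are
        opaque and never converted).
    counts : ndarray of int, shape (n_barcodes, n_timepoints)
        Non-negative read counts.
    """

    barcode_ids: list[str]
    timepoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise BarcodeTableError("counts must be a 2-D (barcode x timepoint) matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise BarcodeTableError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise BarcodeTableError("counts must be non-negative")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.ndim != 1 or counts.shape[1] != tp.size:
            raise BarcodeTableError("timepoints length must match counts columns")
        if tp.size > 1 and not np.all(np.diff(tp) > 0):
            raise BarcodeTableError("timepoints must be strictly increasing")
        if len(self.barcode_ids) != counts.shape[0]:
            raise BarcodeTableError("barcode_ids length must match counts rows")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            raise BarcodeTableError("duplicate barcode IDs")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "timepoints", tp)
        object.__setattr__(self, "barcode_ids", list(self.barcode_ids))

    @property
    def totals(self) -> np.ndarray:
        """Summed reads per timepoint."""
        return self.counts.sum(axis=0)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcode_ids)

    @property
    def n_timepoints(self) -> int:
        return self.timepoints.size

    def to_long(self, column_names: tuple[str, str, str] = DEFAULT_COLUMNS,
                drop_zeros: bool = True) -> pd.DataFrame:
        """Long-format (ID, Time, Reads) view; zero-count rows elided by default."""
        idc, timec, readc = column_names
        n_b, n_t = self.counts.shape
        df = pd.DataFrame(
            {
                idc: np.repeat(np.asarray(self.barcode_ids, dtype=object), n_t),
                timec: np.tile(self.timepoints, n_b),
                readc: self.counts.ravel(),
            }
        )
        if drop_zeros:
            df = df[df[readc] > 0].reset_index(drop=True)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BarcodeTimeSeries):
            return NotImplemented
        return (
            self.barcode_ids == other.barcode_ids
            and np.array_equal(self.timepoints, other.timepoints)
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class FrequencyMatrix:
    """Barcode frequencies ``f_k(t)`` with metadata.

    ``freqs`` columns sum to 1 over all barcodes present at construction;
    a *filtered* matrix keeps the original population fractions and its
    columns may sum to less than 1. ``floor`` is the pseudo-frequency used
    in place of zero by log-space consumers.
    """

    barcode_ids: list[str]
    timepoints: np.ndarray
    freqs: np.ndarray
    floor: float
    filtered: bool = field(default=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise BarcodeTableError("frequencies must lie in [0, 1]")
        if not self.filtered:
            colsums = f.sum(axis=0)
            if f.shape[0] and not np.allclose(colsums, 1.0, atol=1e-9, rtol=0):
                raise BarcodeTableError(
                    f"frequency columns must sum to 1 (got {colsums})"
                )
        if not self.floor > 0:
            raise BarcodeTableError("floor must be positive")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "timepoints", np.asarray(self.timepoints, dtype=float))
        object.__setattr__(self, "barcode_ids", list(self.barcode_ids))

    @property
    def n_barcodes(self) -> int:
        return len(self.barcode_ids)

    @property
    def n_timepoints(self) -> int:
        return self.timepoints.size

    def restrict(self, mask: np.ndarray) -> "FrequencyMatrix":
        """Row-subset without renormalization (fractions of the whole population)."""
        mask = np.asarray(mask, dtype=bool)
        ids = [b for b, m in zip(self.barcode_ids, mask) if m]
        return FrequencyMatrix(ids, self.timepoints, self.freqs[mask], self.floor,
                               filtered=True)


def read_barcode_table(
    path: str | os.PathLike | io.TextIOBase,
    delimiter: str = ",",
    column_names: tuple[str, str, str] = DEFAULT_COLUMNS,
) -> BarcodeTimeSeries:
    """Read a long-format (ID, Time, Reads) table into a dense grid.

    (barcode, time) pairs absent from the file receive count 0. Duplicate
    (barcode, time) rows, negative or non-integer counts and missing columns
    raise :class:`BarcodeTableError`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={column_names[0]: str})
    idc, timec, readc = column_names
    for col in (idc, timec, readc):
        if col not in df.columns:
            raise BarcodeTableError(f"missing required column {col!r}")
    reads = pd.to_numeric(df[readc], errors="coerce")
    bad = reads.isna() | (reads < 0) | (reads != np.floor(reads))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise BarcodeTableError(
            f"count {df[readc].iloc[row]!r} at data row {row} is not a "
            "non-negative integer"
        )
    if df.duplicated(subset=[idc, timec]).any():
        dup = df[df.duplicated(subset=[idc, timec])].iloc[0]
        raise BarcodeTableError(
            f"duplicate (barcode, time) row: ({dup[idc]!r}, {dup[timec]!r})"
        )
    times = np.unique(pd.to_numeric(df[timec]).to_numpy(dtype=float))
    barcodes = sorted(df[idc].astype(str).unique())
    wide = (
        df.assign(**{readc: reads.astype(np.int64), timec: pd.to_numeric(df[timec])})
        .pivot(index=idc, columns=timec, values=readc)
        .reindex(index=barcodes, columns=times)
        .fillna(0)
        .to_numpy(dtype=np.int64)
    )
    return BarcodeTimeSeries(barcodes, times, wide)


def write_barcode_table(
    ts: BarcodeTimeSeries,
    path: str | os.PathLike | io.TextIOBase,
    delimiter: str = ",",
    column_names: tuple[str, str, str] = DEFAULT_COLUMNS,
) -> None:
    """Write a series back to long format (zero-count rows elided).

    Round-trips: ``read_barcode_table(write_barcode_table(ts)) == ts`` as long
    as no barcode or timepoint has all-zero counts (those rows/columns are not
    representable in a sparse long table).
    """
    ts.to_long(column_names).to_csv(path, sep=delimiter, index=False)


def to_frequencies(
    ts: BarcodeTimeSeries,
    floor_policy: str | float = "half_min_detectable",
) -> FrequencyMatrix:
    """Column-normalize counts to frequencies and fix the zero floor.

    ``floor_policy`` is either ``"half_min_detectable"`` — half of the smallest
    detectable frequency at the deepest timepoint, ``1 / (2 * max_t totals[t])``
    — or a fixed positive float.
    """
    totals = ts.totals
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise BarcodeTableError(
            f"timepoint {ts.timepoints[zero[0]]} has zero total reads"
        )
    freqs = ts.counts / totals[np.newaxis, :]
    if floor_policy == "half_min_detectable":
        floor = 1.0 / (2.0 * float(totals.max()))
    else:
        floor = float(floor_policy)
        if floor <= 0:
            raise BarcodeTableError("fixed floor must be positive")
    return FrequencyMatrix(ts.barcode_ids, ts.timepoints, freqs, floor)
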