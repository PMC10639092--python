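"""Parcellated BOLD time-series preprocessing.

Operates on region-averaged signals only (no image-domain steps): dummy
volume removal, demeaning/linear detrending, zero-phase Butterworth
band-pass filtering (default 0.01-0.08 Hz), confound expansion
(derivatives, squares, squared derivatives) and nuisance regression.

The canonical stage order, applied by :func:`clean_timeseries`, is

    remove volumes -> detrend/demean -> band-pass -> confound regression

with the expanded confounds passed through the same band-pass before the
regression so the filtered signal is not re-contaminated with frequencies
outside the passband.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import (
    DataAlignmentError,
    InputLengthError,
    SamplingRateError,
)

log = logging.getLogger(__name__)

DEFAULT_LOW_HZ = 0.01
DEFAULT_HIGH_HZ = 0.08
DEFAULT_FILTER_ORDER = 2
DEFAULT_DROP_VOLUMES = 4


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """T x N matrix of per-region BOLD signal with its repetition time."""

    values: np.ndarray = field(repr=False)
    tr_seconds: float
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if values.ndim != 2:
            raise DataAlignmentError("time series must be a 2-D (T x N) matrix")
        if values.shape[1] != len(self.node_labels):
            raise DataAlignmentError(
                f"{values.shape[1]} columns but {len(self.node_labels)} node labels"
            )
        if not np.all(np.isfinite(values)):
            raise DataAlignmentError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise SamplingRateError("tr_seconds must be > 0")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "TimeSeriesMatrix":
        return replace(self, values=values)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, columns=list(self.node_labels)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, tr_seconds: float) -> "TimeSeriesMatrix":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame.to_numpy(float), tr_seconds, tuple(frame.columns))


@dataclass(frozen=True)
class ConfoundMatrix:
    """T x K matrix of nuisance regressors with column labels."""

    values: np.ndarray = field(repr=False)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 2 or values.shape[1] != len(self.labels):
            raise DataAlignmentError("confound matrix shape does not match labels")
        if not np.all(np.isfinite(values)):
            raise DataAlignmentError("confound matrix contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, columns=list(self.labels)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "ConfoundMatrix":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame.to_numpy(float), tuple(frame.columns))


def remove_initial_volumes(ts: TimeSeriesMatrix, k: int = DEFAULT_DROP_VOLUMES) -> TimeSeriesMatrix:
    """Drop the first ``k`` volumes (steady-state magnetization dummies)."""
    if k < 0:
        raise InputLengthError("k must be >= 0")
    if k >= ts.n_volumes:
        raise InputLengthError(
            f"cannot remove {k} volumes from a series of length {ts.n_volumes}"
        )
    return ts.with_values(ts.values[k:])


def remove_initial_rows(c: ConfoundMatrix, k: int = DEFAULT_DROP_VOLUMES) -> ConfoundMatrix:
    """Same removal for a confound matrix, keeping rows aligned."""
    if k < 0 or k >= c.n_volumes:
        raise InputLengthError(f"cannot remove {k} rows from {c.n_volumes}")
    return ConfoundMatrix(c.values[k:], c.labels)


def detrend_demean(ts: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Remove, per column, the least-squares linear trend and the mean."""
    if ts.n_volumes < 3:
        raise InputLengthError("detrending requires at least 3 volumes")
    return ts.with_values(sps.detrend(ts.values, axis=0, type="linear"))


def _butter_bandpass(low_hz: float, high_hz: float, order: int, fs: float):
    nyquist = fs / 2.0
    if not 0 < low_hz < high_hz:
        raise SamplingRateError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise SamplingRateError(
            f"high_hz={high_hz} is at or above the Nyquist frequency {nyquist:.4g}"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs)


def _filtfilt(values: np.ndarray, b, a, order: int) -> np.ndarray:
    # reflective padding of length 3*(2*order+1) to suppress edge transients
    padlen = 3 * (2 * order + 1)
    if values.shape[0] <= padlen:
        raise InputLengthError(
            f"series of length {values.shape[0]} too short for filter padding {padlen}"
        )
    return sps.filtfilt(b, a, values, axis=0, padtype="even", padlen=padlen)


def bandpass(
    ts: TimeSeriesMatrix,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass, applied forward-backward per column.

    The forward-backward pass doubles the effective order and cancels the
    filter's phase response, which preserves the lag structure on which
    the correlation-based connectivity depends.
    """
    b, a = _butter_bandpass(low_hz, high_hz, order, fs=1.0 / ts.tr_seconds)
    return ts.with_values(_filtfilt(ts.values, b, a, order))


def bandpass_confounds(
    c: ConfoundMatrix,
    tr_seconds: float,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> ConfoundMatrix:
    """Apply the identical band-pass to a confound matrix."""
    b, a = _butter_bandpass(low_hz, high_hz, order, fs=1.0 / tr_seconds)
    return ConfoundMatrix(_filtfilt(c.values, b, a, order), c.labels)


def expand_confounds(c: ConfoundMatrix) -> ConfoundMatrix:
    """Expand K base regressors to 4K: originals, backward-difference
    derivatives (leading row zero), squares, and squared derivatives."""
    if c.values.shape[1] < 1:
        raise DataAlignmentError("need at least one confound column")
    x = c.values
    dx = np.zeros_like(x)
    dx[1:] = np.diff(x, axis=0)
    blocks = np.hstack([x, dx, x**2, dx**2])
    labels = (
        list(c.labels)
        + [f"{lab}_dt" for lab in c.labels]
        + [f"{lab}_sq" for lab in c.labels]
        + [f"{lab}_dtsq" for lab in c.labels]
    )
    return ConfoundMatrix(blocks, labels)


def regress_confounds(ts: TimeSeriesMatrix, c_expanded: ConfoundMatrix) -> TimeSeriesMatrix:
    """Residualize every node signal on [intercept | confounds].

    Uses a minimum-norm least-squares solve, so a rank-deficient design
    (e.g. constant confounds duplicating the intercept) degrades
    gracefully; a warning is logged in that case.
    """
    if ts.n_volumes != c_expanded.n_volumes:
        raise DataAlignmentError(
            f"time series has {ts.n_volumes} rows, confounds {c_expanded.n_volumes}"
        )
    design = np.column_stack([np.ones(ts.n_volumes), c_expanded.values])
    beta, _, rank, _ = np.linalg.lstsq(design, ts.values, rcond=None)
    if rank < design.shape[1]:
        log.warning(
            "confound design matrix is rank deficient (rank %d < %d); "
            "minimum-norm solution used",
            rank,
            design.shape[1],
        )
    return ts.with_values(ts.values - design @ beta)


def clean_timeseries(
    ts: TimeSeriesMatrix,
    confounds: ConfoundMatrix,
    drop_volumes: int = DEFAULT_DROP_VOLUMES,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    add_global_signal: bool = False,
) -> TimeSeriesMatrix:
    """Run the full cleaning pipeline in the canonical order.

    With ``add_global_signal`` the node-mean signal joins the base
    confounds as a ninth regressor (36 columns after expansion instead
    of 32).
    """
    if ts.n_volumes != confounds.n_volumes:
        raise DataAlignmentError("time series and confounds must have equal length")
    log.info(
        "cleaning pipeline: drop=%d -> detrend/demean -> bandpass "
        "[%g, %g] Hz order %d (zero-phase) -> 4x-expanded confound regression "
        "(confounds band-passed with the same filter; global signal %s)",
        drop_volumes,
        low_hz,
        high_hz,
        order,
        "added" if add_global_signal else "not added",
    )
    ts = remove_initial_volumes(ts, drop_volumes)
    conf = remove_initial_rows(confounds, drop_volumes)
    if add_global_signal:
        conf = ConfoundMatrix(
            np.column_stack([conf.values, ts.values.mean(axis=1)]),
            conf.labels + ("global_signal",),
        )
    ts = detrend_demean(ts)
    ts = bandpass(ts, low_hz, high_hz, order)
    conf = expand_confounds(conf)
    conf = bandpass_confounds(conf, ts.tr_seconds, low_hz, high_hz, order)
    return regress_confounds(ts, conf)
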