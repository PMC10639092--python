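"""Weighted functional-connectivity network construction.

Per subject: Pearson correlation between every pair of region signals,
Fisher r-to-z variance stabilization, zeroing of negative weights
(whose physiological meaning is contested), proportional density
thresholding over a sweep of densities, and trapezoidal area-under-curve
integration of any metric across that sweep.

The fixed pipeline order is: correlation -> Fisher -> zero negatives ->
threshold.  Thresholding keeps the strongest K = round(d * N(N-1)/2)
edges *with their weights* (the networks stay weighted); ties at the
cutoff are broken by ascending (i, j) node-pair order so the result is
deterministic and the edge sets are nested across densities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleaning import TimeSeriesMatrix
from .exceptions import DataAlignmentError

log = logging.getLogger(__name__)

DEFAULT_D_MIN = 0.05
DEFAULT_D_MAX = 0.40
DEFAULT_D_STEP = 0.05


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N weighted matrix with zero diagonal."""

    weights: np.ndarray = field(repr=False)
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DataAlignmentError("connectivity matrix must be square")
        if w.shape[0] != len(self.node_labels):
            raise DataAlignmentError("node labels do not match matrix size")
        if not np.allclose(w, w.T, atol=1e-12):
            raise DataAlignmentError("connectivity matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise DataAlignmentError("connectivity matrix must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.weights, columns=list(self.node_labels)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame.to_numpy(float), tuple(frame.columns))


@dataclass(frozen=True)
class ThresholdedNetworkSet:
    """Weighted adjacency per density, densities strictly increasing."""

    densities: tuple[float, ...]
    adjacencies: tuple[np.ndarray, ...] = field(repr=False)
    node_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "densities", tuple(float(d) for d in self.densities))
        object.__setattr__(self, "adjacencies", tuple(self.adjacencies))
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        if len(self.densities) != len(self.adjacencies):
            raise DataAlignmentError("densities and adjacencies differ in length")
        if any(b <= a for a, b in zip(self.densities, self.densities[1:])):
            raise DataAlignmentError("densities must be strictly increasing")

    def __len__(self) -> int:
        return len(self.densities)


def correlation_matrix(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between every pair of node signals.

    Zero-variance nodes (flat signals) get zero correlation with every
    other node; this is logged rather than fatal.
    """
    if ts.n_volumes < 3:
        raise DataAlignmentError("need at least 3 volumes for correlation")
    values = ts.values
    sd = values.std(axis=0)
    flat = sd == 0
    if flat.any():
        log.warning(
            "%d zero-variance node(s); their correlations set to 0", int(flat.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(r, ts.node_labels)


def fisher_transform(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Element-wise Fisher r-to-z (arctanh); |r| = 1 clipped just inside."""
    w = m.weights.copy()
    clip = 1.0 - 1e-7
    extreme = np.abs(w) >= 1.0
    if extreme.any():
        log.warning("%d correlation(s) at +/-1 clipped before arctanh", int(extreme.sum()))
        w = np.clip(w, -clip, clip)
    z = np.arctanh(w)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, m.node_labels)


def zero_negatives(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Replace negative weights by zero; non-negative weights unchanged."""
    return ConnectivityMatrix(np.where(m.weights < 0, 0.0, m.weights), m.node_labels)


def _edge_order(w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    iu, ju = np.triu_indices(w.shape[0], k=1)
    weights = w[iu, ju]
    # np.lexsort: last key is primary
    order = np.lexsort((ju, iu, -weights))
    return iu[order], ju[order], weights[order]


def edge_count_for_density(n: int, d: float) -> int:
    """Number of edges at proportional density d (round half up)."""
    m_total = n * (n - 1) // 2
    return int(math.floor(d * m_total + 0.5))


def threshold_density(m: ConnectivityMatrix, d: float) -> np.ndarray:
    """Keep the K strongest edges (weights retained), zero the rest."""
    if not 0 < d <= 1:
        raise DataAlignmentError("density must be in (0, 1]")
    w = m.weights
    if np.any(w < 0):
        raise DataAlignmentError("thresholding expects a non-negative matrix")
    n = m.n_nodes
    k = edge_count_for_density(n, d)
    iu, ju, weights = _edge_order(w)
    available = int(np.count_nonzero(weights > 0))
    if available < k:
        log.warning(
            "only %d nonzero edges available for density %.3g (needs %d); keeping all",
            available,
            d,
            k,
        )
        k = available
    out = np.zeros_like(w)
    keep_i, keep_j = iu[:k], ju[:k]
    out[keep_i, keep_j] = w[keep_i, keep_j]
    out[keep_j, keep_i] = w[keep_j, keep_i]
    return out


def density_grid(
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    step: float = DEFAULT_D_STEP,
) -> tuple[float, ...]:
    """The density sweep grid, e.g. 0.05, 0.10, ..., 0.40."""
    if not (0 < d_min <= d_max <= 1) or step <= 0:
        raise DataAlignmentError("invalid density grid")
    n_steps = int(round((d_max - d_min) / step))
    if abs(d_min + n_steps * step - d_max) > 1e-9:
        raise DataAlignmentError("density grid step does not divide the range")
    return tuple(round(d_min + i * step, 10) for i in range(n_steps + 1))


def density_sweep(
    m: ConnectivityMatrix,
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    step: float = DEFAULT_D_STEP,
) -> ThresholdedNetworkSet:
    """Threshold at every density of the grid (default 8 networks)."""
    densities = density_grid(d_min, d_max, step)
    adjacencies = tuple(threshold_density(m, d) for d in densities)
    return ThresholdedNetworkSet(densities, adjacencies, m.node_labels)


def auc_integrate(values, densities) -> float:
    """Trapezoidal area under a metric-versus-density curve."""
    values = np.asarray(values, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if values.shape != densities.shape:
        raise DataAlignmentError("values and densities must have equal length")
    if values.size < 2:
        raise DataAlignmentError("AUC integration needs at least 2 points")
    if np.any(np.diff(densities) <= 0):
        raise DataAlignmentError("densities must be strictly increasing")
    return float(np.trapezoid(values, densities))


def build_connectome(
    ts: TimeSeriesMatrix,
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    step: float = DEFAULT_D_STEP,
) -> tuple[ConnectivityMatrix, ThresholdedNetworkSet]:
    """Full construction: correlation -> Fisher -> zero negatives -> sweep."""
    log.info(
        "connectome pipeline: correlation -> Fisher r-to-z -> zero negatives -> "
        "density sweep [%g, %g] step %g (weighted, round-half-up edge counts, "
        "lexicographic tie-break)",
        d_min,
        d_max,
        step,
    )
    fc = zero_negatives(fisher_transform(correlation_matrix(ts)))
    return fc, density_sweep(fc, d_min, d_max, step)
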