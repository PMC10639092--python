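"""Weighted undirected graph measures, implemented from scratch.

The measure set covers segregation (clustering coefficient, local
efficiency, modularity), integration (global efficiency, nodal
efficiency), centrality (betweenness) and network strength, on
non-negative weighted adjacency matrices with zero diagonal.

Conventions (fixed and logged by :func:`compute_all_metrics`):

* edge length for shortest paths is the inverse weight, ``L = 1/w``;
  unreachable pairs have infinite distance and contribute zero
  efficiency;
* the clustering coefficient is the Onnela geometric-mean-of-triangles
  form with weights normalized by the matrix maximum;
* local efficiency is the (weighted) global efficiency of the subgraph
  induced by a node's neighbours (a cube-root variant is available);
* betweenness uses Brandes' algorithm on weighted lengths, unnormalized
  with undirected path counts halved; the global summary is the node
  mean;
* modularity is Newman's weighted Q optimized by Louvain with a fixed
  number of seeded restarts.
"""

from __future__ import annotations

import heapq
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ThresholdedNetworkSet, auc_integrate
from .exceptions import DataAlignmentError, DegenerateInputError

log = logging.getLogger(__name__)

NODAL_METRIC_NAMES = (
    "strength",
    "clustering_coefficient",
    "local_efficiency",
    "nodal_efficiency",
    "betweenness_centrality",
)
GLOBAL_METRIC_NAMES = (
    "strength",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "betweenness_centrality",
    "modularity",
)


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise DataAlignmentError("adjacency must be square")
    if np.any(adj < 0):
        raise DataAlignmentError("adjacency must be non-negative")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise DataAlignmentError("adjacency must be symmetric")
    return adj


def _lengths(adj: np.ndarray) -> np.ndarray:
    """Edge lengths 1/w (inf where there is no edge), zero diagonal."""
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / adj, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    d = lengths.copy()
    for k in range(d.shape[0]):
        np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :], out=d)
    return d


def _dijkstra_all(lengths: np.ndarray) -> np.ndarray:
    n = lengths.shape[0]
    neighbors = [np.flatnonzero(np.isfinite(lengths[i]) & (np.arange(n) != i)) for i in range(n)]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        d = dist[s]
        d[s] = 0.0
        heap = [(0.0, s)]
        done = np.zeros(n, dtype=bool)
        while heap:
            du, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            for v in neighbors[u]:
                nd = du + lengths[u, v]
                if nd < d[v]:
                    d[v] = nd
                    heapq.heappush(heap, (nd, v))
    return dist


def shortest_paths(adj: np.ndarray, method: str = "dijkstra") -> np.ndarray:
    """All-pairs shortest path lengths under edge length 1/weight.

    ``method`` selects Dijkstra per source (default) or a vectorized
    Floyd-Warshall; both are exact and are cross-checked in the test
    suite.  Unreachable pairs are ``inf``.
    """
    adj = _check_adjacency(adj)
    lengths = _lengths(adj)
    if method == "dijkstra":
        return _dijkstra_all(lengths)
    if method == "floyd-warshall":
        return _floyd_warshall(lengths)
    raise DataAlignmentError(f"unknown shortest-path method {method!r}")


def node_strength(adj: np.ndarray) -> np.ndarray:
    """Sum of edge weights incident to each node (row sums)."""
    return _check_adjacency(adj).sum(axis=1)


def _efficiency_from_distances(dist: np.ndarray) -> np.ndarray:
    """Per-node mean of inverse distances to all other nodes (1/inf = 0)."""
    n = dist.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 1.0 / dist, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_efficiency(adj: np.ndarray, dist: np.ndarray | None = None) -> np.ndarray:
    """For node i, the mean over j != i of 1 / d(i, j)."""
    adj = _check_adjacency(adj)
    if adj.shape[0] < 2:
        raise DegenerateInputError("nodal efficiency needs at least 2 nodes")
    if dist is None:
        dist = _floyd_warshall(_lengths(adj))
    return _efficiency_from_distances(dist)


def global_efficiency(adj: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Average inverse shortest path length over ordered node pairs."""
    return float(nodal_efficiency(adj, dist).mean())


def clustering_coefficient(adj: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering, weights normalized by the matrix max.

    C(i) = (1 / (k_i (k_i - 1))) * sum_{j != h} (w'_ij w'_jh w'_hi)^(1/3)
    with w' = w / max(w); C(i) = 0 for degree k_i < 2.
    """
    adj = _check_adjacency(adj)
    w_max = adj.max()
    if w_max == 0:
        return np.zeros(adj.shape[0])
    w_hat = np.cbrt(adj / w_max)
    cycles = np.diag(w_hat @ w_hat @ w_hat)
    degree = (adj > 0).sum(axis=1)
    denom = degree * (degree - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, cycles / denom, 0.0)
    return c


def local_efficiency(adj: np.ndarray, variant: str = "subgraph") -> np.ndarray:
    """Per-node local efficiency.

    ``subgraph`` (default): the weighted global efficiency of the
    subgraph induced by the node's neighbours (zero for fewer than two
    neighbours).  ``cuberoot``: a cube-root-weighted variant in which
    the neighbour subgraph distances are computed on cube-root weights
    and each inverse distance is weighted by the connection strengths to
    the centre node.
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        if variant == "subgraph":
            dist = _floyd_warshall(_lengths(sub))
            out[i] = _efficiency_from_distances(dist).mean()
        elif variant == "cuberoot":
            sw = np.cbrt(adj[i, nbrs])
            dist = _floyd_warshall(_lengths(np.cbrt(sub)))
            with np.errstate(divide="ignore"):
                inv = np.where(dist > 0, 1.0 / dist, 0.0)
            np.fill_diagonal(inv, 0.0)
            numer = float(sw @ inv @ sw)
            k = nbrs.size
            out[i] = numer / (k * (k - 1))
        else:
            raise DataAlignmentError(f"unknown local-efficiency variant {variant!r}")
    return out


def betweenness_centrality(adj: np.ndarray) -> np.ndarray:
    """Brandes betweenness on weighted lengths 1/w.

    Unnormalized shortest-path counts, halved because the graph is
    undirected (each geodesic is otherwise counted in both directions).
    """
    adj = _check_adjacency(adj)
    n = adj.shape[0]
    lengths = _lengths(adj)
    neighbors = [np.flatnonzero(adj[i] > 0) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        sigma = np.zeros(n)
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        settled_order: list[int] = []
        done = np.zeros(n, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            du, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            settled_order.append(u)
            for v in neighbors[u]:
                nd = du + lengths[u, v]
                if nd < dist[v]:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, v))
                elif nd == dist[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for u in reversed(settled_order):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    return bc / 2.0


def modularity_value(adj: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Newman weighted modularity of a partition, by the direct formula.

    Q = (1/2m) * sum_ij [w_ij - gamma * s_i s_j / 2m] delta(c_i, c_j).
    """
    adj = _check_adjacency(adj)
    labels = np.asarray(labels)
    m2 = adj.sum()
    if m2 == 0:
        raise DegenerateInputError("modularity is undefined for an edgeless graph")
    strength = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        w_in = adj[np.ix_(idx, idx)].sum()
        s_tot = strength[idx].sum()
        q += w_in / m2 - gamma * (s_tot / m2) ** 2
    return float(q)


def _louvain_level(b: np.ndarray, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """One Louvain level: local moving on the (possibly aggregated) matrix
    ``b`` (diagonal = twice the internal self-weight).  Returns community
    labels for the rows of ``b``."""
    # Convention: b[i, j] is the weight between super-nodes i and j and
    # b[i, i] the internal weight counted in both directions, so the
    # node strength is the plain row sum and 2m = b.sum().
    n = b.shape[0]
    m2 = b.sum()
    k = b.sum(axis=1)
    comm = np.arange(n)
    sigma_tot = k.copy()
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            # link weights from i to each community (self-loop excluded)
            row = b[i].copy()
            row[i] = 0.0
            w_ic = np.bincount(comm, weights=row, minlength=n)
            sigma_tot[ci] -= k[i]
            gains = w_ic - gamma * k[i] * sigma_tot / m2
            best = int(np.argmax(gains))
            # strict improvement over staying put, deterministic tie-break
            if gains[best] > gains[ci] + 1e-12:
                comm[i] = best
                improved = True
            sigma_tot[comm[i]] += k[i]
    return comm


def _aggregate(b: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, relabel = np.unique(comm, return_inverse=True)
    nc = uniq.size
    agg = np.zeros((nc, nc))
    for c in range(nc):
        idx = np.flatnonzero(relabel == c)
        for d in range(c, nc):
            jdx = np.flatnonzero(relabel == d)
            agg[c, d] = agg[d, c] = b[np.ix_(idx, jdx)].sum()
    return agg, relabel


def modularity_louvain(
    adj: np.ndarray,
    gamma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, float]:
    """Louvain optimization of weighted Newman modularity.

    Runs ``n_restarts`` seeded restarts (random node orders) and returns
    the best partition together with its Q recomputed by the direct
    formula, so the returned value always satisfies the definition.
    """
    adj = _check_adjacency(adj)
    if adj.sum() == 0:
        raise DegenerateInputError("modularity is undefined for an edgeless graph")
    n = adj.shape[0]
    best_q = -np.inf
    best_labels = np.zeros(n, dtype=int)
    for restart in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, restart]))
        labels = np.arange(n)
        b = adj.copy()
        while True:
            comm = _louvain_level(b, gamma, rng)
            agg, relabel = _aggregate(b, comm)
            labels = relabel[labels]
            if agg.shape[0] == b.shape[0]:
                break
            b = agg
        q = modularity_value(adj, labels, gamma)
        if q > best_q + 1e-15:
            best_q = q
            best_labels = labels.copy()
    # canonical labels: communities numbered by first appearance
    _, canonical = np.unique(best_labels, return_inverse=True)
    return canonical, float(best_q)


def subject_modularity_seed(subject_id: str) -> int:
    """Stable per-subject seed for the Louvain restarts (CRC-32 of the id)."""
    return zlib.crc32(subject_id.encode()) & 0x7FFFFFFF


@dataclass(frozen=True)
class MetricResult:
    """AUC-integrated and per-density metrics for one subject."""

    global_auc: pd.Series = field(repr=False)
    nodal_auc: pd.DataFrame = field(repr=False)
    per_density_global: pd.DataFrame = field(repr=False)  # densities x metrics
    per_density_nodal: pd.DataFrame = field(repr=False)  # tidy

    def to_tidy(self, subject_id: str) -> pd.DataFrame:
        """Tidy rows: subject_id, density ("AUC" or value), scope,
        node_label, metric, value."""
        rows = []
        for metric, value in self.global_auc.items():
            rows.append((subject_id, "AUC", "global", "", metric, value))
        for label, row in self.nodal_auc.iterrows():
            for metric, value in row.items():
                rows.append((subject_id, "AUC", "node", label, metric, value))
        for density, row in self.per_density_global.iterrows():
            for metric, value in row.items():
                rows.append((subject_id, str(density), "global", "", metric, value))
        for _, r in self.per_density_nodal.iterrows():
            rows.append(
                (subject_id, str(r["density"]), "node", r["node_label"], r["metric"], r["value"])
            )
        return pd.DataFrame(
            rows,
            columns=["subject_id", "density", "scope", "node_label", "metric", "value"],
        )


def metrics_at_density(
    adj: np.ndarray,
    include: tuple[str, ...],
    modularity_seed: int = 0,
    n_restarts: int = 10,
    local_variant: str = "subgraph",
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """All requested metrics on a single thresholded adjacency."""
    adj = _check_adjacency(adj)
    global_vals: dict[str, float] = {}
    nodal_vals: dict[str, np.ndarray] = {}
    need_dist = {"global_efficiency", "nodal_efficiency"} & set(include)
    dist = _floyd_warshall(_lengths(adj)) if need_dist else None
    if "strength" in include:
        s = node_strength(adj)
        nodal_vals["strength"] = s
        global_vals["strength"] = float(s.mean())
    if dist is not None:
        ne = _efficiency_from_distances(dist)
        if "nodal_efficiency" in include:
            nodal_vals["nodal_efficiency"] = ne
        if "global_efficiency" in include:
            global_vals["global_efficiency"] = float(ne.mean())
    if "clustering_coefficient" in include:
        c = clustering_coefficient(adj)
        nodal_vals["clustering_coefficient"] = c
        global_vals["clustering_coefficient"] = float(c.mean())
    if "local_efficiency" in include:
        le = local_efficiency(adj, variant=local_variant)
        nodal_vals["local_efficiency"] = le
        global_vals["local_efficiency"] = float(le.mean())
    if "betweenness_centrality" in include:
        bc = betweenness_centrality(adj)
        nodal_vals["betweenness_centrality"] = bc
        global_vals["betweenness_centrality"] = float(bc.mean())
    if "modularity" in include:
        if adj.sum() > 0:
            _, q = modularity_louvain(adj, seed=modularity_seed, n_restarts=n_restarts)
        else:
            q = 0.0
        global_vals["modularity"] = q
    return global_vals, nodal_vals


ALL_METRICS = tuple(dict.fromkeys(GLOBAL_METRIC_NAMES + NODAL_METRIC_NAMES))


def compute_all_metrics(
    net_set: ThresholdedNetworkSet,
    include: tuple[str, ...] | None = None,
    modularity_seed: int = 0,
    n_restarts: int = 10,
    local_variant: str = "subgraph",
) -> MetricResult:
    """Compute every metric at every density and integrate across density.

    Global scalars are node means (modularity excepted, which is global
    only) computed *before* integration; integration is the trapezoidal
    area under the metric-versus-density curve.  A single-density sweep
    cannot be integrated: the raw single-density values are returned with
    a warning.
    """
    include = tuple(include) if include is not None else ALL_METRICS
    unknown = set(include) - set(ALL_METRICS)
    if unknown:
        raise DataAlignmentError(f"unknown metrics {sorted(unknown)}")
    densities = list(net_set.densities)
    labels = list(net_set.node_labels)
    per_global: list[dict[str, float]] = []
    per_nodal: list[dict[str, np.ndarray]] = []
    for adj in net_set.adjacencies:
        g, nodal = metrics_at_density(
            adj, include, modularity_seed, n_restarts, local_variant
        )
        per_global.append(g)
        per_nodal.append(nodal)

    global_names = [m for m in GLOBAL_METRIC_NAMES if m in include]
    nodal_names = [m for m in NODAL_METRIC_NAMES if m in include]
    per_density_global = pd.DataFrame(per_global, index=densities)[global_names]

    single = len(densities) < 2
    if single:
        log.warning(
            "density sweep has a single density; returning raw metrics instead of AUC"
        )

    def integrate(values: np.ndarray) -> float:
        if single:
            return float(values[0])
        return auc_integrate(values, densities)

    global_auc = pd.Series(
        {m: integrate(per_density_global[m].to_numpy()) for m in global_names},
        name="AUC",
    )
    nodal_auc = pd.DataFrame(index=pd.Index(labels, name="node_label"))
    tidy_rows = []
    for m in nodal_names:
        stacked = np.vstack([nodal[m] for nodal in per_nodal])  # densities x nodes
        nodal_auc[m] = [integrate(stacked[:, i]) for i in range(len(labels))]
        for di, density in enumerate(densities):
            for i, lab in enumerate(labels):
                tidy_rows.append((density, lab, m, stacked[di, i]))
    per_density_nodal = pd.DataFrame(
        tidy_rows, columns=["density", "node_label", "metric", "value"]
    )
    return MetricResult(global_auc, nodal_auc, per_density_global, per_density_nodal)
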