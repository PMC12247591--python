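"""Global network measures on tract-count connectomes.

The connectivity matrix of tract counts is converted to a distance matrix by
taking reciprocals (strong anatomical connections are "short"), all-pairs
shortest paths are computed on that distance matrix, and the global measures
follow:

* **wCPL** — weighted characteristic path length, the arithmetic mean
  shortest-path length over connected node pairs.  Disconnected pairs are
  excluded from the average and counted, rather than making the metric
  infinite.
* **GE** — global efficiency, the mean inverse shortest-path length
  (disconnected pairs contribute 0).
* **CC** — mean weighted clustering coefficient, geometric-mean triangle
  form with weights normalized by the global maximum weight.
* **SWN** — small-worldness, here the plain ratio CC / wCPL; a normalized
  variant against degree-preserving rewired null networks is also provided
  because the plain ratio is scale-dependent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .io import CohortTable, ConnectivityMatrix

logger = logging.getLogger("connectopath")


class EmptyNetworkError(ValueError):
    """All node pairs are disconnected; path-based metrics are undefined."""


@dataclass
class DistanceMatrix:
    """Edge lengths: reciprocal tract counts, +inf where no tracts exist."""

    nodes: list[str]
    d: np.ndarray


@dataclass
class PathLengthMatrix:
    """All-pairs shortest-path distances on the inverse-weight graph."""

    nodes: list[str]
    splen: np.ndarray


@dataclass
class MetricRow:
    """Per-subject global network metrics."""

    subject_id: str
    wcpl: float
    cc: float
    ge: float
    swn: float
    log_swn: float
    n_disconnected_pairs: int


def to_distance(conn: ConnectivityMatrix) -> DistanceMatrix:
    """Reciprocal transform: d_ij = 1 / w_ij, +inf for absent edges."""
    w = conn.weights
    with np.errstate(divide="ignore", over="ignore"):
        # reciprocals of subnormal weights overflow to +inf, i.e. no edge
        d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(conn.nodes), d)


def shortest_paths(dist: DistanceMatrix) -> PathLengthMatrix:
    """All-pairs shortest paths (Dijkstra from each source, binary heap)."""
    d = dist.d
    n = d.shape[0]
    ii, jj = np.nonzero(np.isfinite(d) & (d > 0))
    graph = csr_matrix((d[ii, jj], (ii, jj)), shape=(n, n))
    splen = dijkstra(graph, directed=False)
    np.fill_diagonal(splen, 0.0)
    return PathLengthMatrix(list(dist.nodes), splen)


def _offdiag_pairs(splen: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(splen.shape[0], k=1)
    return splen[iu]


def wcpl(splen: PathLengthMatrix) -> tuple[float, int]:
    """Mean shortest-path length over connected unordered pairs.

    Returns the average and the number of disconnected pairs excluded from
    it (surfaced for QC).  Raises :class:`EmptyNetworkError` when every pair
    is disconnected.
    """
    vals = _offdiag_pairs(splen.splen)
    finite = np.isfinite(vals)
    n_disc = int((~finite).sum())
    if not finite.any():
        raise EmptyNetworkError("empty network: all node pairs disconnected")
    if n_disc:
        logger.warning("wCPL excludes %d disconnected pairs", n_disc)
    return float(vals[finite].mean()), n_disc


def global_efficiency(splen: PathLengthMatrix) -> float:
    """Mean inverse shortest-path length; disconnected pairs contribute 0."""
    vals = _offdiag_pairs(splen.splen)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals), 1.0 / vals, 0.0)
    return float(inv.mean())


def clustering_coefficient(conn: ConnectivityMatrix) -> float:
    """Mean weighted clustering coefficient (geometric-mean triangle form).

    Weights are normalized by the global maximum weight, so the value is
    invariant under uniform rescaling of tract counts; nodes with fewer than
    two neighbours contribute 0.
    """
    g = nx.from_numpy_array(conn.weights)
    g.remove_edges_from([(u, v) for u, v, w in g.edges(data="weight") if w == 0])
    return float(nx.average_clustering(g, weight="weight"))


def small_worldness(
    cc: float,
    wcpl_value: float,
    mode: str = "plain",
    null_ensemble: Sequence[ConnectivityMatrix] | None = None,
) -> float:
    """Small-worldness: CC / wCPL, optionally normalized by rewired nulls.

    In ``normalized`` mode both CC and wCPL are divided by their means over
    a null ensemble of degree-preserving rewirings before taking the ratio.
    """
    if wcpl_value <= 0:
        raise ValueError("wCPL must be positive to form the SWN ratio")
    if mode == "plain":
        return cc / wcpl_value
    if mode != "normalized":
        raise ValueError(f"unknown SWN mode {mode!r}")
    if not null_ensemble:
        raise ValueError("normalized SWN requires a non-empty null ensemble")
    cc_null = []
    wcpl_null = []
    for null in null_ensemble:
        cc_null.append(clustering_coefficient(null))
        w, _ = wcpl(shortest_paths(to_distance(null)))
        wcpl_null.append(w)
    cc_bar = float(np.mean(cc_null))
    wcpl_bar = float(np.mean(wcpl_null))
    if cc_bar <= 0 or wcpl_bar <= 0:
        raise ValueError("degenerate null ensemble (zero mean CC or wCPL)")
    return (cc / cc_bar) / (wcpl_value / wcpl_bar)


def rewire_null(
    conn: ConnectivityMatrix, n_swaps: int, seed: int
) -> ConnectivityMatrix:
    """Degree-preserving rewiring null model.

    Double-edge swaps on the binary topology preserve the degree sequence
    exactly; the original multiset of edge weights is then permuted onto the
    rewired edge set, preserving the weight distribution exactly.  Graphs
    that admit no legal swap are returned unchanged with a warning.
    """
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    g = nx.from_numpy_array((conn.weights > 0).astype(int))
    weights = conn.weights[np.triu_indices(conn.n_nodes, k=1)]
    weights = weights[weights > 0]
    try:
        nx.double_edge_swap(
            g, nswap=n_swaps, max_tries=max(100, 100 * n_swaps), seed=seed
        )
    except nx.NetworkXException as exc:
        logger.warning("rewiring impossible (%s); returning input unchanged", exc)
        return ConnectivityMatrix(list(conn.nodes), conn.weights.copy())
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(weights)
    w = np.zeros_like(conn.weights)
    for (u, v), wt in zip(sorted(g.edges()), shuffled):
        w[u, v] = wt
        w[v, u] = wt
    return ConnectivityMatrix(list(conn.nodes), w)


def subject_metrics(
    subject_id: str,
    conn: ConnectivityMatrix,
    swn_mode: str = "plain",
    n_nulls: int = 0,
    seed: int = 0,
) -> MetricRow:
    """Compute the full metric row for one subject's connectome."""
    splen = shortest_paths(to_distance(conn))
    w, n_disc = wcpl(splen)
    ge = global_efficiency(splen)
    cc = clustering_coefficient(conn)
    ensemble = None
    if swn_mode == "normalized":
        n_edges = int((conn.weights > 0).sum() // 2)
        ensemble = [
            rewire_null(conn, n_swaps=10 * n_edges, seed=seed + k)
            for k in range(max(1, n_nulls))
        ]
    swn = small_worldness(cc, w, mode=swn_mode, null_ensemble=ensemble)
    if swn <= 0:
        raise ValueError(
            f"subject {subject_id}: SWN = {swn:g} is not positive; "
            "log transform undefined"
        )
    return MetricRow(
        subject_id=subject_id,
        wcpl=w,
        cc=cc,
        ge=ge,
        swn=swn,
        log_swn=math.log(swn),
        n_disconnected_pairs=n_disc,
    )


def metrics_for_cohort(
    cohort: CohortTable,
    swn_mode: str = "plain",
    n_nulls: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """One metric row per subject, as a DataFrame indexed like the metadata."""
    rows = []
    for rec in cohort.records:
        try:
            rows.append(
                subject_metrics(
                    rec.subject_id,
                    cohort.matrices[rec.subject_id],
                    swn_mode=swn_mode,
                    n_nulls=n_nulls,
                    seed=seed,
                )
            )
        except Exception as exc:
            raise type(exc)(f"subject {rec.subject_id}: {exc}") from exc
    return pd.DataFrame([vars(r) for r in rows])
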