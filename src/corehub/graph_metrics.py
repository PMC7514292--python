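"""Shortest-path metrics on the directed NTE graph and hub identification.

NTE weights are flow-like (bigger = stronger coupling), so they are mapped
to path lengths by the reciprocal d = 1/w (absent edges, w = 0, become
infinite distance); a -log alternative is available.  On the resulting
directed distance graph:

* betweenness centrality of node i is the fraction of all-pairs shortest
  paths that pass through i, normalized by (n-1)(n-2) so BC lies in [0,1];
  tied shortest paths all count;
* the characteristic path length l is the mean shortest-path distance over
  ordered node pairs; unreachable pairs are excluded from the average with
  the pair count adjusted (and logged), which keeps l finite after node
  removal;
* a node is a hub when the one-sided Mann-Whitney test of its per-window
  BC samples against the pooled samples of all remaining nodes rejects
  "not higher" at the configured level (5% by default, per-node, no
  multiple-testing correction unless the Bonferroni switch is on);
* removal impact is the percent change of l after deleting a node set,
  with the full network as benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.stats import mannwhitneyu

from .connectivity import ConnectivityMatrix
from .io_core import ParameterError, logger

__all__ = [
    "DistanceMatrix",
    "weight_to_distance",
    "betweenness",
    "characteristic_path_length",
    "identify_hubs",
    "removal_impact",
]


@dataclass
class DistanceMatrix:
    """N x N shortest-hop lengths derived from connectivity weights."""

    distances: np.ndarray
    channel_labels: list[str]
    mapping: str = "reciprocal"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        n = len(self.channel_labels)
        if self.distances.shape != (n, n):
            raise ParameterError("distance matrix shape does not match labels")

    @property
    def n_nodes(self) -> int:
        return len(self.channel_labels)


def weight_to_distance(cm: ConnectivityMatrix, mapping: str | None = None) -> DistanceMatrix:
    """Convert NTE weights to edge lengths.

    ``reciprocal``: d = 1/w.  ``neglog``: d = -log(w / max(w)), so the
    strongest edge has length 0 and weaker edges grow logarithmically.
    Zero weights become +inf (edge absent); the diagonal stays 0.
    """
    mapping = mapping or cm.params.distance_mapping
    w = cm.weights
    with np.errstate(divide="ignore"):
        if mapping == "reciprocal":
            dist = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        elif mapping == "neglog":
            wmax = w.max()
            if wmax == 0:
                dist = np.full_like(w, np.inf)
            else:
                dist = np.where(w > 0, -np.log(np.where(w > 0, w, 1.0) / wmax), np.inf)
        else:
            raise ParameterError(f"unknown weight->distance mapping {mapping!r}")
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, list(cm.channel_labels), mapping)


def _to_digraph(dm: DistanceMatrix) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(dm.n_nodes))
    rows, cols = np.nonzero(np.isfinite(dm.distances))
    for i, j in zip(rows, cols):
        if i != j:
            g.add_edge(int(i), int(j), weight=float(dm.distances[i, j]))
    return g


def betweenness(dm: DistanceMatrix) -> dict[str, float]:
    """Per-node betweenness centrality in [0, 1] (ties all counted).

    Normalization is 1/((n-1)(n-2)), the directed-graph pair count, and
    source/target pairs with no connecting path contribute zero.
    """
    if dm.n_nodes < 3:
        raise ParameterError("betweenness normalization needs at least 3 nodes")
    g = _to_digraph(dm)
    bc = nx.betweenness_centrality(g, normalized=True, weight="weight")
    return {dm.channel_labels[i]: float(bc[i]) for i in range(dm.n_nodes)}


def _shortest_path_matrix(dm: DistanceMatrix) -> np.ndarray:
    # inf marks absent edges; explicit zero-length edges (neglog mapping)
    # survive the dense->csgraph conversion
    from scipy.sparse.csgraph import csgraph_from_dense

    graph = csgraph_from_dense(dm.distances, null_value=np.inf)
    return dijkstra(graph, directed=True)


def characteristic_path_length(dm: DistanceMatrix) -> float:
    """Mean shortest-path distance over reachable ordered pairs."""
    n = dm.n_nodes
    if n < 2:
        raise ParameterError("characteristic path length needs at least 2 nodes")
    sp = _shortest_path_matrix(dm)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(sp) & off
    n_pairs = int(finite.sum())
    if n_pairs == 0:
        raise ParameterError("graph is fully disconnected: no reachable pairs")
    n_total = n * (n - 1)
    if n_pairs < n_total:
        logger.info(
            "characteristic path length: %d of %d ordered pairs unreachable "
            "(excluded from the average)", n_total - n_pairs, n_total,
        )
    return float(sp[finite].mean())


def identify_hubs(
    bc_samples: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Flag hubs from per-window BC samples via one-sided Mann-Whitney tests.

    ``bc_samples``: windows x nodes frame (one column per channel, one row
    per analysis window).  Each node's samples are tested against the
    pooled samples of every other node with alternative "greater"; a node
    whose BC is statistically higher than the rest is a hub.

    Returns a frame with columns node, is_hub, p_value, median_bc.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    if len(bc_samples) < 2:
        raise ParameterError(
            "need >= 2 BC samples per node: run windowed betweenness first"
        )
    nodes = list(bc_samples.columns)
    level = alpha / len(nodes) if bonferroni else alpha
    rows = []
    values = bc_samples.to_numpy(dtype=float)
    for k, node in enumerate(nodes):
        own = values[:, k]
        others = np.delete(values, k, axis=1).ravel()
        if np.ptp(np.concatenate([own, others])) == 0:
            p = 1.0  # all BC values identical: no evidence either way
        else:
            p = float(mannwhitneyu(own, others, alternative="greater").pvalue)
        rows.append(
            {"node": node, "is_hub": p < level, "p_value": p,
             "median_bc": float(np.median(own))}
        )
    return pd.DataFrame(rows)


def removal_impact(
    cm: ConnectivityMatrix,
    nodes: set[str] | list[str],
    mapping: str | None = None,
) -> float:
    """Percent change of l after deleting a node set (full net as benchmark).

    Positive values mean the network got less efficient (longer paths).
    """
    names = set(nodes)
    unknown = names - set(cm.channel_labels)
    if unknown:
        raise ParameterError(f"unknown channel labels: {sorted(unknown)}")
    if names >= set(cm.channel_labels):
        raise ParameterError("cannot remove every node")
    keep = [i for i, lab in enumerate(cm.channel_labels) if lab not in names]
    if len(keep) < 2:
        raise ParameterError("fewer than 2 nodes would remain")

    dm_full = weight_to_distance(cm, mapping)
    l_before = characteristic_path_length(dm_full)
    sub = DistanceMatrix(
        dm_full.distances[np.ix_(keep, keep)],
        [cm.channel_labels[i] for i in keep],
        dm_full.mapping,
    )
    try:
        l_after = characteristic_path_length(sub)
    except ParameterError as exc:
        raise ParameterError(
            f"removing {sorted(names)} disconnects the network entirely"
        ) from exc
    return float(100.0 * (l_after - l_before) / l_before)
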