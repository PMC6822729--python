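"""Directed-network construction and whole-network topology metrics.

An inhibition network is a simple directed graph: nodes are isolates of one
sympatric community, and an edge u → v means isolate u inhibits isolate v
(mean inhibition zone above threshold). This module computes the summary
topology statistics used to compare communities: density, in/out degree
summaries, mean shortest directed path length L, the directed clustering
coefficient C, and the small-world indices gamma, lambda, S.

Conventions that matter:

* ``L`` averages directed shortest-path hop counts over reachable ordered
  pairs only; unreachable pairs are excluded from both numerator and
  denominator (never averaged as infinity).
* ``C`` is directed transitivity: the fraction of directed two-paths
  u → v → w (all nodes distinct) that are closed by the shortcut edge
  u → w. On dense random digraphs its expectation is the edge density,
  which makes it directly comparable to Erdős–Rényi null means.
* Statistics that are undefined on a given graph (no reachable pair, no
  two-path) are returned as NaN, which ensemble code treats as "excluded".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .assay_io import InhibitionMatrix


@dataclass(frozen=True)
class InhibitionNetwork:
    """Simple labeled digraph over one community's isolates.

    ``adjacency[i, j]`` is True iff ``labels[i]`` inhibits ``labels[j]``.
    No self-loops; isolated nodes are retained.
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray
    community_id: str = ""

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool).copy()
        n = len(self.labels)
        if adj.shape != (n, n):
            raise ValueError(f"adjacency shape {adj.shape} does not match {n} labels")
        np.fill_diagonal(adj, False)
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1)) if n > 1 else float("nan")

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(int)

    def edges(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.adjacency)
        return [(self.labels[i], self.labels[j]) for i, j in zip(rows, cols)]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.edges())
        return g

    def to_matrix(self) -> InhibitionMatrix:
        return InhibitionMatrix(
            labels=self.labels,
            cells=self.adjacency.astype(np.int8),
            community_id=self.community_id,
        )


def build_network(matrix: InhibitionMatrix) -> InhibitionNetwork:
    """Directed unweighted network from a binary interaction matrix."""
    return InhibitionNetwork(
        labels=matrix.labels,
        adjacency=matrix.cells.astype(bool),
        community_id=matrix.community_id,
    )


def from_networkx(g: nx.DiGraph, community_id: str = "") -> InhibitionNetwork:
    labels = tuple(str(x) for x in g.nodes())
    adj = nx.to_numpy_array(g, nodelist=list(g.nodes()), dtype=bool)
    return InhibitionNetwork(labels=labels, adjacency=adj, community_id=community_id)


def degree_summary(net: InhibitionNetwork) -> dict:
    """Degree vectors plus means and sample (n−1) standard deviations."""
    out_deg = net.out_degrees()
    in_deg = net.in_degrees()
    ddof = 1 if net.n_nodes > 1 else 0
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "density": net.density,
        "out_degrees": out_deg,
        "in_degrees": in_deg,
        "mean_out_degree": float(out_deg.mean()),
        "sd_out_degree": float(out_deg.std(ddof=ddof)),
        "mean_in_degree": float(in_deg.mean()),
        "sd_in_degree": float(in_deg.std(ddof=ddof)),
    }


def mean_shortest_path(net: InhibitionNetwork) -> float:
    """Mean directed shortest-path length L over reachable ordered pairs.

    Returns NaN when no ordered pair is reachable (e.g. the empty graph).
    """
    if net.n_nodes < 2 or net.n_edges == 0:
        return float("nan")
    dist = shortest_path(net.adjacency.astype(np.int8), method="D", unweighted=True)
    mask = np.isfinite(dist)
    np.fill_diagonal(mask, False)
    if not mask.any():
        return float("nan")
    return float(dist[mask].mean())


def clustering_coefficient(net: InhibitionNetwork) -> float:
    """Directed transitivity: closed directed two-paths / directed two-paths.

    A two-path is an ordered distinct triple (u, v, w) with u → v and v → w;
    it is closed when u → w also holds. NaN when the graph has no two-path.
    """
    a = net.adjacency.astype(np.int64)
    a2 = a @ a  # a2[u, w] = number of two-paths u -> v -> w
    np.fill_diagonal(a2, 0)  # drop u == w (covers u->v->u)
    paths = int(a2.sum())
    if paths == 0:
        return float("nan")
    closed = int((a2 * a).sum())
    return closed / paths


def network_summary(net: InhibitionNetwork) -> dict:
    """All Table-style per-network metrics as one flat dict."""
    summary = degree_summary(net)
    summary["L"] = mean_shortest_path(net)
    summary["C"] = clustering_coefficient(net)
    return summary


@dataclass(frozen=True)
class SmallWorldIndices:
    """gamma = C/C̄_ER, lambda = L/L̄_ER, S = gamma/lambda.

    S > 1 indicates small-world structure: more clustered than a random
    graph of the same size without correspondingly longer paths.
    """

    gamma: float
    lam: float
    smallworldness: float


def small_world_indices(
    L: float,
    C: float,
    er_mean_L: float,
    er_mean_C: float,
    lam_override: float | None = None,
) -> SmallWorldIndices:
    """Small-world indices against an Erdős–Rényi ensemble baseline.

    ``lam_override`` substitutes a user-supplied lambda in the S ratio
    (gamma / lambda); by default lambda = L / mean ER L.
    """
    gamma = C / er_mean_C if er_mean_C else float("nan")
    lam = L / er_mean_L if er_mean_L else float("nan")
    lam_used = lam if lam_override is None else lam_override
    s = gamma / lam_used if lam_used else float("nan")
    return SmallWorldIndices(gamma=gamma, lam=lam, smallworldness=s)
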