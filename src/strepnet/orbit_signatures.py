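"""Node-participation (orbit) signatures within connected triads.

Where the triad census describes a whole network, orbit analysis describes
each node: within every connected triad a node occupies one of a small set
of automorphism-equivalent positions ("orbits"). Across the 13 connected
triad classes there are exactly 30 orbits, each identified by the triad
class together with the node's within-triad out- and in-degree (labels
like ``t4.2.0``: triad 4, two out-edges, no in-edge). Counting, for every
node, how often it occupies each orbit gives a 30-vector *signature* of
its cumulative local interaction structure: e.g. a "super-killer" isolate
loads on high-out-degree orbits while a broadly-susceptible one loads on
high-in-degree orbits.

Signatures are compared by Pearson correlation (on square-root-transformed
proportions by default) with average-linkage hierarchical clustering, and
summarized per node by the Shannon diversity H′ of orbit use; an among-
community one-way ANOVA on H′ asks whether communities differ in how
evenly their members participate in local structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .network_metrics import InhibitionNetwork
from .triad_motifs import _PAIRS, CODE_TO_CLASS, _triple_indices, triple_tricodes

N_ORBITS = 30
CONNECTED_CLASSES = tuple(range(4, 17))  # classes 1..3 are disconnected

# orbit multiplicities per connected class, fixed by triad automorphisms
_EXPECTED_MULTIPLICITY = {4: 2, 5: 2, 6: 3, 7: 3, 8: 3, 9: 3, 10: 1,
                          11: 2, 12: 2, 13: 2, 14: 3, 15: 3, 16: 1}


@dataclass(frozen=True)
class Orbit:
    triad_index: int
    out_degree: int
    in_degree: int
    n_positions: int  # orbit size within one triad instance (1..3)

    @property
    def orbit_id(self) -> str:
        return f"t{self.triad_index}.{self.out_degree}.{self.in_degree}"


def _class_degrees(code: int) -> list[tuple[int, int]]:
    """(out, in) within-triad degrees of positions 0,1,2 for a tricode."""
    out = [0, 0, 0]
    inn = [0, 0, 0]
    for k, (u, v) in enumerate(_PAIRS):
        if code & (1 << k):
            out[u] += 1
            inn[v] += 1
    return list(zip(out, inn))


def _automorphism_orbits(code: int) -> list[set[int]]:
    """Node orbits of a 3-node digraph under its automorphism group."""
    autos = []
    for perm in permutations(range(3)):
        c = 0
        for k, (u, v) in enumerate(_PAIRS):
            if code & (1 << k):
                c |= 1 << _PAIRS.index((perm[u], perm[v]))
        if c == code:
            autos.append(perm)
    orbits: list[set[int]] = []
    for node in range(3):
        image = {perm[node] for perm in autos}
        if image not in orbits:
            orbits.append(image)
    return orbits


def _build_orbits() -> tuple[list[Orbit], np.ndarray]:
    """All 30 orbits, plus the (64 tricodes × 3 positions) → column lookup.

    Derived by automorphism analysis of each connected class representative;
    asserts the field convention that (class, out, in) keys orbits uniquely.
    """
    rep_code = {k: int(np.flatnonzero(CODE_TO_CLASS == k)[0]) for k in CONNECTED_CLASSES}
    orbits: list[Orbit] = []
    index_of: dict[tuple[int, int, int], int] = {}
    for cls in CONNECTED_CLASSES:
        code = rep_code[cls]
        degs = _class_degrees(code)
        cls_orbits = _automorphism_orbits(code)
        assert len(cls_orbits) == _EXPECTED_MULTIPLICITY[cls]
        # order orbits within the class by (out desc, in desc) for stable columns
        keyed = []
        for members in cls_orbits:
            member_degs = {degs[i] for i in members}
            assert len(member_degs) == 1  # same automorphism orbit, same degrees
            out_d, in_d = member_degs.pop()
            keyed.append((out_d, in_d, len(members)))
        for out_d, in_d, size in sorted(keyed, key=lambda t: (-t[0], -t[1])):
            key = (cls, out_d, in_d)
            assert key not in index_of, f"orbit key collision at {key}"
            index_of[key] = len(orbits)
            orbits.append(Orbit(cls, out_d, in_d, size))
    assert len(orbits) == N_ORBITS
    # per-tricode, per-position orbit column (-1 for disconnected classes)
    lookup = np.full((64, 3), -1, dtype=np.int64)
    for code in range(64):
        cls = int(CODE_TO_CLASS[code])
        if cls < 4:
            continue
        for pos, (out_d, in_d) in enumerate(_class_degrees(code)):
            lookup[code, pos] = index_of[(cls, out_d, in_d)]
    return orbits, lookup

ORBITS, _ORBIT_LOOKUP = _build_orbits()
ORBIT_IDS: tuple[str, ...] = tuple(o.orbit_id for o in ORBITS)


def orbit_table() -> pd.DataFrame:
    """The 30 orbits: triad class, within-triad out/in degree, orbit size."""
    return pd.DataFrame(
        {
            "orbit_id": ORBIT_IDS,
            "triad": [o.triad_index for o in ORBITS],
            "out_degree": [o.out_degree for o in ORBITS],
            "in_degree": [o.in_degree for o in ORBITS],
            "n_positions": [o.n_positions for o in ORBITS],
        }
    )


def node_orbit_census(net: InhibitionNetwork) -> pd.DataFrame:
    """Per-node 30-vector of orbit participation counts (nodes × orbits).

    Every connected triad a node belongs to increments the orbit matching
    its within-triad out/in degrees; disconnected triads do not count.
    """
    n = net.n_nodes
    if n < 3:
        raise ValueError("orbit census requires at least 3 nodes")
    triples = _triple_indices(n)
    codes = triple_tricodes(net.adjacency, triples)
    counts = np.zeros((n, N_ORBITS), dtype=np.int64)
    for pos in range(3):
        cols = _ORBIT_LOOKUP[codes, pos]
        keep = cols >= 0
        np.add.at(counts, (triples[keep, pos], cols[keep]), 1)
    return pd.DataFrame(counts, index=list(net.labels), columns=list(ORBIT_IDS))


def signature_proportions(signatures: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized orbit proportions; all-zero nodes stay all-zero."""
    totals = signatures.sum(axis=1)
    props = signatures.div(totals.where(totals > 0, 1), axis=0)
    return props.astype(float)


def signature_heatmap_matrix(signatures: pd.DataFrame) -> pd.DataFrame:
    """Square-root-transformed orbit proportions (the heatmap scale).

    Rows of participating nodes have unit sum of squares; nodes in no
    connected triad yield all-zero rows.
    """
    return np.sqrt(signature_proportions(signatures))


def cluster_signatures(
    signatures: pd.DataFrame,
    k: int | None = None,
    use_sqrt: bool = True,
) -> dict:
    """Average-linkage hierarchical clustering of signature vectors.

    Distance is 1 − Pearson correlation between node signature vectors
    (square-root-transformed proportions by default). Nodes with no
    connected-triad participation, or with zero-variance vectors, are
    excluded from the tree and reported; with ``k`` given, flat cluster
    labels are returned (excluded nodes become singletons after the fact).
    """
    mat = signature_heatmap_matrix(signatures) if use_sqrt else signature_proportions(signatures)
    participating = mat.sum(axis=1) > 0
    variable = mat.std(axis=1) > 0
    usable = mat.index[participating & variable].tolist()
    excluded = mat.index[~(participating & variable)].tolist()
    if len(usable) < 2:
        raise ValueError("need at least 2 nodes with variable nonzero signatures")
    sub = mat.loc[usable].to_numpy(dtype=float)
    corr = np.corrcoef(sub)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(usable), k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    out = {"nodes": usable, "excluded": excluded, "linkage": linkage,
           "distance": pd.DataFrame(dist, index=usable, columns=usable)}
    if k is not None:
        flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
        out["clusters"] = pd.Series(flat, index=usable, name="cluster")
    return out


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


def node_shannon(signature) -> float:
    """Shannon diversity H′ = −Σ p ln p of one node's orbit proportions.

    Nodes in no connected triad get H′ = 0 (no participation to diversify).
    """
    counts = np.asarray(signature, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_by_node(signatures: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {node: node_shannon(row) for node, row in signatures.iterrows()},
        name="shannon_h",
    )


def community_anova(h_by_community: dict[str, "pd.Series | np.ndarray"]) -> dict:
    """One-way fixed-effects ANOVA of node H′ grouped by community."""
    groups = [np.asarray(v, dtype=float) for v in h_by_community.values()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f, p = stats.f_oneway(*groups)
    summary = {
        name: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)), "n": len(v)}
        for name, v in h_by_community.items()
    }
    return {"F": float(f), "p": float(p), "groups": summary}
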