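"""Synthetic inhibition communities and raw assay tables.

The generator emulates the statistical structure observed in sympatric
*Streptomyces* antagonism assays so that every stage of the pipeline is
testable without laboratory data:

* communities of 17–18 isolates with directed edge densities around
  0.26–0.33;
* **bimodal** out-degree distributions — a few "super-killer" isolates
  inhibiting most of the community plus many weak inhibitors — alongside
  ``even`` (uniform) and ``unimodal`` (truncated normal) alternatives;
* optional reciprocation bias (excess mutual inhibition over independence);
* planted triad classes for motif-recovery power experiments;
* replicated zone-of-inhibition tables with truncated-normal measurement
  noise, from which binarization should recover the generating matrix.

All generators are driven by an explicit ``numpy`` Generator and are fully
reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .assay_io import AssayTable, InhibitionMatrix
from .network_metrics import InhibitionNetwork, build_network
from .null_models import rewire_degree_preserving
from .triad_motifs import CODE_TO_CLASS, _PAIRS


@dataclass(frozen=True)
class CommunityProfile:
    """Structural recipe for one synthetic community.

    ``out_degree_model`` is one of:

    * ``("bimodal", p_super, (lo_hi, hi_hi), (lo_lo, hi_lo))`` — with
      probability ``p_super`` a node is a super-killer with out-degree
      uniform in the high range, otherwise uniform in the low range;
    * ``("even", (lo, hi))`` — out-degree uniform in a single range;
    * ``("unimodal", mean, sd)`` — rounded truncated normal.

    ``target_density`` rescales drawn out-degrees so the expected edge count
    matches ``density · n(n−1)``; ``mutual_excess`` ≥ 0 biases target choice
    toward nodes that already inhibit the source (0 = independent edges).
    """

    n_isolates: int
    out_degree_model: tuple = ("bimodal", 0.2, (12, 16), (0, 4))
    target_density: float | None = None
    mutual_excess: float = 0.0
    community_id: str = "synthetic"


def _draw_out_degrees(profile: CommunityProfile, rng: np.random.Generator) -> np.ndarray:
    n = profile.n_isolates
    model = profile.out_degree_model
    kind = model[0]
    if kind == "bimodal":
        _, p_super, high, low = model
        is_super = rng.random(n) < p_super
        degs = np.where(
            is_super,
            rng.integers(high[0], high[1] + 1, size=n),
            rng.integers(low[0], low[1] + 1, size=n),
        )
    elif kind == "even":
        _, rng_range = model
        degs = rng.integers(rng_range[0], rng_range[1] + 1, size=n)
    elif kind == "unimodal":
        _, mean, sd = model
        degs = np.rint(np.clip(rng.normal(mean, sd, size=n), 0, n - 1)).astype(int)
    else:
        raise ValueError(f"unknown out-degree model {kind!r}")
    degs = np.clip(degs, 0, n - 1)
    if profile.target_density is not None:
        target_m = profile.target_density * n * (n - 1)
        if degs.sum() > 0 and target_m >= 0:
            scaled = degs * (target_m / degs.sum())
            floor = np.floor(scaled).astype(int)
            frac = scaled - floor
            degs = floor + (rng.random(n) < frac)
            degs = np.clip(degs, 0, n - 1)
    return degs


def simulate_community(
    profile: CommunityProfile, rng: np.random.Generator
) -> InhibitionMatrix:
    """Simple random digraph with the profile's out-degree structure.

    Out-degrees are drawn from the model (infeasible draws are capped at
    n−1); each source then picks that many distinct targets, weighted
    ``1 + mutual_excess`` toward targets that already inhibit it.
    """
    n = profile.n_isolates
    degs = _draw_out_degrees(profile, rng)
    adj = np.zeros((n, n), dtype=np.int8)
    order = rng.permutation(n)
    for i in order:
        weights = np.ones(n)
        weights[i] = 0.0
        if profile.mutual_excess > 0:
            weights += profile.mutual_excess * adj[:, i]
            weights[i] = 0.0
        probs = weights / weights.sum()
        targets = rng.choice(n, size=int(degs[i]), replace=False, p=probs)
        adj[i, targets] = 1
    labels = tuple(f"{profile.community_id}.{k + 1}" for k in range(n))
    return InhibitionMatrix(labels=labels, cells=adj, community_id=profile.community_id)


def simulate_from_degrees(
    out_seq,
    in_seq,
    rng: np.random.Generator,
    labels: tuple[str, ...] | None = None,
    n_swaps: int | None = None,
) -> InhibitionMatrix:
    """Random simple digraph with exactly the given in/out degree sequences.

    A deterministic Havel–Hakimi-style realization is randomized by
    degree-preserving edge swaps (default 10·m attempts), so degrees are
    exact in every sample. Raises if the sequences are not realizable as a
    simple digraph.
    """
    import networkx as nx

    out_seq = [int(x) for x in out_seq]
    in_seq = [int(x) for x in in_seq]
    if sum(out_seq) != sum(in_seq):
        raise ValueError("out- and in-degree sums differ; not realizable")
    try:
        g = nx.directed_havel_hakimi_graph(in_deg_sequence=in_seq, out_deg_sequence=out_seq)
    except nx.NetworkXError as exc:
        raise ValueError(f"degree sequences not digraph-realizable: {exc}") from exc
    n = len(out_seq)
    adj = np.zeros((n, n), dtype=bool)
    for u, v in g.edges():
        adj[u, v] = True
    if labels is None:
        labels = tuple(str(k) for k in range(n))
    net = InhibitionNetwork(labels=labels, adjacency=adj)
    m = net.n_edges
    if n_swaps is None:
        n_swaps = 10 * max(m, 1)
    net = rewire_degree_preserving(net, n_swaps=n_swaps, rng=rng)
    return net.to_matrix()


@dataclass(frozen=True)
class PlantSpec:
    triad_class: int
    count: int


def plant_triads(
    base: InhibitionMatrix, spec: PlantSpec, rng: np.random.Generator
) -> InhibitionMatrix:
    """Overwrite disjoint node triples so each realizes ``triad_class`` exactly.

    Triples are chosen at random without overlap; all six internal ordered
    pairs of a chosen triple are rewritten (edges to/from the rest of the
    graph are untouched). Node labels within each planted triple are
    permuted at random, so oriented classes appear in all labelings.
    """
    if not 1 <= spec.triad_class <= 16:
        raise ValueError("triad_class must be in 1..16")
    n = base.n_isolates
    if 3 * spec.count > n:
        raise ValueError(f"cannot plant {spec.count} disjoint triads in {n} nodes")
    rep_code = int(np.flatnonzero(CODE_TO_CLASS == spec.triad_class)[0])
    rep_edges = [_PAIRS[k] for k in range(6) if rep_code & (1 << k)]
    nodes = rng.permutation(n)[: 3 * spec.count]
    cells = np.asarray(base.cells).copy()
    for t in range(spec.count):
        triple = nodes[3 * t : 3 * t + 3]
        perm = rng.permutation(3)
        for u, v in permutations(range(3), 2):
            cells[triple[u], triple[v]] = 0
        for u, v in rep_edges:
            cells[triple[perm[u]], triple[perm[v]]] = 1
    return InhibitionMatrix(labels=base.labels, cells=cells, community_id=base.community_id)


def simulate_zone_table(
    matrices: "InhibitionMatrix | list[InhibitionMatrix]",
    edge_zone_mean: float = 8.0,
    noise_sd: float = 1.0,
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
) -> AssayTable:
    """Replicated zone-of-inhibition table consistent with binary matrices.

    True edges draw zones from Normal(edge_zone_mean, noise_sd) and
    non-edges from Normal(0, noise_sd), both truncated at 0; two
    perpendicular measurements per replicate. With
    ``edge_zone_mean > threshold + a few noise sd``, binarization recovers
    the generating matrices exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(matrices, InhibitionMatrix):
        matrices = [matrices]
    rows = []
    community_of: dict[str, str] = {}
    isolates: list[str] = []
    for matrix in matrices:
        isolates.extend(matrix.labels)
        for lab in matrix.labels:
            community_of[lab] = matrix.community_id
        n = matrix.n_isolates
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                mean = edge_zone_mean if matrix.cells[i, j] else 0.0
                for rep in range(1, n_replicates + 1):
                    za, zb = np.maximum(rng.normal(mean, noise_sd, size=2), 0.0)
                    rows.append(
                        (matrix.labels[i], matrix.labels[j], rep, float(za), float(zb))
                    )
    df = pd.DataFrame(
        rows, columns=["source", "target", "replicate", "zone_a_mm", "zone_b_mm"]
    )
    return AssayTable(measurements=df, isolates=isolates, community_of=community_of)


def reference_profiles(seed_tag: str = "") -> dict[str, CommunityProfile]:
    """Three default profiles emulating the study communities A, B, C.

    A: 18 isolates, density 0.258, bimodal out-degrees (super-killers plus
    many weak inhibitors); B: 17 isolates, density 0.327, even out-degrees;
    C: 17 isolates, density 0.294, unimodal moderate out-degrees.
    """
    return {
        "A": CommunityProfile(
            n_isolates=18,
            out_degree_model=("bimodal", 0.2, (12, 16), (0, 4)),
            target_density=0.258,
            community_id=f"A{seed_tag}",
        ),
        "B": CommunityProfile(
            n_isolates=17,
            out_degree_model=("even", (0, 14)),
            target_density=0.327,
            community_id=f"B{seed_tag}",
        ),
        "C": CommunityProfile(
            n_isolates=17,
            out_degree_model=("unimodal", 4.7, 3.0),
            target_density=0.294,
            community_id=f"C{seed_tag}",
        ),
    }


def simulate_reference_communities(
    seed: int,
) -> dict[str, InhibitionMatrix]:
    """Deterministic three-community fixture from the reference profiles."""
    rng = np.random.default_rng(seed)
    return {
        name: simulate_community(profile, rng)
        for name, profile in reference_profiles().items()
    }


# re-export for callers building networks straight from simulations
__all__ = [
    "CommunityProfile",
    "PlantSpec",
    "simulate_community",
    "simulate_from_degrees",
    "plant_triads",
    "simulate_zone_table",
    "reference_profiles",
    "simulate_reference_communities",
    "build_network",
]
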