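"""Directed triad census, motif tests, and chi-squared comparisons.

Any three nodes of a simple digraph induce one of 16 isomorphism classes
("triads"), conventionally labeled 003, 012, 102, 021D, 021U, 021C, 111D,
111U, 030T, 030C, 201, 120D, 120U, 120C, 210, 300 (the M-A-N scheme:
counts of mutual, asymmetric, null dyads plus an orientation letter). We
index them 1..16 in that order; classes 1–3 are the disconnected ones,
class 4 (021D) is the out-star, and class 10 (030C) is the directed
3-cycle — the "rock–paper–scissors" configuration.

A triad census counts all C(n,3) node triples by class. Motifs are classes
whose observed count deviates from a null ensemble (z-test per class,
Benjamini–Hochberg FDR across the 16 classes of one network × model
comparison). Whole-census fit uses the chi-squared goodness-of-fit
statistic against ensemble mean counts, and censuses from different
communities are compared with Pearson's chi-squared on the communities × 16
contingency table; both use Monte-Carlo p-values because several classes
are rare.

Internals: the induced subgraph on an ordered triple is encoded as a 6-bit
"tricode" over the ordered pairs (0,1),(0,2),(1,0),(1,2),(2,0),(2,1); a
precomputed 64-entry table maps tricodes to classes, which makes the
whole-graph census a handful of vectorized gathers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network_metrics import InhibitionNetwork
from .null_models import NullEnsembleSummary, z_test

TRIAD_NAMES: tuple[str, ...] = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)
N_TRIADS = 16

# ordered node pairs of a 3-node digraph, in tricode bit order
_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))
_BIT = {pair: 1 << k for k, pair in enumerate(_PAIRS)}


def _tricode_of_edges(edges) -> int:
    code = 0
    for u, v in edges:
        code |= _BIT[(u, v)]
    return code


def _canonical(code: int) -> int:
    """Minimum tricode over the 6 relabelings of the triple."""
    best = 64
    for perm in permutations(range(3)):
        c = 0
        for k, (u, v) in enumerate(_PAIRS):
            if code & _BIT[(perm[u], perm[v])]:
                c |= 1 << k
        best = min(best, c)
    return best


def _build_code_table() -> np.ndarray:
    """Map each of the 64 tricodes to its 1-based triad class index.

    Class representatives come from the standard census ordering
    (networkx ``triad_graph``), so indices 1..16 follow TRIAD_NAMES.
    """
    canon_to_class: dict[int, int] = {}
    for idx, name in enumerate(TRIAD_NAMES, start=1):
        g = nx.triad_graph(name)
        node_of = {lab: i for i, lab in enumerate(sorted(g.nodes()))}
        code = _tricode_of_edges((node_of[u], node_of[v]) for u, v in g.edges())
        canon_to_class[_canonical(code)] = idx
    table = np.zeros(64, dtype=np.int64)
    for code in range(64):
        table[code] = canon_to_class[_canonical(code)]
    assert len(canon_to_class) == N_TRIADS
    return table

CODE_TO_CLASS: np.ndarray = _build_code_table()

EDGE_COUNT_OF_CLASS: np.ndarray = np.array(
    [bin(code).count("1") for code in
     [int(np.flatnonzero(CODE_TO_CLASS == k)[0]) for k in range(1, 17)]],
    dtype=np.int64,
)


@dataclass(frozen=True)
class TriadCensus:
    """16-vector of triad-class counts for one network."""

    counts: np.ndarray
    n_nodes: int
    community_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64).copy()
        if counts.shape != (N_TRIADS,):
            raise ValueError("census must be a 16-vector")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def classify_triad(edges, nodes=(0, 1, 2)) -> int:
    """Isomorphism class (1..16) of the digraph the edges induce on 3 nodes.

    ``edges`` are ordered pairs over ``nodes`` (any 3 distinct labels).
    Label-order invariant; self-loops are rejected.
    """
    node_list = list(nodes)
    if len(set(node_list)) != 3:
        raise ValueError("exactly 3 distinct nodes required")
    index = {lab: i for i, lab in enumerate(node_list)}
    pairs = []
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed in a triad")
        pairs.append((index[u], index[v]))
    if len(set(pairs)) != len(pairs):
        raise ValueError("parallel edges not allowed in a triad")
    return int(CODE_TO_CLASS[_tricode_of_edges(pairs)])


def _triple_indices(n: int) -> np.ndarray:
    return np.array(list(combinations(range(n), 3)), dtype=np.int64)


def triple_tricodes(adjacency: np.ndarray, triples: np.ndarray | None = None) -> np.ndarray:
    """Vector of tricodes for every node triple of the graph."""
    a = np.asarray(adjacency, dtype=bool)
    if triples is None:
        triples = _triple_indices(a.shape[0])
    codes = np.zeros(len(triples), dtype=np.int64)
    for k, (u, v) in enumerate(_PAIRS):
        codes |= a[triples[:, u], triples[:, v]].astype(np.int64) << k
    return codes


def triad_census(net: InhibitionNetwork) -> TriadCensus:
    """Counts of all C(n,3) node triples by triad class."""
    n = net.n_nodes
    if n < 3:
        raise ValueError("triad census requires at least 3 nodes")
    codes = triple_tricodes(net.adjacency)
    counts = np.bincount(CODE_TO_CLASS[codes], minlength=N_TRIADS + 1)[1:]
    return TriadCensus(counts=counts, n_nodes=n, community_id=net.community_id)


def motif_tests(
    census: TriadCensus,
    ensemble: NullEnsembleSummary,
    alpha: float = 0.05,
    census_stat: str = "triad_census",
) -> pd.DataFrame:
    """Per-triad z-tests against an ensemble, BH-FDR adjusted across the 16.

    The FDR family is the 16 triads of this one network × model comparison.
    A class is flagged as a motif when its adjusted p is below ``alpha``
    (over- or under-represented according to the sign of z).
    """
    means = np.asarray(ensemble.means[census_stat], dtype=float)
    sds = np.asarray(ensemble.sds[census_stat], dtype=float)
    if means.shape != (N_TRIADS,) or sds.shape != (N_TRIADS,):
        raise ValueError("ensemble summary lacks per-triad means/sds")
    results = [z_test(float(o), float(m), float(s))
               for o, m, s in zip(census.counts, means, sds)]
    p_raw = np.array([r.p for r in results])
    _, p_fdr, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "triad": np.arange(1, N_TRIADS + 1),
            "triad_name": TRIAD_NAMES,
            "observed": census.counts,
            "null_mean": means,
            "null_sd": sds,
            "z": [r.z for r in results],
            "p": p_raw,
            "p_fdr": p_fdr,
            "motif": p_fdr < alpha,
            "model": ensemble.model,
        }
    )


def gof_chisq(observed, expected) -> float:
    """Chi-squared goodness-of-fit statistic Σ (O−E)²/E over the 16 classes."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have the same shape")
    bad = (e <= 0) & (o > 0)
    if bad.any():
        raise ValueError(
            f"expected count is zero for non-empty categories {np.flatnonzero(bad) + 1}"
        )
    keep = e > 0
    return float(((o[keep] - e[keep]) ** 2 / e[keep]).sum())


def monte_carlo_gof_p(
    observed,
    expected,
    n_sim: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Monte-Carlo goodness-of-fit test of a census against expected counts.

    Simulates ``n_sim`` multinomial censuses of size Σ observed with cell
    probabilities E/ΣE, and reports (statistic, p) where the statistic is
    the chi-squared GOF of the observed census against E rescaled to the
    observed total, and p uses the add-one permutation-test estimator
    (never exactly zero).
    """
    if rng is None:
        rng = np.random.default_rng()
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    total = o.sum()
    if total <= 0:
        raise ValueError("observed census is empty")
    probs = e / e.sum()
    e_scaled = probs * total
    stat = gof_chisq(o, e_scaled)
    sims = rng.multinomial(int(total), probs, size=n_sim).astype(float)
    keep = e_scaled > 0
    sim_stats = ((sims[:, keep] - e_scaled[keep]) ** 2 / e_scaled[keep]).sum(axis=1)
    p = (1.0 + int((sim_stats >= stat).sum())) / (n_sim + 1.0)
    return stat, p


def _pearson_stat(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    keep = expected > 0
    return float(((table - expected)[keep] ** 2 / expected[keep]).sum())


def cross_network_chisq(
    censuses: dict[str, TriadCensus],
    n_sim: int = 2000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Pearson chi-squared comparison of triad composition among communities.

    Builds the communities × 16 contingency table; all-zero triad columns
    are dropped (with a note in the result). The p-value is Monte-Carlo:
    ``n_sim`` random tables with both margins fixed.
    """
    if len(censuses) < 2:
        raise ValueError("need at least two communities")
    if rng is None:
        rng = np.random.default_rng()
    names = list(censuses)
    table = np.vstack([censuses[k].counts for k in names]).astype(np.int64)
    dropped = np.flatnonzero(table.sum(axis=0) == 0)
    kept = table[:, table.sum(axis=0) > 0]
    stat = _pearson_stat(kept.astype(float))
    sampler = stats.random_table(kept.sum(axis=1), kept.sum(axis=0))
    sims = sampler.rvs(n_sim, random_state=rng)
    sim_stats = np.array([_pearson_stat(s) for s in sims])
    p = (1.0 + int((sim_stats >= stat).sum())) / (n_sim + 1.0)
    return {
        "statistic": stat,
        "p": p,
        "df": (kept.shape[0] - 1) * (kept.shape[1] - 1),
        "communities": names,
        "dropped_triads": (dropped + 1).tolist(),
        "table": pd.DataFrame(table, index=names, columns=list(TRIAD_NAMES)),
    }


def per_triad_cross_network_tests(
    censuses: dict[str, TriadCensus],
    n_sim: int = 2000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-triad-class comparison of counts across communities.

    For each class, the observed counts per community are tested against
    expected counts proportional to each community's census total (total
    triples), with a Monte-Carlo multinomial p-value. Classes absent from
    every community are skipped (NaN row).
    """
    if rng is None:
        rng = np.random.default_rng()
    names = list(censuses)
    table = np.vstack([censuses[k].counts for k in names]).astype(float)
    totals = table.sum(axis=1)
    probs = totals / totals.sum()
    rows = []
    for t in range(N_TRIADS):
        col = table[:, t]
        if col.sum() == 0:
            rows.append({"triad": t + 1, "triad_name": TRIAD_NAMES[t],
                         "statistic": np.nan, "p": np.nan, "skipped": True})
            continue
        stat, p = monte_carlo_gof_p(col, probs * col.sum(), n_sim=n_sim, rng=rng)
        rows.append({"triad": t + 1, "triad_name": TRIAD_NAMES[t],
                     "statistic": stat, "p": p, "skipped": False})
    return pd.DataFrame(rows)
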