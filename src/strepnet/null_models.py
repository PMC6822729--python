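"""Null-model ensembles for directed inhibition networks.

Three nested nulls, ordered by how much of the observed structure they keep:

* **Erdős–Rényi (er)** — only node count and edge count are preserved; the m
  edges are placed uniformly at random among the n(n−1) ordered pairs.
* **Dyad-conditioned (dyad)** — the dyad census (counts of mutual,
  asymmetric, and null unordered pairs) is preserved; dyad types are
  assigned uniformly at random to pairs and each asymmetric dyad is
  oriented by a fair coin. This keeps the reciprocity structure.
* **Degree-conditioned (degree)** — every node's in- and out-degree is
  preserved exactly by attempted edge swaps from the observed network:
  pick two edges (a→b, c→d), propose (a→d, c→b), apply only if the result
  stays simple. Attempts, not acceptances, are counted (1000 by default).

Observed statistics are compared to an ensemble with plain z-tests on the
ensemble mean and standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.stats import norm

from .network_metrics import InhibitionNetwork

DEFAULT_N_REPS = 10_000
DEFAULT_N_SWAPS = 1_000


@dataclass(frozen=True)
class DyadCensus:
    mutual: int
    asymmetric: int
    null: int

    @property
    def n_pairs(self) -> int:
        return self.mutual + self.asymmetric + self.null

    @property
    def n_edges(self) -> int:
        return 2 * self.mutual + self.asymmetric


@dataclass(frozen=True)
class ZTestResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float


@dataclass
class NullEnsembleSummary:
    """Per-statistic mean/sd over one null ensemble.

    ``means``/``sds`` map statistic name to a float or, for vector-valued
    statistics such as the 16-triad census, a 1-d array. ``n_excluded``
    counts samples on which a statistic was undefined (NaN) and dropped.
    """

    model: str
    n_reps: int
    seed: int | None
    means: dict[str, np.ndarray | float] = field(default_factory=dict)
    sds: dict[str, np.ndarray | float] = field(default_factory=dict)
    n_excluded: dict[str, int] = field(default_factory=dict)


def sample_er(n: int, m: int, rng: np.random.Generator) -> InhibitionNetwork:
    """Uniform simple digraph with n nodes and exactly m edges, no self-loops."""
    n_pairs = n * (n - 1)
    if not 0 <= m <= n_pairs:
        raise ValueError(f"m={m} out of range for n={n} (max {n_pairs})")
    chosen = rng.choice(n_pairs, size=m, replace=False)
    rows, cols = np.divmod(chosen, n - 1)
    cols = cols + (cols >= rows)  # skip the diagonal slot
    adj = np.zeros((n, n), dtype=bool)
    adj[rows, cols] = True
    return InhibitionNetwork(labels=tuple(map(str, range(n))), adjacency=adj, community_id="er")


def dyad_census(net: InhibitionNetwork) -> DyadCensus:
    a = net.adjacency
    both = a & a.T
    mutual = int(np.triu(both, 1).sum())
    either = a | a.T
    asym = int(np.triu(either & ~both, 1).sum())
    n = net.n_nodes
    return DyadCensus(mutual=mutual, asymmetric=asym, null=n * (n - 1) // 2 - mutual - asym)


def sample_dyad_conditioned(
    census: DyadCensus, n: int, rng: np.random.Generator
) -> InhibitionNetwork:
    """Random digraph with exactly the given dyad census on n nodes."""
    n_pairs = n * (n - 1) // 2
    if census.n_pairs != n_pairs or min(census.mutual, census.asymmetric, census.null) < 0:
        raise ValueError(f"dyad census {census} inconsistent with n={n}")
    types = np.repeat(
        np.array([2, 1, 0], dtype=np.int8),
        [census.mutual, census.asymmetric, census.null],
    )
    rng.shuffle(types)
    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=bool)
    mut = types == 2
    adj[iu[mut], ju[mut]] = True
    adj[ju[mut], iu[mut]] = True
    asym = types == 1
    flip = rng.random(int(asym.sum())) < 0.5
    src = np.where(flip, iu[asym], ju[asym])
    dst = np.where(flip, ju[asym], iu[asym])
    adj[src, dst] = True
    return InhibitionNetwork(labels=tuple(map(str, range(n))), adjacency=adj, community_id="dyad")


def rewire_degree_preserving(
    net: InhibitionNetwork,
    n_swaps: int = DEFAULT_N_SWAPS,
    rng: np.random.Generator | None = None,
    return_stats: bool = False,
):
    """Degree-preserving randomization by attempted edge swaps.

    Each attempt picks two distinct edges (a→b, c→d) uniformly and proposes
    (a→d, c→b); the proposal is applied only if it introduces no self-loop
    and no parallel edge. Failed proposals still count toward ``n_swaps``.
    In- and out-degrees of every node are preserved exactly.
    """
    if rng is None:
        rng = np.random.default_rng()
    edges = net.edges()
    m = len(edges)
    if m < 2:
        return (net, {"attempts": 0, "accepted": 0}) if return_stats else net
    adj = net.adjacency.copy()
    index = {lab: i for i, lab in enumerate(net.labels)}
    edge_idx = np.array([(index[u], index[v]) for u, v in edges], dtype=np.int64)
    accepted = 0
    picks = rng.integers(0, m, size=(n_swaps, 2))
    for k in range(n_swaps):
        e1, e2 = picks[k]
        if e1 == e2:
            continue
        a, b = edge_idx[e1]
        c, d = edge_idx[e2]
        if a == d or c == b:
            continue  # proposal would create a self-loop
        if adj[a, d] or adj[c, b]:
            continue  # proposal would duplicate an existing edge
        adj[a, b] = adj[c, d] = False
        adj[a, d] = adj[c, b] = True
        edge_idx[e1] = (a, d)
        edge_idx[e2] = (c, b)
        accepted += 1
    out = InhibitionNetwork(labels=net.labels, adjacency=adj, community_id=net.community_id)
    if return_stats:
        return out, {"attempts": n_swaps, "accepted": accepted}
    return out


def make_sampler(
    model: str, net: InhibitionNetwork, n_swaps: int = DEFAULT_N_SWAPS
) -> Callable[[np.random.Generator], InhibitionNetwork]:
    """Sampler closure for one of the three null models, conditioned on ``net``."""
    if model == "er":
        n, m = net.n_nodes, net.n_edges
        return lambda rng: sample_er(n, m, rng)
    if model == "dyad":
        census, n = dyad_census(net), net.n_nodes
        return lambda rng: sample_dyad_conditioned(census, n, rng)
    if model == "degree":
        return lambda rng: rewire_degree_preserving(net, n_swaps=n_swaps, rng=rng)
    raise ValueError(f"unknown null model {model!r} (expected er | dyad | degree)")


def ensemble_summary(
    sampler: Callable[[np.random.Generator], InhibitionNetwork],
    statistics: Mapping[str, Callable[[InhibitionNetwork], float | np.ndarray]],
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    model: str = "custom",
) -> NullEnsembleSummary:
    """Monte-Carlo mean and sample sd of each statistic over the ensemble.

    Samples on which a statistic evaluates to NaN are excluded for that
    statistic (and counted in ``n_excluded``); sd uses ddof=1. Fully
    reproducible for a fixed seed.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    rng = np.random.default_rng(seed)
    values: dict[str, list] = {name: [] for name in statistics}
    for _ in range(n_reps):
        net = sampler(rng)
        for name, fn in statistics.items():
            values[name].append(fn(net))
    summary = NullEnsembleSummary(model=model, n_reps=n_reps, seed=seed)
    for name, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        if arr.ndim == 1:
            ok = ~np.isnan(arr)
            summary.n_excluded[name] = int((~ok).sum())
            kept = arr[ok]
            summary.means[name] = float(kept.mean()) if kept.size else float("nan")
            summary.sds[name] = float(kept.std(ddof=1)) if kept.size > 1 else float("nan")
        else:
            ok = ~np.isnan(arr).any(axis=1)
            summary.n_excluded[name] = int((~ok).sum())
            kept = arr[ok]
            summary.means[name] = kept.mean(axis=0)
            summary.sds[name] = kept.std(axis=0, ddof=1)
    return summary


def z_test(observed: float, null_mean: float, null_sd: float) -> ZTestResult:
    """Two-sided z-test of an observed statistic against ensemble moments.

    Degenerate ensembles (sd = 0) arise for structurally forced statistics;
    then p is 1 for an exact match and 0 otherwise.
    """
    if null_sd < 0:
        raise ValueError("null_sd must be non-negative")
    if null_sd == 0:
        z = 0.0 if observed == null_mean else np.inf * np.sign(observed - null_mean)
        p = 1.0 if observed == null_mean else 0.0
    else:
        z = (observed - null_mean) / null_sd
        p = 2.0 * norm.sf(abs(z))
    return ZTestResult(observed=observed, null_mean=null_mean, null_sd=null_sd, z=float(z), p=float(p))
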