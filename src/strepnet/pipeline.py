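"""End-to-end orchestration: matrices (or zone tables) → full report bundle.

``run_full_analysis`` takes an :class:`AnalysisConfig`, loads or binarizes
the per-community interaction matrices, and writes a report directory:

* ``metrics.tsv`` — per-community network metrics plus small-world indices
  against the Erdős–Rényi ensemble;
* ``census.tsv`` — triad censuses;
* ``motif_tests.tsv`` — per-triad z-tests vs every requested null model,
  FDR-adjusted, plus whole-census goodness-of-fit rows;
* ``cross_network.json`` — Pearson chi-squared comparison among communities;
* ``orbits.tsv`` / ``signatures_sqrt.tsv`` / ``dendrogram.nwk`` /
  ``clusters.tsv`` — node orbit censuses and clustering;
* ``diversity.tsv`` — per-node Shannon H′ with the among-community ANOVA;
* ``analysis.json`` — all parameters, seeds, and derived sub-seeds.

All randomness flows from one master seed through ``numpy`` SeedSequence
spawning, so a config re-run is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assay_io, network_metrics, null_models, orbit_signatures, triad_motifs

log = logging.getLogger("strepnet")

NULL_MODELS = ("er", "dyad", "degree")


@dataclass
class AnalysisConfig:
    matrix_paths: dict[str, str] = field(default_factory=dict)  # community -> path
    matrices_xlsx: str | None = None
    zone_table: str | None = None
    community_map: dict[str, str] = field(default_factory=dict)
    communities_from_prefix: bool = False
    threshold_mm: float = assay_io.DEFAULT_THRESHOLD_MM
    n_reps: int = null_models.DEFAULT_N_REPS
    n_swaps: int = null_models.DEFAULT_N_SWAPS
    n_sim: int = 2000
    alpha: float = 0.05
    seed: int = 0
    null_model_set: tuple[str, ...] = NULL_MODELS
    cluster_k: int | None = None
    output_dir: str = "strepnet_report"

    def __post_init__(self) -> None:
        for name, value in (("n_reps", self.n_reps), ("n_swaps", self.n_swaps),
                            ("n_sim", self.n_sim)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.null_model_set) - set(NULL_MODELS)
        if unknown:
            raise ValueError(f"unknown null models: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "null_model_set" in raw:
            raw["null_model_set"] = tuple(raw["null_model_set"])
        return cls(**raw)


def _load_networks(config: AnalysisConfig) -> dict[str, network_metrics.InhibitionNetwork]:
    matrices: dict[str, assay_io.InhibitionMatrix] = {}
    if config.zone_table:
        table = assay_io.read_zone_table(
            config.zone_table,
            community_map=config.community_map or None,
            communities_from_prefix=config.communities_from_prefix,
        )
        matrices.update(assay_io.binarize(table, threshold=config.threshold_mm))
    if config.matrices_xlsx:
        matrices.update(assay_io.read_matrices_xlsx(config.matrices_xlsx))
    for community, path in config.matrix_paths.items():
        matrices[community] = assay_io.read_matrix(path, community_id=community)
    if not matrices:
        raise ValueError("config provides no input matrices or zone table")
    return {k: network_metrics.build_network(m) for k, m in matrices.items()}


def _census_statistic(net: network_metrics.InhibitionNetwork) -> np.ndarray:
    return triad_motifs.triad_census(net).counts.astype(float)


ENSEMBLE_STATISTICS = {
    "L": network_metrics.mean_shortest_path,
    "C": network_metrics.clustering_coefficient,
    "triad_census": _census_statistic,
}


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole pipeline and write the report bundle; returns it in memory."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    seed_seq = np.random.SeedSequence(config.seed)
    networks = _load_networks(config)
    names = sorted(networks)
    log.info("loaded %d communities: %s", len(names), names)

    # one spawned stream per (community, model) plus one for cross-network MC
    child_seeds = {}
    children = seed_seq.spawn(len(names) * len(config.null_model_set) + 2)
    it = iter(children)
    for name in names:
        for model in config.null_model_set:
            child_seeds[(name, model)] = next(it)
    cross_seq = next(it)
    gof_seq = next(it)

    ensembles: dict[tuple[str, str], null_models.NullEnsembleSummary] = {}
    for (name, model), child in child_seeds.items():
        sampler = null_models.make_sampler(model, networks[name], n_swaps=config.n_swaps)
        seed_int = int(child.generate_state(1)[0] % (2**31))
        ensembles[(name, model)] = null_models.ensemble_summary(
            sampler, ENSEMBLE_STATISTICS, n_reps=config.n_reps,
            seed=seed_int, model=model,
        )
        log.info("ensemble %s/%s done (%d reps)", name, model, config.n_reps)

    # --- network metrics and small-world indices -------------------------
    metric_rows = {}
    for name in names:
        net = networks[name]
        m = network_metrics.network_summary(net)
        er = ensembles.get((name, "er"))
        row = {k: v for k, v in m.items() if not isinstance(v, np.ndarray)}
        for model in config.null_model_set:
            ens = ensembles[(name, model)]
            for stat in ("L", "C"):
                zt = null_models.z_test(m[stat], ens.means[stat], ens.sds[stat])
                row[f"{stat}_{model}_mean"] = ens.means[stat]
                row[f"{stat}_{model}_p"] = zt.p
        if er is not None:
            sw = network_metrics.small_world_indices(
                m["L"], m["C"], er.means["L"], er.means["C"]
            )
            row.update(gamma=sw.gamma, **{"lambda": sw.lam},
                       smallworldness=sw.smallworldness)
        metric_rows[name] = row
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(out_dir / "metrics.tsv", sep="\t")
    manifest.append("metrics.tsv")

    # --- triad censuses and motif tests ----------------------------------
    censuses = {name: triad_motifs.triad_census(networks[name]) for name in names}
    census_df = pd.DataFrame(
        {name: censuses[name].counts for name in names},
        index=list(triad_motifs.TRIAD_NAMES),
    )
    census_df.to_csv(out_dir / "census.tsv", sep="\t")
    manifest.append("census.tsv")

    motif_frames = []
    gof_rows = []
    gof_rng = np.random.default_rng(gof_seq)
    for name in names:
        for model in config.null_model_set:
            ens = ensembles[(name, model)]
            tests = triad_motifs.motif_tests(censuses[name], ens, alpha=config.alpha)
            tests.insert(0, "community", name)
            motif_frames.append(tests)
            stat, p = triad_motifs.monte_carlo_gof_p(
                censuses[name].counts, np.asarray(ens.means["triad_census"]),
                n_sim=config.n_sim, rng=gof_rng,
            )
            gof_rows.append({"community": name, "model": model,
                             "chisq": stat, "p_mc": p})
    motif_df = pd.concat(motif_frames, ignore_index=True)
    motif_df.to_csv(out_dir / "motif_tests.tsv", sep="\t", index=False)
    manifest.append("motif_tests.tsv")
    gof_df = pd.DataFrame(gof_rows)
    gof_df.to_csv(out_dir / "census_gof.tsv", sep="\t", index=False)
    manifest.append("census_gof.tsv")

    cross = None
    if len(names) >= 2:
        cross_rng = np.random.default_rng(cross_seq)
        cross = triad_motifs.cross_network_chisq(censuses, n_sim=config.n_sim, rng=cross_rng)
        per_triad = triad_motifs.per_triad_cross_network_tests(
            censuses, n_sim=config.n_sim, rng=cross_rng
        )
        per_triad.to_csv(out_dir / "cross_network_per_triad.tsv", sep="\t", index=False)
        manifest.append("cross_network_per_triad.tsv")
        with open(out_dir / "cross_network.json", "w") as fh:
            json.dump({"statistic": cross["statistic"], "p": cross["p"],
                       "df": cross["df"], "dropped_triads": cross["dropped_triads"],
                       "communities": cross["communities"]}, fh, indent=2)
        manifest.append("cross_network.json")

    # --- orbit signatures, clustering, diversity -------------------------
    signatures = {}
    h_by_comm = {}
    sig_frames = []
    for name in names:
        sig = orbit_signatures.node_orbit_census(networks[name])
        signatures[name] = sig
        h_by_comm[name] = orbit_signatures.shannon_by_node(sig)
        tagged = sig.copy()
        tagged.insert(0, "community", name)
        sig_frames.append(tagged)
    all_sigs = pd.concat(sig_frames)
    all_sigs.to_csv(out_dir / "orbits.tsv", sep="\t")
    manifest.append("orbits.tsv")
    sqrt_all = orbit_signatures.signature_heatmap_matrix(
        all_sigs.drop(columns="community")
    )
    sqrt_all.to_csv(out_dir / "signatures_sqrt.tsv", sep="\t")
    manifest.append("signatures_sqrt.tsv")

    clustering = orbit_signatures.cluster_signatures(
        all_sigs.drop(columns="community"), k=config.cluster_k
    )
    newick = orbit_signatures.linkage_to_newick(clustering["linkage"], clustering["nodes"])
    (out_dir / "dendrogram.nwk").write_text(newick + "\n")
    manifest.append("dendrogram.nwk")
    if "clusters" in clustering:
        clustering["clusters"].to_csv(out_dir / "clusters.tsv", sep="\t")
        manifest.append("clusters.tsv")

    diversity = pd.concat(
        [pd.DataFrame({"community": name, "shannon_h": h}) for name, h in h_by_comm.items()]
    )
    diversity.to_csv(out_dir / "diversity.tsv", sep="\t")
    manifest.append("diversity.tsv")
    anova = None
    if len(names) >= 2 and all(len(v) >= 2 for v in h_by_comm.values()):
        anova = orbit_signatures.community_anova(h_by_comm)

    report = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "communities": names,
        "metrics": metrics_df.to_dict(),
        "census_gof": gof_rows,
        "cross_network": None if cross is None else
            {"statistic": cross["statistic"], "p": cross["p"]},
        "anova": anova,
        "ensemble_seeds": {f"{n}/{m}": ensembles[(n, m)].seed
                           for (n, m) in ensembles},
    }
    with open(out_dir / "analysis.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    manifest.append("analysis.json")
    (out_dir / "MANIFEST").write_text("\n".join(manifest) + "\n")

    report["motif_tests"] = motif_df
    report["censuses"] = censuses
    report["signatures"] = signatures
    return report
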