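"""End-to-end orchestration: synth inputs -> sourcetrack -> diversity ->
network -> assembly, with a manifest recording parameters and timings.

All result files are deterministic given (config, seed); the manifest
additionally records wall times and is therefore the one file excluded
from the byte-identity guarantee.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeding import child_seed
from .assembly import assembly_analysis
from .config import PipelineConfig
from .diversity import alpha_diversity, pcoa, permanova_pairwise, unifrac_distance_matrix
from .io import (
    FeatureTable,
    read_feature_table,
    read_metadata,
    read_tree,
    write_feature_table,
    write_metadata,
    write_tree,
)
from .network import build_network, keystone_report, niche_overlap
from .sourcetrack import results_to_frame, track_all
from .synth import SyntheticTruth, simulate_sink, simulate_sources, simulate_tree

logger = logging.getLogger("littersuccession")


def _synth_inputs(config: PipelineConfig, out: Path):
    """Generate the demo data set: sources, mixed sinks, tree, metadata."""
    s = config.synth
    seed = config.seed
    sources, meta, profiles = simulate_sources(
        n_sources=2,
        n_taxa=s.n_taxa,
        samples_per_source=s.samples_per_source,
        dirichlet_concentration=s.dirichlet_concentration,
        seed=child_seed(seed, "synth.sources"),
        depth=s.depth,
    )
    rng = np.random.default_rng(child_seed(seed, "synth.unknown"))
    unknown_profile = rng.dirichlet(np.full(s.n_taxa, s.dirichlet_concentration))
    alpha = np.asarray(s.mixing, dtype=float)
    sink_cols, truths = [], {}
    for i in range(s.n_sinks):
        counts, truth = simulate_sink(
            profiles, alpha, unknown_profile, depth=s.depth,
            seed=child_seed(seed, f"synth.sink{i}"),
        )
        sink_cols.append(counts)
        truths[f"litter_s{i + 1:02d}"] = truth.mixing_proportions
    sinks = FeatureTable(
        sources.taxon_ids,
        tuple(f"litter_s{i + 1:02d}" for i in range(s.n_sinks)),
        np.column_stack(sink_cols),
    )
    sink_meta = pd.DataFrame(
        {"habitat": "litter", "stage": "EDL", "altitude": 750.0}, index=list(sinks.sample_ids)
    )
    metadata = pd.concat([meta, sink_meta]).fillna(value=pd.NA)
    tree = simulate_tree(s.n_taxa, seed=child_seed(seed, "synth.tree"))

    write_feature_table(sources, out / "sources.tsv")
    write_feature_table(sinks, out / "sinks.tsv")
    write_metadata(metadata, out / "metadata.tsv")
    write_tree(tree, out / "tree.nwk")
    SyntheticTruth(seed=seed, mixing_proportions={"phyllosphere": float(alpha[0]),
                                                  "soil": float(alpha[1]),
                                                  "unknown": float(alpha[2])}
                   ).to_json(out / "truth.json")
    return sources, sinks, metadata, tree


def _load_inputs(config: PipelineConfig):
    p = config.paths
    sinks = read_feature_table(p.sinks)
    sources = read_feature_table(p.sources)
    metadata = read_metadata(p.metadata)
    tree = read_tree(p.tree)
    return sources, sinks, metadata, tree


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all enabled stages; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    timings: dict[str, float] = {}
    stage_list: list[str] = []

    def timed(name):
        stage_list.append(name)
        timings[name] = time.perf_counter()
        logger.info("stage %s started", name)

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)
        logger.info("stage %s finished in %.1fs", name, timings[name])

    external = all(
        getattr(config.paths, k) for k in ("sinks", "sources", "tree", "metadata")
    )
    timed("inputs")
    if external:
        sources, sinks, metadata, tree = _load_inputs(config)
    else:
        sources, sinks, metadata, tree = _synth_inputs(config, out)
    done("inputs")

    combined = FeatureTable(
        sources.taxon_ids,
        sources.sample_ids + sinks.sample_ids,
        np.column_stack([sources.counts, sinks.select_taxa(list(sources.taxon_ids)).counts]),
    )

    if config.stages.sourcetrack:
        timed("sourcetrack")
        results = track_all(
            sinks, sources, metadata,
            depth=config.sourcetrack.depth,
            tol=config.sourcetrack.tol,
            max_iter=config.sourcetrack.max_iter,
            seed=child_seed(seed, "sourcetrack"),
        )
        frame = results_to_frame(results)
        frame.to_csv(out / "sourcetrack.tsv", sep="\t")
        (out / "sourcetrack.json").write_text(json.dumps(
            {r.sink_id: r.contributions for r in results}, sort_keys=True, indent=1))
        done("sourcetrack")

    if config.stages.diversity:
        timed("diversity")
        base = 2 if config.diversity.shannon_base == "2" else "e"
        alpha_diversity(combined, base=base).to_csv(out / "alpha.tsv", sep="\t")
        dm = unifrac_distance_matrix(combined, tree)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(out / "beta_unifrac.tsv", sep="\t")
        ordination = pcoa(dm)
        ordination.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
        habitat = {s: metadata.loc[s, "habitat"] for s in combined.sample_ids}
        table = permanova_pairwise(
            dm, habitat, n_perm=config.diversity.n_perm,
            seed=child_seed(seed, "permanova"), p_adjust=config.diversity.p_adjust,
        )
        table.to_csv(out / "permanova.tsv", sep="\t", index=False)
        done("diversity")

    if config.stages.network:
        timed("network")
        net = build_network(
            combined,
            top_n=min(config.network.top_n, len(combined.taxon_ids)),
            method=config.network.method,
            r_threshold=config.network.r_threshold,
            p_threshold=config.network.p_threshold,
        )
        net.edge_frame().to_csv(out / "network_edges.tsv", sep="\t", index=False)
        habitat = metadata["habitat"]
        phyllo = [s for s in sources.sample_ids if habitat.get(s) == "phyllosphere"]
        soil = [s for s in sources.sample_ids if habitat.get(s) == "soil"]
        report = keystone_report(
            net,
            phyllosphere_table=sources.select_samples(phyllo) if phyllo else None,
            soil_table=sources.select_samples(soil) if soil else None,
            quantile=config.network.keystone_quantile,
        )
        report.to_csv(out / "network_nodes.tsv", sep="\t")
        overlap = {}
        if "origin" in report.columns:
            key = report[report["keystone"]]
            ex_p = sorted(key.index[key["origin"] == "phyllosphere"])
            ex_s = sorted(key.index[key["origin"] == "soil"])
            if ex_p and ex_s:
                overlap["pianka_phyllosphere_vs_soil"] = niche_overlap(ex_p, ex_s, sinks)
        (out / "niche_overlap.json").write_text(json.dumps(overlap, sort_keys=True, indent=1))
        done("network")

    if config.stages.assembly:
        timed("assembly")
        litter = sinks
        frame, fractions = assembly_analysis(
            litter, tree,
            ds=config.assembly.ds,
            min_bin_size=config.assembly.min_bin_size,
            min_reads=config.assembly.min_reads,
            n_null=config.assembly.n_null,
            nti_cut=config.assembly.nti_cut,
            rc_cut=config.assembly.rc_cut,
            seed=child_seed(seed, "assembly"),
        )
        frame.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        pd.Series(fractions, name="fraction").rename_axis("process").to_csv(
            out / "assembly_fractions.tsv", sep="\t")
        done("assembly")

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": config.model_dump(),
        "stages_run": stage_list,
        "wall_seconds": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return out
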