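"""Pipeline orchestration: config, stage sequencing, outputs, CLI.

``run_pipeline`` sequences the full analysis over one count table (read from
TSV or generated synthetically): low-count filtering, alpha/beta diversity
with permutation inference, clr differential abundance, per-season SparCC
network inference with focal-taxon ego subnetworks and taxon-exclusion
re-inference, topology tables, and robustness simulations (attacks and node
addition). Every random stage receives an explicit seed derived from the
config seed, the config is echoed into the output directory, and all
outputs are plain text (TSV/CSV/JSON/GraphML/Newick), so a fixed config and
seed reproduce the output tree byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from tickmicro import __version__, cooccurrence, diffabund, diversity, nettopo, robustness, synthdata, tables_io
from tickmicro.tables_io import CooccurrenceNetwork, CountTable

__all__ = ["PipelineConfig", "run_pipeline", "cli", "STAGES"]

STAGES = ("simulate", "filter", "diversity", "diffabund", "network", "topology", "robustness")


@dataclass
class PipelineConfig:
    """All pipeline knobs; every default is overridable from YAML."""

    # input: either a TSV table (+ optional Newick tree) or synthetic data
    input_table: str | None = None
    input_tree: str | None = None
    synth: dict = field(default_factory=lambda: {
        "n_samples_per_group": [8, 7, 6],
        "n_taxa": 60,
        "n_modules": 4,
        "module_correlation": 0.98,
        "hub_degree": 10,
        "depth_mean": 50000,
    })
    filter_min_reads: int = 3
    filter_rule: str = "total"
    n_perm: int = 999
    n_mc: int = 128
    diff_alpha: float = 0.05
    sparcc: dict = field(default_factory=lambda: {
        "threshold_r": 0.75,
        "alpha": 0.05,
        "n_boot": 1000,
        "n_iter": 20,
        "exclusion_threshold": 0.1,
        "exclusion_rounds": 10,
        "include_isolated": False,
    })
    focal_taxa: list = field(default_factory=lambda: ["Francisella", "Rickettsia"])
    robustness: dict = field(default_factory=lambda: {
        "k_list": [100, 300, 500, 700, 1000],
        "attack_reps": 30,
        "addition_reps": 20,
        "attachment": "density",
        "ci_level": 0.95,
        "se_threshold": 0.9,
    })
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                default.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return "&".join(sorted(o))
    raise TypeError(f"not JSON serializable: {type(o)}")


def _venn_jsonable(venn: dict) -> dict:
    return {
        "regions": {"&".join(sorted(k)): v for k, v in venn["regions"].items()},
        "counts": {"&".join(sorted(k)): v for k, v in venn["counts"].items()},
        "union_size": venn["union_size"],
    }


def _annotate(net: CooccurrenceNetwork, seed: int) -> None:
    """Attach module ids and eigenvector centrality as node attributes."""
    if net.n_edges == 0:
        return
    partition, _ = nettopo.louvain_partition(net, seed=seed)
    centrality = nettopo.eigenvector_centrality(net)
    for node in net.graph.nodes:
        net.graph.nodes[node]["module"] = int(partition.get(node, -1))
        net.graph.nodes[node]["eigenvector_centrality"] = float(centrality.get(node, 0.0))


def _network_outputs(net: CooccurrenceNetwork, outdir: Path, stem: str) -> None:
    tables_io.write_network(net, outdir / f"{stem}.graphml", "graphml")
    tables_io.write_network(net, outdir / f"{stem}_edges.csv", "edge_list_csv")


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the configured stages; returns a manifest dict (also written).

    Focal taxa absent from a season's table or network are skipped with an
    explicit notice (mirrors a taxon undetected in a whole season); the
    pipeline still completes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "config.yaml").write_text(config.to_yaml())

    # ---- input ------------------------------------------------------------
    tree = None
    if config.input_table:
        table = tables_io.read_count_table(config.input_table)
        if config.input_tree:
            tree = tables_io.read_newick(config.input_tree)
    else:
        table, truth, tree = synthdata.generate_seasonal_counts(
            tuple(config.synth["n_samples_per_group"]),
            n_taxa=config.synth["n_taxa"],
            n_modules=config.synth["n_modules"],
            module_correlation=config.synth["module_correlation"],
            hub_degree=config.synth["hub_degree"],
            depth_mean=config.synth["depth_mean"],
            seed=config.seed,
        )
        if "simulate" in stages:
            tables_io.write_count_table(table, out / "counts.tsv")
            tables_io.write_newick(tree, out / "tree.nwk")
            truth.to_json(out / "truth.json")

    # ---- filter -----------------------------------------------------------
    filtered, dropped = diffabund.filter_min_reads(
        table, config.filter_min_reads, config.filter_rule
    )
    if "filter" in stages:
        tables_io.write_count_table(filtered, out / "counts_filtered.tsv")
        _write_json(
            {"rule": config.filter_rule, "min_reads": config.filter_min_reads,
             "n_dropped": len(dropped), "dropped": dropped},
            out / "filter_report.json",
        )
    seasons = filtered.groups()

    # ---- diversity ---------------------------------------------------------
    if "diversity" in stages:
        alpha = diversity.alpha_diversity(filtered, tree)
        alpha.per_sample.to_csv(out / "alpha_diversity.tsv", sep="\t")
        alpha.kruskal.to_csv(out / "alpha_kruskal.tsv", sep="\t")
        dist = diversity.bray_curtis(filtered)
        dist.to_csv(out / "bray_curtis.tsv", sep="\t")
        perm = diversity.permanova(dist, filtered.group, n_perm=config.n_perm, seed=config.seed + 11)
        pairwise = diversity.pairwise_permanova(dist, filtered.group, n_perm=config.n_perm, seed=config.seed + 12)
        disp = diversity.beta_dispersion(dist, filtered.group)
        clust = diversity.jaccard_cluster(filtered)
        venn = diversity.venn_sets(
            {s: set(filtered.subset_group(s).detected_taxa()) for s in seasons}
        )
        _write_json(
            {
                "permanova": perm,
                "pairwise_permanova": pairwise.to_dict(orient="records"),
                "dispersion": {
                    "anova_F": disp["anova_F"],
                    "p": disp["p"],
                    "negative_eigenvalue_mass": disp["negative_eigenvalue_mass"],
                    "negative_eigenvalue_warning": bool(disp["negative_eigenvalue_warning"]),
                },
                "jaccard_leaf_order": clust["leaf_order"],
                "jaccard_assignment": clust["assignment"].to_dict(),
                "taxa_venn": _venn_jsonable(venn),
                "assumptions": "counts not rarefied; PERMANOVA permutations = "
                               f"{config.n_perm} (not stated by the study design)",
            },
            out / "beta_diversity.json",
        )

    # ---- differential abundance --------------------------------------------
    if "diffabund" in stages:
        inst = diffabund.clr_instances(filtered, n_mc=config.n_mc, seed=config.seed + 21)
        report = diffabund.aldex_kw(inst, alpha=config.diff_alpha)
        report.to_csv(out / "differential_abundance.tsv", sep="\t", index=False)
        sig = report.loc[report["significant"], "taxon"].tolist()
        if sig:
            heat = diffabund.clr_heat_matrix(inst, sig)
            heat.to_csv(out / "clr_heatmap_matrix.tsv", sep="\t")
        else:
            notices.append("no significant taxa at adjusted alpha; heatmap skipped")

    # ---- networks ------------------------------------------------------------
    networks: dict[str, CooccurrenceNetwork] = {}
    season_tables: dict[str, CountTable] = {}
    sp = config.sparcc
    if "network" in stages or "topology" in stages or "robustness" in stages:
        netdir = out / "networks"
        netdir.mkdir(exist_ok=True)
        for si, season in enumerate(seasons):
            sub = filtered.subset_group(season)
            season_tables[season] = sub
            seed_s = config.seed + 100 + si
            res = cooccurrence.sparcc_bootstrap(
                sub, n_boot=sp["n_boot"], seed=seed_s, n_iter=sp["n_iter"],
                exclusion_rounds=sp["exclusion_rounds"],
                exclusion_threshold=sp["exclusion_threshold"],
            )
            net = cooccurrence.build_network(
                res, threshold_r=sp["threshold_r"], alpha=sp["alpha"],
                include_isolated=sp["include_isolated"], name=season,
            )
            _annotate(net, seed=seed_s)
            networks[season] = net
            _network_outputs(net, netdir, season)
            res.pair_frame().to_csv(netdir / f"{season}_sparcc_pairs.csv", index=False)
            # ego subnetworks for focal taxa
            for focal in config.focal_taxa:
                if focal not in net.graph:
                    notices.append(f"{season}: focal taxon {focal} not in network; ego skipped")
                    continue
                ego = nettopo.ego_subnetwork(net, focal)
                _network_outputs(ego, netdir, f"{season}_ego_{focal}")
            # exclusion re-inference
            for focal in config.focal_taxa:
                if focal not in sub.taxon_ids:
                    notices.append(
                        f"{season}: taxon {focal} absent from all samples; exclusion network skipped"
                    )
                    continue
                _, ex_net = cooccurrence.exclude_taxon_and_reinfer(
                    sub, focal, n_boot=sp["n_boot"], seed=seed_s + 1000,
                    threshold_r=sp["threshold_r"], alpha=sp["alpha"],
                    include_isolated=sp["include_isolated"],
                    name=f"{season}_wo_{focal}",
                    n_iter=sp["n_iter"],
                    exclusion_rounds=sp["exclusion_rounds"],
                    exclusion_threshold=sp["exclusion_threshold"],
                )
                _annotate(ex_net, seed=seed_s + 1000)
                networks[f"{season}_wo_{focal}"] = ex_net
                _network_outputs(ex_net, netdir, f"{season}_wo_{focal}")
        # node-set comparisons per season (original vs exclusions)
        venns = {}
        for season in seasons:
            named = {"N": networks[season]}
            for focal in config.focal_taxa:
                key = f"{season}_wo_{focal}"
                if key in networks:
                    named[f"Wo{focal[0]}"] = networks[key]
            if len(named) >= 2:
                venns[season] = _venn_jsonable(nettopo.compare_node_sets(named))
        _write_json(venns, out / "network_node_venns.json")

    # ---- topology -------------------------------------------------------------
    if "topology" in stages and networks:
        rows = []
        for ni, (name, net) in enumerate(networks.items()):
            rep = nettopo.topology_report(net, seed=config.seed + 300 + ni, name=name)
            rows.append(rep.to_dict())
        topo = pd.DataFrame(rows)
        topo.to_csv(out / "topology_summary.tsv", sep="\t", index=False)
        focal_rows = []
        for season in seasons:
            for focal in config.focal_taxa:
                if focal in networks[season].graph:
                    focal_rows.append(
                        {"season": season, "focal": focal,
                         "degree": nettopo.focal_degree(networks[season], focal)}
                    )
        pd.DataFrame(focal_rows).to_csv(out / "focal_degrees.tsv", sep="\t", index=False)

    # ---- robustness ------------------------------------------------------------
    if "robustness" in stages and networks:
        rb = config.robustness
        robdir = out / "robustness"
        robdir.mkdir(exist_ok=True)
        summary_rows = []
        stats_frames = []
        for ni, (name, net) in enumerate(networks.items()):
            if net.n_edges == 0:
                notices.append(f"{name}: empty network; robustness skipped")
                continue
            seed_r = config.seed + 500 + ni
            curves = {}
            for strat in robustness.ATTACK_STRATEGIES:
                res = robustness.attack(
                    net, strat, seed=seed_r,
                    n_reps=rb["attack_reps"] if strat == "random" else 1,
                    ci_level=rb["ci_level"],
                )
                curves[strat] = res
                row = {"network": name, "strategy": strat, "frac_for_80": res.frac_for_80}
                if strat == "random":
                    se = robustness.loss_se(res, rb["se_threshold"])
                    row["mean_se_below_threshold"] = se["mean_se_below_threshold"]
                summary_rows.append(row)
            curve_df = pd.DataFrame({"fraction_removed": curves["random"].fractions})
            for strat, res in curves.items():
                curve_df[strat] = res.loss
            curve_df["random_ci_low"] = curves["random"].ci_low
            curve_df["random_ci_high"] = curves["random"].ci_high
            curve_df.to_csv(robdir / f"{name}_attack_curves.tsv", sep="\t", index=False)
            # node addition
            additions = {}
            for k in rb["k_list"]:
                additions[k] = robustness.add_random_nodes(
                    net, k, attachment=rb["attachment"],
                    n_reps=rb["addition_reps"], seed=seed_r + 7000 + k,
                )
            stats = robustness.addition_stats(additions)
            stats.insert(0, "network", name)
            stats_frames.append(stats)
            pd.DataFrame([a.summary() for a in additions.values()]).to_csv(
                robdir / f"{name}_addition_summary.tsv", sep="\t", index=False
            )
        pd.DataFrame(summary_rows).to_csv(robdir / "attack_summary.tsv", sep="\t", index=False)
        if stats_frames:
            pd.concat(stats_frames, ignore_index=True).to_csv(
                robdir / "addition_stats.tsv", sep="\t", index=False
            )
        manifest["connectivity_loss_definition"] = (
            "1 - (connected ordered node pairs after removal) / (connected ordered node pairs intact)"
        )
        manifest["addition_attachment_rule"] = rb["attachment"]

    manifest["notices"] = notices
    _write_json(manifest, out / "manifest.json")
    (out / "notices.txt").write_text("\n".join(notices) + ("\n" if notices else ""))
    return manifest


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML config; defaults apply if omitted.")
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=None, help="Overrides the config seed.")
@click.option("--stage", "stage", type=click.Choice(STAGES + ("all",)), default="all",
              help="Run one stage (plus its prerequisites) or everything.")
def cli(config_path, out_dir, seed, stage):
    """Seasonal microbiome network pipeline (synthetic or TSV input)."""
    config = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    if seed is not None:
        config.seed = seed
    stages = STAGES if stage == "all" else (stage,)
    manifest = run_pipeline(config, out_dir, stages=stages)
    click.echo(f"wrote {out_dir} ({len(manifest['notices'])} notices)")


if __name__ == "__main__":
    cli()
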