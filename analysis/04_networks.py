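#!/usr/bin/env python
"""Per-season SparCC co-occurrence networks with focal-taxon analyses.

For each season: SparCC correlations with 1000-replicate permutation
bootstrap, edges at |r| >= 0.75 and BH-adjusted p < 0.05; ego subnetworks of
the focal taxa (Francisella, Rickettsia); and exclusion networks re-inferred
after dropping each focal taxon's column. Writes GraphML + edge CSVs under
results/networks/. The slowest step (~minutes).
"""

from pathlib import Path

from tickmicro import cooccurrence, diffabund, nettopo, tables_io

SEED = 1
N_BOOT = 1000
FOCAL = ["Francisella", "Rickettsia"]
DATA = Path("results/data")
OUT = Path("results/networks")


def annotate(net, seed):
    if net.n_edges == 0:
        return
    partition, _ = nettopo.louvain_partition(net, seed=seed)
    centrality = nettopo.eigenvector_centrality(net)
    for node in net.graph.nodes:
        net.graph.nodes[node]["module"] = int(partition.get(node, -1))
        net.graph.nodes[node]["eigenvector_centrality"] = float(centrality.get(node, 0.0))


def write(net, stem):
    tables_io.write_network(net, OUT / f"{stem}.graphml", "graphml")
    tables_io.write_network(net, OUT / f"{stem}_edges.csv", "edge_list_csv")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = tables_io.read_count_table(DATA / "counts.tsv")
    filtered, _ = diffabund.filter_min_reads(table)

    for si, season in enumerate(filtered.groups()):
        sub = filtered.subset_group(season)
        seed_s = SEED + 100 + si
        res = cooccurrence.sparcc_bootstrap(sub, n_boot=N_BOOT, seed=seed_s)
        net = cooccurrence.build_network(res, name=season)
        annotate(net, seed_s)
        write(net, season)
        res.pair_frame().to_csv(OUT / f"{season}_sparcc_pairs.csv", index=False)
        print(f"{season}: {net.n_nodes} nodes, {net.n_edges} edges "
              f"({sub.n_samples} samples, {sub.n_taxa} taxa)")

        for focal in FOCAL:
            if focal in net.graph:
                ego = nettopo.ego_subnetwork(net, focal)
                write(ego, f"{season}_ego_{focal}")
                print(f"  {focal}: degree {nettopo.focal_degree(net, focal)}; "
                      f"ego subnetwork {ego.n_nodes} nodes / {ego.n_edges} edges")
            else:
                print(f"  {focal}: not in the {season} network; ego skipped")
            if focal in sub.taxon_ids:
                _, ex = cooccurrence.exclude_taxon_and_reinfer(
                    sub, focal, n_boot=N_BOOT, seed=seed_s + 1000,
                    name=f"{season}_wo_{focal}",
                )
                annotate(ex, seed_s + 1000)
                write(ex, f"{season}_wo_{focal}")
                print(f"  without {focal} (re-inferred): "
                      f"{ex.n_nodes} nodes, {ex.n_edges} edges")
            else:
                print(f"  {focal}: absent from all {season} samples; "
                      f"exclusion network skipped")


if __name__ == "__main__":
    main()
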