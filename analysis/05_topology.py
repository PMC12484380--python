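#!/usr/bin/env python
"""Topology tables and node-set comparisons of the inferred networks.

Reads the GraphML networks written by 04_networks.py and produces the
seasonal topology summary (nodes, edges, sign counts, modularity, diameter,
average/weighted degree, clustering coefficient, component count), focal
degrees, and the per-season Venn partitions comparing the original network
with the exclusion networks. Writes results/topology/.
"""

import json
from pathlib import Path

import pandas as pd

from tickmicro import nettopo, tables_io

SEED = 1
NETS = Path("results/networks")
OUT = Path("results/topology")
FOCAL = ["Francisella", "Rickettsia"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    networks = {}
    for path in sorted(NETS.glob("*.graphml")):
        if "_ego_" in path.stem:
            continue
        networks[path.stem] = tables_io.read_network(path)

    rows = []
    for ni, (name, net) in enumerate(networks.items()):
        rep = nettopo.topology_report(net, seed=SEED + ni, name=name)
        rows.append(rep.to_dict())
    topo = pd.DataFrame(rows)
    topo.to_csv(OUT / "topology_summary.tsv", sep="\t", index=False)
    print(topo[["name", "n_nodes", "n_edges", "modularity", "diameter",
                "avg_degree", "clustering_coeff", "n_components"]].to_string(index=False))

    venns = {}
    for season in ("autumn", "spring", "summer"):
        named = {}
        if season in networks:
            named["N"] = networks[season]
        for focal in FOCAL:
            key = f"{season}_wo_{focal}"
            if key in networks:
                named[f"Wo{focal[0]}"] = networks[key]
        if len(named) >= 2:
            venn = nettopo.compare_node_sets(named)
            venns[season] = {"&".join(sorted(k)): v for k, v in venn["counts"].items()}
    (OUT / "node_set_venns.json").write_text(json.dumps(venns, indent=1, sort_keys=True))
    print("node-set Venn counts per season:", json.dumps(venns))


if __name__ == "__main__":
    main()
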