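#!/usr/bin/env python
"""Attack and node-addition robustness of every inferred network.

For each network from 04_networks.py: connectivity-loss curves under random
(30 replicates, bootstrap CIs), degree, betweenness and cascading attacks
with the node fraction needed for 80% loss; and node-addition experiments
(k = 100..1000, density-matched attachment) tracking LCC and APL with
Wilcoxon signed-rank tests against the intact baseline (BH across k).
Writes results/robustness/.
"""

from pathlib import Path

import pandas as pd

from tickmicro import robustness, tables_io

SEED = 1
K_LIST = [100, 300, 500, 700, 1000]
NETS = Path("results/networks")
OUT = Path("results/robustness")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary, stats_frames = [], []
    paths = [p for p in sorted(NETS.glob("*.graphml")) if "_ego_" not in p.stem]
    for ni, path in enumerate(paths):
        net = tables_io.read_network(path)
        name = path.stem
        if net.n_edges == 0:
            print(f"{name}: empty network, skipped")
            continue
        seed_r = SEED + 500 + ni
        curves = {}
        for strat in robustness.ATTACK_STRATEGIES:
            res = robustness.attack(net, strat, seed=seed_r, n_reps=30)
            curves[strat] = res
            summary.append({"network": name, "strategy": strat,
                            "frac_for_80": res.frac_for_80})
        df = pd.DataFrame({"fraction_removed": curves["random"].fractions})
        for strat, res in curves.items():
            df[strat] = res.loss
        df["random_ci_low"] = curves["random"].ci_low
        df["random_ci_high"] = curves["random"].ci_high
        df.to_csv(OUT / f"{name}_attack_curves.tsv", sep="\t", index=False)
        worst = min(curves, key=lambda s: curves[s].frac_for_80)
        print(f"{name}: fraction removed for 80% connectivity loss — " +
              ", ".join(f"{s}: {curves[s].frac_for_80:.2f}" for s in curves) +
              f" (most disruptive: {worst})")

        additions = {
            k: robustness.add_random_nodes(net, k, n_reps=20, seed=seed_r + 7000 + k)
            for k in K_LIST
        }
        stats = robustness.addition_stats(additions)
        stats.insert(0, "network", name)
        stats_frames.append(stats)
        lo, hi = additions[K_LIST[0]], additions[K_LIST[-1]]
        print(f"  node addition: APL {lo.apl.mean():.2f} (k={K_LIST[0]}) -> "
              f"{hi.apl.mean():.2f} (k={K_LIST[-1]}); "
              f"LCC {lo.lcc.mean():.1f} -> {hi.lcc.mean():.1f}")

    pd.DataFrame(summary).to_csv(OUT / "attack_summary.tsv", sep="\t", index=False)
    if stats_frames:
        pd.concat(stats_frames, ignore_index=True).to_csv(
            OUT / "addition_stats.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
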