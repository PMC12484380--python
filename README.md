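# tickmicro

Seasonal analysis of a tick (*Hyalomma*-type) microbiome from a genus-level
16S count table: diversity, compositional differential abundance, SparCC
co-occurrence networks with keystone-taxon analyses, and network-robustness
simulation. Written for microbial ecologists who have a small sample × taxon
count table with group labels (here: 21 engorged ticks over three seasons)
and want the full downstream pipeline — reproducible, seeded, and testable —
without the point-and-click tools such analyses are usually spread across.

Because the emulated study's raw reads are not an input, the package
includes a synthetic-data generator whose defaults encode the study design
(8/7/6 samples in autumn/spring/summer, a dominant *Francisella*-like hub,
*Rickettsia* absent in spring, planted correlation modules and
season-differential taxa), so every stage can be validated against known
ground truth.

## What it computes

**Diversity.** Observed features, Shannon *H* = −Σ pᵢ ln pᵢ, Pielou
*J* = *H*/ln *S*, Faith's PD (total branch length of the minimal rooted
subtree spanning observed tips), with Kruskal–Wallis tests across seasons;
Bray–Curtis distances with PERMANOVA (pseudo-*F* from the among/within
partition of squared distances, permutation *p*, *R*² = SS_among/SS_total;
pairwise tests BH-adjusted), betadisper-style dispersion ANOVA, Jaccard
clustering and Venn set partitions.

**Differential abundance (ALDEx2-style).** Dirichlet(counts + 0.5)
Monte-Carlo instances of the clr transform, Kruskal–Wallis per taxon per
instance, expected *p* averaged over instances, BH across taxa.

**Co-occurrence networks (SparCC).** From log-ratio variances
T_ij = Var(log xᵢ/xⱼ), basis variances ωᵢ are solved under the sparsity
approximation and correlations ρᵢⱼ = (ωᵢ + ωⱼ − Tᵢⱼ)/(2√(ωᵢωⱼ)) estimated
with iterative exclusion of the most correlated pairs (median over 20
Dirichlet resamplings). Significance by a 1000-replicate permutation
bootstrap (each taxon's counts shuffled independently), BH-adjusted; edges
require |r| ≥ 0.75 **and** adjusted p < 0.05. Ego subnetworks of focal taxa
and exclusion networks (drop the taxon's column, re-infer everything) mirror
the keystone analyses; topology tables report nodes, edges, sign counts,
Louvain modularity on |r|, diameter, average and weighted degree, clustering
coefficient and component count.

**Robustness.** Connectivity loss = 1 − surviving fraction of reachable
ordered node pairs, under random, degree, betweenness and cascading
(betweenness recomputed per removal) attacks, with the node fraction needed
for 80% loss; node-addition experiments (k = 100…1000, density-matched
attachment by default) tracking the largest connected component (LCC) and
the average path length over connected pairs (APL), with Wilcoxon
signed-rank tests against the intact baseline.

Model details, conventions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic dataset, writing tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_diversity.py
python analysis/03_differential_abundance.py
python analysis/04_networks.py      # the slow step (~4 min: 8 bootstrapped networks)
python analysis/05_topology.py
python analysis/06_robustness.py
```

`02_diversity.py` prints:

```
PERMANOVA: R2 = 0.42, p = 0.001 (999 permutations)
pairwise PERMANOVA adjusted p:
  autumn vs spring: p_adj = 0.0015
  autumn vs summer: p_adj = 0.0030
  spring vs summer: p_adj = 0.0015
beta dispersion ANOVA: F = 1.75, p = 0.203
```

so season explains 42% of the Bray–Curtis variance and the clustering is a
location effect, not unequal dispersion. `03_differential_abundance.py`
flags 10 taxa (the 8 planted season-differential taxa, plus *Rickettsia*,
which is structurally absent in spring) — the clr/Kruskal–Wallis stage
recovers exactly the planted signal. `04_networks.py` reports, e.g.:

```
autumn: 55 nodes, 181 edges (8 samples, 60 taxa)
  Francisella: degree 5; ego subnetwork 6 nodes / 11 edges
  Rickettsia: degree 3; ego subnetwork 4 nodes / 6 edges
  without Rickettsia (re-inferred): 56 nodes, 207 edges
spring: ...
  Rickettsia: absent from all spring samples; exclusion network skipped
```

— exclusion networks are re-inferred, not pruned, which is why they can
gain nodes and edges; the spring *Rickettsia* exclusion is impossible by
construction and is skipped with a notice. `06_robustness.py` then shows
the seasonal attack profile (cascading/betweenness most disruptive where
the network has long paths, e.g. summer reaches 80% connectivity loss after
removing 19% of nodes under cascading vs 45% under random attack) and that
node addition drives LCC to n + k while APL stays near 2 under
density-matched attachment.

The same pipeline is available as a single command over a YAML config
(`tickmicro --out results/pipeline --seed 1`), or stage by stage with
`--stage`. Each run echoes its config, seeds and notices into the output
directory, and identical configs reproduce every output byte-for-byte.

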