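# Methods

`tickmicro` implements the downstream analysis of a small seasonal
microbiome study — alpha/beta diversity, compositional differential
abundance, SparCC co-occurrence networks with focal-taxon analyses, and
network-robustness simulation — as a reusable, seeded pipeline over a
sample × taxon count table. Because the study's raw reads are not an input,
the package ships a synthetic-data generator whose defaults encode the
study conditions, so every stage is testable against known ground truth.

## Synthetic data model

Counts are generated by the latent model compositional correlation
estimators assume:

1. Log basis abundances are multivariate normal:
   `log a_s ~ N(mu + delta_g, sigma^2 * C)` with `sigma = 1`, where `C` is the
   planted basis correlation and `delta_g` the group (season) effect.
2. Abundances are closed to proportions `p_s = a_s / sum(a_s)` (they sum to
   1 to machine precision).
3. Counts are `Multinomial(D_s, p_s)` with depth `D_s ~ Poisson(depth_mean)`,
   emulating uneven library sizes.

The correlation structure is built from latent factors, so it is positive
semi-definite for any configuration: each of `n_modules` modules has a
factor on which members load `sqrt(rho)` (pairwise correlation `rho`), and a
hub taxon ("Francisella") is its own factor on which `hub_degree` partners
load `rho` (hub–partner correlation exactly `rho`, partner–partner
`rho^2`). A star-shaped correlation matrix specified directly would not be
PSD for `hub_degree > 1/rho^2`, which is why the factor construction is
used. An explicitly supplied correlation matrix is accepted but rejected if
not PSD.

Default conditions (the study design being emulated):

| parameter | default | rationale |
| --- | --- | --- |
| samples per season | 8 / 7 / 6 (autumn/spring/summer) | the study's 21 engorged ticks |
| `n_taxa` | 60 | per-season detected taxa land in the study's 35–170 range |
| `n_modules` | 4, tiling all non-hub taxa | in the study's networks nearly every detected taxon participates in co-occurrence structure |
| `module_correlation` | 0.98 | see "small-sample edge calling" below |
| `hub_degree` | 10 | a high-connectivity symbiont hub |
| `depth_mean` | 50 000 reads | typical post-QC MiSeq depth |
| absent taxon | "Rickettsia" zeroed in spring; member of module 0 elsewhere | the study's pathogen, undetected in spring, with several strong associations where present |
| differential taxa | 8 taxa at ±4 log2 in one season | the study reported eight season-differential taxa; 16-fold is a clear effect |
| hub baseline | `mu` +3 log units | a dominant nutritional endosymbiont |

The tree is a random binary topology over all taxa with Exp(1) branch
lengths — sufficient for Faith's PD, which only needs a valid rooted tree.

What the generator does *not* emulate: chimeras, contamination and negative
controls, host DNA, tick sex/life-stage covariates, overdispersion beyond
multinomial, and phylogenetic signal in the correlation structure. Passing
tests therefore demonstrate the correctness and calibration of the
*methods*, not field performance on real tick data.

### Small-sample edge calling and the choice of rho = 0.98

Per-pair significance is an empirical permutation p-value with floor
`1/(n_boot+1)`; Benjamini–Hochberg over `d(d-1)/2` pairs can only call
edges if roughly `P/(n_boot·alpha)` pairs sit near that floor. At the
study's 6–8 samples per season the permutation null for SparCC r is very
wide, so pairwise correlations only clear that bar when co-occurrence is
near-deterministic (`rho ≈ 0.98`), which is exactly the regime the study's
dense seasonal networks (51–538 edges from 6–8 ticks) imply for the real
data. Weaker planted correlations at these sample sizes yield empty
networks under honest FDR control; that instability is inherent to the
design and is surfaced in pipeline notices rather than hidden.

## Filtering

Default rule: drop taxa whose **total** count across samples is below
`min_reads = 3`. The stricter per-sample reading ("fewer than 3 reads in
any sample") is available (`rule="per_sample"`) but removes nearly all taxa
in sparse tables; both rules report the dropped taxa.

## Diversity

* Shannon entropy in nats, computed as `ln S − Σ p ln(pS)` — algebraically
  `−Σ p ln p`, but exactly `ln S` on uniform compositions so Pielou
  `J = H / ln S` is exactly 1 there; `J` is undefined (NaN) for samples with
  ≤ 1 observed taxon. Observed features = taxa with count > 0. Faith's PD is
  the total branch length of the minimal rooted subtree spanning the
  observed tips (stem included), via scikit-bio.
* Bray–Curtis on raw counts; no rarefaction anywhere (the emulated analysis
  did not state any).
* PERMANOVA: pseudo-F from the among/within partition of squared distances,
  `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` with `n_perm = 999` default;
  R² = SS_among/SS_total. Implemented in-package because the report exposes
  R²; the statistic is cross-checked against scikit-bio's PERMANOVA in the
  test suite. Pairwise tests are BH-adjusted.
* Beta dispersion: principal-coordinate embedding (axes with positive
  eigenvalues; a warning is recorded when > 10% of the eigenvalue mass is
  negative), per-sample distance to the group centroid, one-way ANOVA.
* Jaccard distances on presence/absence with average-linkage clustering; an
  empty sample is assigned distance 1 to everything and flagged.

## Differential abundance

ALDEx2-style: per sample, `n_mc = 128` Dirichlet(counts + 0.5) Monte-Carlo
draws; clr transform (rows sum to 0); Kruskal–Wallis across seasons per
taxon per instance (vectorized, no tie correction — clr draws are
continuous; checked against scipy); expected p = mean over instances;
BH across taxa. Significance is called on the BH-adjusted expected p at
alpha = 0.05; calls at the raw p and at 0.01 are also emitted, since both
thresholds appear in this analysis tradition. Taxa with identical counts in
every sample get p = 1 by convention. The heatmap matrix reports
across-instance median clr per sample, clipped to [−15, 15].

## SparCC

Per iteration (20 by default), fractions are resampled from
Dirichlet(counts + 1); the log-ratio variance matrix
`T_ij = Var(log x_i/x_j)` satisfies
`T_ij = w_i + w_j − 2 r_ij sqrt(w_i w_j)`. Neglecting covariance sums (the
sparsity approximation), row sums give the linear system
`[(d−2)I + J] w = t`, solved with LAPACK (batched across bootstrap
replicates; singular systems fall back to the pseudo-inverse). The most
strongly correlated pair above 0.1 is then excluded from the system and the
solve repeated, up to 10 rounds; a taxon may lose at most `max(d−3, 1)`
pairs — beyond that its basis equation degenerates and the clipped
correlations saturate at ±1. Final r is the median over iterations, clipped
to [−1, 1], symmetrized, unit diagonal.

Significance: each taxon's counts are permuted across samples independently
(breaking covariance, preserving compositional margins), the full estimator
is re-run per replicate (1000 by default), and the two-sided empirical
p-value per pair is BH-adjusted. Edges require `|r| ≥ 0.75` **and** adjusted
p < 0.05. Nodes are the taxa incident to at least one edge by default;
`include_isolated=True` counts every detected taxon instead (the study's
printed node counts are consistent with either reading, depending on the
table).

Exclusion analysis re-runs the entire inference on the table minus the
focal taxon's column — node deletion cannot reproduce the observed behavior
where exclusion networks *gain* nodes, because removing a dominant taxon
changes every log-ratio.

Known limits: the sparsity approximation fails when a large fraction of
taxa are strongly correlated and `d` is small (≲ 10); null replicates can
then saturate at |r| = 1 and inflate p-values. This is a property of the
estimator class, not of the implementation; the test fixtures for the
small-d examples are sized to stay inside the stable regime.

## Topology

Average degree 2E/N (asserted in every report); weighted degree = mean over
nodes of summed |r|; clustering = mean local unweighted clustering with
degree < 2 contributing 0; diameter = longest shortest path in the largest
connected component (the networks are typically disconnected);
"connectivity" = number of connected components; modularity = Newman
modularity of the best of 10 seeded Louvain restarts on |r| weights
(Louvain is order-dependent; restarts stabilize the value, and the fast
value is tested against the brute-force modularity formula and against
exhaustive partition enumeration on small graphs). Eigenvector centrality
is the principal eigenvector of the |r|-weighted adjacency per connected
component, normalized to max 1; isolated nodes score 0.

## Robustness

Connectivity loss after removing a node set =
`1 − (connected ordered pairs among survivors) / (connected ordered pairs intact)`;
this pair-reachability convention is printed in every report since the
emulated analysis never defines "connectivity". Strategies: `degree` and
`betweenness` rank once on the intact graph; `cascading` recomputes
betweenness after every removal (igraph's C implementation keeps this
tractable); `random` averages ≥ 30 seeded orders with percentile-bootstrap
CIs. Ranking ties break lexicographically by node id, so all curves are
deterministic. The headline `frac_for_80` interpolates linearly between
curve points (curves are step functions with 1/N resolution). The
standard-error summary of the random curve exposes a `variability
threshold` (default 0.9) gating which points enter the scalar summary; the
parameter is inert beyond that, as its intended meaning is not recoverable
from the emulated analysis.

Targeted-beats-random holds on graphs whose centralities distinguish nodes;
on degenerate graphs (e.g. two identical cliques, where every ranking ties)
a lexicographic cascade dismantles one clique at a time and random removal
is genuinely more destructive — the property tests are scoped accordingly.

Node addition: k ∈ {100, 300, 500, 700, 1000} nodes per replicate; the
default attachment wires each new node to every earlier node independently
with probability equal to the intact network's density (the
minimal-assumption reading of "randomly added"); uniform-m and
degree-proportional attachment are selectable. LCC is the largest component
size; APL averages shortest-path lengths over *connected* pairs only, so it
is finite on disconnected graphs (the per-largest-component alternative
would change the baseline, and finite APLs on provably disconnected
networks indicate the connected-pairs convention). Replicates are compared
with the intact baseline by Wilcoxon signed-rank (all-zero differences give
p = 1 by convention), BH-adjusted across the k values. Testing against the
baseline replaces the trivially-true "different from 0" comparison.

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; batched RNG use is ordered,
so a fixed config reproduces all text outputs byte-for-byte (edge CSVs are
sorted with fixed precision for this purpose). The test suite and the
acceptance script size their simulations to desk scale as the package's own
choice of adequate power: SparCC recovery at 60 samples × 40 taxa with
199-replicate bootstraps over 5 seeds; PERMANOVA type-I calibration over
500 null datasets of 18 samples at 199 permutations; clr/KW power at 20
samples per group over 20 seeds; robustness oracles on graphs ≤ 12 nodes
with exhaustive removal sets ≤ 3.

## Known limitations

* Per-season inference from 6–8 samples is intrinsically unstable; seeds
  and notices make this visible rather than smoothing it over.
* SparCC small-d pathologies (above).
* Louvain modularity is a heuristic lower bound on the optimum; restarts
  mitigate but do not remove this.
* The beta-dispersion embedding discards negative-eigenvalue axes; with
  strongly non-Euclidean distances the centroid distances are approximate
  (the warning flag reports when this matters).
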