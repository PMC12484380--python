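"""Synthetic seasonal microbiome data with known ground truth.

The generator emulates a genus-level amplicon count table from a small
seasonal study: three groups of samples (autumn/spring/summer), a
compositional count matrix produced by multinomial sampling of log-normal
latent abundances, planted positive-correlation modules, one
high-connectivity hub taxon ("Francisella", the dominant endosymbiont),
one taxon absent from a whole group ("Rickettsia" in spring) and a set of
group-differential taxa.

The latent model is the one compositional correlation estimators assume:
log basis abundances are multivariate normal with a prescribed correlation
matrix, closed to proportions, then multinomially sampled at a Poisson
sequencing depth. Correlation structure is built through latent factors
(one per module plus one for the hub), which guarantees a positive
semi-definite basis correlation for any hub degree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import skbio

from tickmicro.tables_io import CooccurrenceNetwork, CountTable

__all__ = [
    "SyntheticTruth",
    "generate_seasonal_counts",
    "generate_tree",
    "generate_toy_graph",
    "DEFAULT_GROUPS",
]

DEFAULT_GROUPS = ("autumn", "spring", "summer")
HUB_TAXON = "Francisella"
ABSENT_TAXON = "Rickettsia"


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated count table."""

    basis_correlation: pd.DataFrame
    module_assignment: dict[str, int]
    hub_taxa: list[str]
    hub_partners: list[str]
    absent_in_group: dict[str, str]
    differential_taxa: dict[str, tuple[str, float]]
    seed: int

    def __post_init__(self) -> None:
        c = self.basis_correlation.to_numpy()
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("basis correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("basis correlation must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-8:
            raise ValueError("basis correlation must be positive semi-definite")

    @property
    def taxa(self) -> list[str]:
        return list(self.basis_correlation.index)

    def planted_pairs(self, min_corr: float = 0.5) -> list[tuple[str, str]]:
        """Taxon pairs whose planted basis correlation is >= ``min_corr``."""
        c = self.basis_correlation.to_numpy()
        taxa = self.taxa
        out = []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                if c[i, j] >= min_corr:
                    out.append((taxa[i], taxa[j]))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "taxa": self.taxa,
            "module_assignment": self.module_assignment,
            "hub_taxa": self.hub_taxa,
            "hub_partners": self.hub_partners,
            "absent_in_group": self.absent_in_group,
            "differential_taxa": {
                t: {"group": g, "log2_effect": e}
                for t, (g, e) in self.differential_taxa.items()
            },
            "seed": self.seed,
            "basis_correlation": self.basis_correlation.round(10).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _taxon_names(n_taxa: int) -> list[str]:
    names = [HUB_TAXON, ABSENT_TAXON]
    names += [f"Taxon_{i:03d}" for i in range(3, n_taxa + 1)]
    return names[:n_taxa]


def _build_correlation(
    taxa: list[str],
    n_modules: int,
    module_correlation: float,
    hub_degree: int,
) -> tuple[np.ndarray, dict[str, int], list[str]]:
    """Factor-model basis correlation: block modules plus one hub star.

    Module members load sqrt(rho) on their module factor (pairwise
    correlation rho); hub partners load rho on the hub factor (hub-partner
    correlation rho, partner-partner rho^2). PSD by construction. The
    group-absent taxon (index 1) joins the first module where it is present,
    emulating a pathogen with several strong seasonal associations.
    """
    d = len(taxa)
    rho = module_correlation
    # taxon 0 (hub) stays out of modules; taxon 1 joins module 0 below.
    # Modules tile all taxa left after reserving the hub's partners: in the
    # emulated data most detected taxa take part in co-occurrence structure.
    pool = list(range(2, d))
    module_size = max(2, (d - 2 - hub_degree) // n_modules) if n_modules else 0
    modules: dict[str, int] = {}
    loadings = np.zeros((d, n_modules + 1))
    k = 0
    for m in range(n_modules):
        members = pool[k : k + module_size]
        if len(members) < 2:
            raise ValueError(
                f"cannot place {n_modules} modules of size >= 2 in {d} taxa"
            )
        k += module_size
        if m == 0 and d > 2:
            members = [1] + list(members)
        for i in members:
            modules[taxa[i]] = m
            loadings[i, m] = np.sqrt(rho)
    free = pool[k:]
    if hub_degree > len(free):
        raise ValueError(
            f"hub_degree={hub_degree} exceeds the {len(free)} taxa left outside modules"
        )
    partners = free[:hub_degree]
    loadings[0, n_modules] = 1.0  # hub is its own factor
    for i in partners:
        loadings[i, n_modules] = rho
    corr = loadings @ loadings.T
    np.fill_diagonal(corr, 1.0)
    return corr, modules, [taxa[i] for i in partners]


def generate_seasonal_counts(
    n_samples_per_group: tuple[int, int, int] = (8, 7, 6),
    n_taxa: int = 60,
    n_modules: int = 4,
    module_correlation: float = 0.98,
    hub_degree: int = 10,
    depth_mean: int = 50_000,
    seed: int = 0,
    *,
    group_labels: tuple[str, ...] = DEFAULT_GROUPS,
    absent_in_group: dict[str, str] | None = None,
    differential_taxa: dict[str, tuple[str, float]] | None = None,
    basis_correlation: np.ndarray | None = None,
    log_sd: float = 1.0,
    tree: bool = True,
) -> tuple[CountTable, SyntheticTruth, skbio.TreeNode | None]:
    """Generate a seasonal compositional count table with planted structure.

    Parameters mirror the study design being emulated: 21 samples in three
    seasons (8/7/6), a dominant hub taxon correlated with ``hub_degree``
    partners at ``module_correlation``, ``n_modules`` positive-correlation
    blocks, "Rickettsia" absent from spring, and group-differential taxa
    shifted on the log scale by a stated log2 effect.

    Returns the count table, the ground truth, and a random rooted binary
    tree over all taxa (Exp(1) branch lengths), or None if ``tree=False``.
    """
    if len(n_samples_per_group) != len(group_labels):
        raise ValueError("need one sample size per group label")
    if n_taxa < 2 * n_modules:
        raise ValueError(f"n_taxa={n_taxa} must be >= 2*n_modules={2 * n_modules}")
    if hub_degree >= n_taxa:
        raise ValueError("hub_degree must be < n_taxa")
    if depth_mean < 100:
        raise ValueError("depth_mean must be >= 100")
    if not (0 <= module_correlation < 1):
        raise ValueError("module_correlation must be in [0, 1)")

    taxa = _taxon_names(n_taxa)
    if absent_in_group is None:
        absent_in_group = {ABSENT_TAXON: "spring"} if "spring" in group_labels else {}
    if differential_taxa is None:
        differential_taxa = _default_differential(taxa, group_labels)
    for t in list(absent_in_group) + list(differential_taxa):
        if t not in taxa:
            raise ValueError(f"unknown taxon {t!r} in planted effects")

    if basis_correlation is not None:
        corr = np.asarray(basis_correlation, dtype=float)
        if corr.shape != (n_taxa, n_taxa):
            raise ValueError("basis_correlation shape must be (n_taxa, n_taxa)")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("requested correlation structure is not symmetric")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError(
                "requested correlation structure is not positive semi-definite "
                f"(min eigenvalue {np.linalg.eigvalsh(corr).min():.3g})"
            )
        modules, partners = {}, []
    else:
        corr, modules, partners = _build_correlation(
            taxa, n_modules, module_correlation, hub_degree
        )

    rng = np.random.default_rng(seed)
    d = n_taxa
    # heterogeneous baseline log-abundances; hub boosted to dominance
    mu = rng.normal(0.0, 1.0, size=d)
    mu[0] += 3.0

    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(d))
    groups_per_sample: list[str] = []
    sample_ids: list[str] = []
    rows = []
    for label, n_g in zip(group_labels, n_samples_per_group):
        shift = np.zeros(d)
        for t, (g, log2_eff) in differential_taxa.items():
            if g == label:
                shift[taxa.index(t)] += log2_eff * np.log(2.0)
        z = rng.standard_normal((n_g, d)) @ chol.T
        log_abund = mu + shift + log_sd * z
        abund = np.exp(log_abund)
        for t, g in absent_in_group.items():
            if g == label:
                abund[:, taxa.index(t)] = 0.0
        props = abund / abund.sum(axis=1, keepdims=True)
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)
        depths = rng.poisson(depth_mean, size=n_g)
        if (depths == 0).any():
            raise ValueError("drew a zero sequencing depth; increase depth_mean")
        for i in range(n_g):
            rows.append(rng.multinomial(depths[i], props[i]))
        sample_ids += [f"{label}_{i + 1:02d}" for i in range(n_g)]
        groups_per_sample += [label] * n_g

    counts = pd.DataFrame(
        np.vstack(rows), index=sample_ids, columns=taxa, dtype=np.int64
    )
    counts.index.name = "sample_id"
    table = CountTable(counts, pd.Series(groups_per_sample, index=sample_ids, name="group"))
    truth = SyntheticTruth(
        basis_correlation=pd.DataFrame(corr, index=taxa, columns=taxa),
        module_assignment=modules,
        hub_taxa=[taxa[0]] if partners else [],
        hub_partners=partners,
        absent_in_group=dict(absent_in_group),
        differential_taxa=dict(differential_taxa),
        seed=seed,
    )
    phylo = generate_tree(taxa, seed=seed) if tree else None
    return table, truth, phylo


def _default_differential(
    taxa: list[str], group_labels: tuple[str, ...]
) -> dict[str, tuple[str, float]]:
    """Eight group-differential taxa (the study detected eight), log2 effect 4."""
    if len(group_labels) < 2 or len(taxa) < 30:
        return {}
    chosen = [f"Taxon_{i:03d}" for i in range(20, 28)]
    chosen = [t for t in chosen if t in taxa]
    out: dict[str, tuple[str, float]] = {}
    for i, t in enumerate(chosen):
        out[t] = (group_labels[i % len(group_labels)], 4.0 if i % 2 == 0 else -4.0)
    return out


def generate_tree(taxa: list[str], seed: int = 0) -> skbio.TreeNode:
    """Random rooted binary tree over ``taxa`` with Exp(1) branch lengths."""
    rng = np.random.default_rng(seed)
    nodes = []
    for t in taxa:
        leaf = skbio.TreeNode(name=t)
        leaf.length = float(rng.exponential(1.0))
        nodes.append(leaf)
    if len(nodes) == 1:
        root = skbio.TreeNode(children=nodes)
        root.length = None
        return root
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(children=[a, b])
        parent.length = float(rng.exponential(1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


TOY_KINDS = ("star", "path", "complete", "two_cliques", "erdos_renyi")


def generate_toy_graph(
    kind: str, n: int, p: float = 0.1, seed: int = 0
) -> CooccurrenceNetwork:
    """Named toy graph with unit positive edge weights, for oracle tests.

    Nodes are labelled ``n00..`` so lexicographic tie-breaks are stable.
    ``two_cliques`` splits ``n`` nodes into two disjoint cliques;
    ``erdos_renyi`` is G(n, p) with the given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "star":
        g = nx.star_graph(n - 1)
    elif kind == "path":
        g = nx.path_graph(n)
    elif kind == "complete":
        g = nx.complete_graph(n)
    elif kind == "two_cliques":
        half = n // 2
        g = nx.disjoint_union(nx.complete_graph(half), nx.complete_graph(n - half))
    elif kind == "erdos_renyi":
        if not (0 <= p <= 1):
            raise ValueError("p must be in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ValueError(f"unknown toy graph kind {kind!r}; expected one of {TOY_KINDS}")
    width = max(2, len(str(n - 1)))
    g = nx.relabel_nodes(g, {v: f"n{v:0{width}d}" for v in g.nodes})
    for _, _, d in g.edges(data=True):
        d["weight"] = 1.0
        d["sign"] = "+"
        d["p_adj"] = 0.0
    return CooccurrenceNetwork(g, threshold_r=0.75, alpha=0.05, name=f"{kind}_{n}")
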