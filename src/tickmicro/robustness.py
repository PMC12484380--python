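"""Network robustness: attack simulations and node-addition experiments.

Connectivity of a graph is measured by the number of ordered node pairs
joined by a path; the *connectivity loss* after removing a node set is
``1 - pairs(surviving) / pairs(intact)``. Four removal strategies are
simulated: random order (averaged over replicates with bootstrap confidence
intervals), descending degree, descending betweenness (both ranked once on
the intact graph), and cascading (betweenness re-ranked after every
removal). The headline summary is the fraction of nodes whose removal first
drives the loss to 0.8, linearly interpolated between curve points. Ranking
ties are broken lexicographically by node id so every curve is
deterministic. Betweenness is computed with igraph's C core; everything else
operates on networkx containers.

Node addition grows the network by k new nodes wired in by an attachment
rule (default: each new node links to every earlier node independently with
probability equal to the intact network's density) and tracks the largest
connected component (LCC) and average path length (APL) per replicate. APL
averages shortest-path lengths over *connected* pairs only, so it stays
finite on disconnected graphs. Replicates are compared with the intact
baseline by Wilcoxon signed-rank tests, Benjamini-Hochberg adjusted across
the set of k values.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as sps
from scipy.sparse.csgraph import connected_components, shortest_path
from statsmodels.stats.multitest import multipletests

from tickmicro.tables_io import CooccurrenceNetwork

__all__ = [
    "AttackResult",
    "AdditionResult",
    "connectivity_loss",
    "attack",
    "loss_se",
    "add_random_nodes",
    "addition_stats",
    "lcc_and_apl",
    "ATTACK_STRATEGIES",
    "ATTACHMENT_RULES",
]

ATTACK_STRATEGIES = ("random", "degree", "betweenness", "cascading")
ATTACHMENT_RULES = ("density", "uniform", "degree")


# ---------------------------------------------------------------------------
# connectivity loss
# ---------------------------------------------------------------------------

def _connected_ordered_pairs(g: nx.Graph) -> int:
    return sum(len(c) * (len(c) - 1) for c in nx.connected_components(g))


def connectivity_loss(net: CooccurrenceNetwork | nx.Graph, removed) -> float:
    """1 - surviving fraction of reachable ordered node pairs."""
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    removed = set(removed)
    unknown = removed - set(g.nodes)
    if unknown:
        raise ValueError(f"removed nodes not in graph: {sorted(unknown)}")
    base = _connected_ordered_pairs(g)
    if base == 0:
        return 0.0
    surviving = g.subgraph(n for n in g.nodes if n not in removed)
    return 1.0 - _connected_ordered_pairs(surviving) / base


# ---------------------------------------------------------------------------
# attacks
# ---------------------------------------------------------------------------

def _to_igraph(g: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = sorted(g.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    h = ig.Graph(n=len(nodes), edges=edges, directed=False)
    return h, nodes

def _loss_curve_for_order(g: nx.Graph, order: list) -> np.ndarray:
    """Loss after removing order[:m] for m = 0..N (igraph-backed)."""
    h, nodes = _to_igraph(g)
    index = {n: i for i, n in enumerate(nodes)}
    base = sum(s * (s - 1) for s in h.connected_components().sizes())
    n = len(nodes)
    losses = np.zeros(n + 1)
    if base == 0:  # edgeless graph: no reachable pairs to lose
        return losses
    alive = h.copy()  # igraph reindexes on deletion, so track names
    alive.vs["name"] = [str(x) for x in nodes]
    for m, node in enumerate(order, start=1):
        alive.delete_vertices(alive.vs.find(name=str(node)).index)
        pairs = sum(s * (s - 1) for s in alive.connected_components().sizes())
        losses[m] = 1.0 - pairs / base
    return losses


def _cascading_curve(g: nx.Graph) -> tuple[np.ndarray, list]:
    h, nodes = _to_igraph(g)
    base = sum(s * (s - 1) for s in h.connected_components().sizes())
    n = len(nodes)
    h.vs["name"] = [str(x) for x in nodes]
    losses = np.zeros(n + 1)
    order = []
    for m in range(1, n + 1):
        bet = np.asarray(h.betweenness())
        names = h.vs["name"]
        best = min(range(len(names)), key=lambda i: (-bet[i], names[i]))
        order.append(names[best])
        h.delete_vertices(best)
        if base:
            pairs = sum(s * (s - 1) for s in h.connected_components().sizes())
            losses[m] = 1.0 - pairs / base
    return losses, order


@dataclass
class AttackResult:
    """Connectivity-loss curve for one removal strategy."""

    strategy: str
    fractions: np.ndarray  # removed fraction at each curve point (0..1)
    loss: np.ndarray  # mean loss curve (random) or the single curve
    frac_for_80: float
    removal_order: list | None = None
    n_reps: int = 1
    loss_reps: np.ndarray | None = None  # (n_reps, points) for random
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    ci_level: float = 0.95


def _frac_for_loss(fractions: np.ndarray, loss: np.ndarray, target: float = 0.8) -> float:
    """Smallest removed fraction with loss >= target, linearly interpolated."""
    idx = np.flatnonzero(loss >= target)
    if len(idx) == 0:
        return float("nan")
    i = idx[0]
    if i == 0 or loss[i] == target:
        return float(fractions[i])
    x0, x1 = fractions[i - 1], fractions[i]
    y0, y1 = loss[i - 1], loss[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))


def attack(
    net: CooccurrenceNetwork | nx.Graph,
    strategy: str,
    seed: int = 0,
    n_reps: int = 100,
    ci_level: float = 0.95,
    n_boot_ci: int = 1000,
) -> AttackResult:
    """Simulate node removal under one strategy and score the loss curve.

    ``degree`` and ``betweenness`` rank nodes once on the intact graph;
    ``cascading`` re-ranks betweenness after every removal; ``random``
    averages ``n_reps`` seeded removal orders and attaches percentile
    bootstrap confidence intervals to the mean curve.
    """
    if strategy not in ATTACK_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {ATTACK_STRATEGIES}")
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot attack an empty graph")
    fractions = np.arange(n + 1) / n

    if strategy == "random":
        if n_reps < 30:
            raise ValueError("random strategy needs n_reps >= 30")
        rng = np.random.default_rng(seed)
        reps = np.empty((n_reps, n + 1))
        for r in range(n_reps):
            order = list(rng.permutation(nodes))
            reps[r] = _loss_curve_for_order(g, order)
        mean = reps.mean(axis=0)
        boot_idx = rng.integers(0, n_reps, size=(n_boot_ci, n_reps))
        boot_means = reps[boot_idx].mean(axis=1)
        lo = np.quantile(boot_means, (1 - ci_level) / 2, axis=0)
        hi = np.quantile(boot_means, 1 - (1 - ci_level) / 2, axis=0)
        return AttackResult(
            strategy, fractions, mean, _frac_for_loss(fractions, mean),
            removal_order=None, n_reps=n_reps, loss_reps=reps,
            ci_low=lo, ci_high=hi, ci_level=ci_level,
        )

    if strategy == "degree":
        order = sorted(nodes, key=lambda v: (-g.degree(v), str(v)))
        losses = _loss_curve_for_order(g, order)
    elif strategy == "betweenness":
        h, ig_nodes = _to_igraph(g)
        bet = np.asarray(h.betweenness())
        order = [v for _, v in sorted(zip(-bet, map(str, ig_nodes)))]
        losses = _loss_curve_for_order(g, order)
    else:  # cascading
        losses, order = _cascading_curve(g)
    return AttackResult(
        strategy, fractions, losses, _frac_for_loss(fractions, losses),
        removal_order=list(order),
    )


def loss_se(result: AttackResult, variability_threshold: float = 0.9) -> dict:
    """Per-point standard error of the random-attack loss curve.

    ``variability_threshold`` gates which curve points enter the scalar
    summary (points whose mean loss is <= the threshold); it does not alter
    the per-point SEs.
    """
    if result.loss_reps is None or result.n_reps < 2:
        raise ValueError("per-point SE needs a random attack with >= 2 replicates")
    se = result.loss_reps.std(axis=0, ddof=1) / np.sqrt(result.n_reps)
    mask = result.loss <= variability_threshold
    return {
        "fractions": result.fractions,
        "se": se,
        "summary_mask": mask,
        "mean_se_below_threshold": float(se[mask].mean()) if mask.any() else float("nan"),
        "variability_threshold": variability_threshold,
    }


# ---------------------------------------------------------------------------
# node addition
# ---------------------------------------------------------------------------

def lcc_and_apl(adj: sp.spmatrix) -> tuple[int, float]:
    """Largest-component size and mean shortest-path length over connected pairs."""
    n = adj.shape[0]
    if n == 0:
        return 0, float("nan")
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    lcc = int(sizes.max())
    if (sizes > 1).sum() == 0:
        return lcc, float("nan")
    dist = shortest_path(adj, method="D", directed=False, unweighted=True)
    finite = np.isfinite(dist) & (dist > 0)
    return lcc, float(dist[finite].mean())


def _graph_to_sparse(g: nx.Graph) -> tuple[sp.csr_matrix, list]:
    nodes = sorted(g.nodes, key=str)
    return nx.to_scipy_sparse_array(g, nodelist=nodes, weight=None, format="csr"), nodes


@dataclass
class AdditionResult:
    """LCC/APL distributions after adding k nodes under an attachment rule."""

    k: int
    attachment: str
    lcc: np.ndarray  # per replicate
    apl: np.ndarray  # per replicate
    baseline_lcc: int
    baseline_apl: float
    n_reps: int
    seed: int = 0

    def summary(self) -> dict:
        return {
            "k": self.k,
            "attachment": self.attachment,
            "lcc_mean": float(self.lcc.mean()),
            "lcc_min": float(self.lcc.min()),
            "lcc_max": float(self.lcc.max()),
            "apl_mean": float(np.nanmean(self.apl)),
            "apl_min": float(np.nanmin(self.apl)),
            "apl_max": float(np.nanmax(self.apl)),
            "baseline_lcc": self.baseline_lcc,
            "baseline_apl": self.baseline_apl,
            "n_reps": self.n_reps,
        }


def add_random_nodes(
    net: CooccurrenceNetwork | nx.Graph,
    k: int,
    attachment: str = "density",
    n_reps: int = 30,
    seed: int = 0,
    attach_p: float | None = None,
    m_edges: int = 2,
) -> AdditionResult:
    """Add k nodes per replicate and measure LCC and APL.

    Rules: ``density`` wires each new node to every earlier node (original or
    previously added) independently with probability ``attach_p`` (default:
    the intact network's density); ``uniform`` attaches each new node to
    ``m_edges`` earlier nodes chosen uniformly; ``degree`` chooses the
    ``m_edges`` targets with probability proportional to current degree + 1.
    """
    if attachment not in ATTACHMENT_RULES:
        raise ValueError(f"unknown attachment rule {attachment!r}; expected one of {ATTACHMENT_RULES}")
    if k < 0:
        raise ValueError("k must be >= 0")
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    adj0, nodes = _graph_to_sparse(g)
    n = len(nodes)
    base_lcc, base_apl = lcc_and_apl(adj0)
    if k == 0:
        return AdditionResult(
            0, attachment, np.full(max(n_reps, 1), base_lcc),
            np.full(max(n_reps, 1), base_apl), base_lcc, base_apl,
            max(n_reps, 1), seed,
        )
    if n == 0:
        raise ValueError("cannot add nodes to an empty graph")
    density = 2 * g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    p = density if attach_p is None else attach_p
    rng = np.random.default_rng(seed)
    lccs = np.empty(n_reps)
    apls = np.empty(n_reps)
    rows0, cols0 = adj0.nonzero()
    for rep in range(n_reps):
        rows = list(rows0)
        cols = list(cols0)
        if attachment == "degree":
            deg = np.zeros(n + k)
            deg[:n] = np.asarray(adj0.sum(axis=1)).ravel()
        for new in range(n, n + k):
            if attachment == "density":
                mask = rng.random(new) < p
                targets = np.flatnonzero(mask)
            elif attachment == "uniform":
                targets = rng.choice(new, size=min(m_edges, new), replace=False)
            else:
                w = deg[:new] + 1.0
                targets = rng.choice(new, size=min(m_edges, new), replace=False, p=w / w.sum())
                deg[targets] += 1
                deg[new] += len(targets)
            for t in targets:
                rows += [new, t]
                cols += [t, new]
        total = n + k
        adj = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(total, total)
        )
        lccs[rep], apls[rep] = lcc_and_apl(adj)
    return AdditionResult(k, attachment, lccs, apls, base_lcc, base_apl, n_reps, seed)


def _wilcoxon_vs_baseline(values: np.ndarray, baseline: float) -> float:
    diffs = np.asarray(values, dtype=float) - baseline
    diffs = diffs[~np.isnan(diffs)]
    if len(diffs) == 0 or np.all(diffs == 0):
        return 1.0  # identical to baseline by convention
    stat = sps.wilcoxon(diffs, zero_method="wilcox")
    return float(stat.pvalue)


def addition_stats(results: dict[int, AdditionResult]) -> pd.DataFrame:
    """Wilcoxon signed-rank tests of LCC/APL vs the intact baseline, per k.

    p-values are Benjamini-Hochberg adjusted across the set of k values,
    separately for LCC and APL.
    """
    ks = sorted(results)
    for k in ks:
        if results[k].n_reps < 10:
            raise ValueError("addition_stats needs >= 10 replicates per k")
    rows = []
    for k in ks:
        r = results[k]
        rows.append(
            {
                "k": k,
                "lcc_mean": float(r.lcc.mean()),
                "apl_mean": float(np.nanmean(r.apl)),
                "baseline_lcc": r.baseline_lcc,
                "baseline_apl": r.baseline_apl,
                "wilcoxon_p_lcc": _wilcoxon_vs_baseline(r.lcc, r.baseline_lcc),
                "wilcoxon_p_apl": _wilcoxon_vs_baseline(r.apl, r.baseline_apl),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj_lcc"] = multipletests(out["wilcoxon_p_lcc"], method="fdr_bh")[1]
        out["p_adj_apl"] = multipletests(out["wilcoxon_p_apl"], method="fdr_bh")[1]
    return out
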