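"""Alpha/beta diversity, permutation inference, clustering and set comparisons.

Alpha metrics follow the QIIME-style definitions: observed features is the
count of taxa with nonzero counts; Shannon entropy is in natural log (nats),
so Pielou's evenness is exactly H / ln(S) and equals 1 on uniform
compositions; Faith's PD is the total branch length of the minimal rooted
subtree spanning the observed tips (stem to the root included). Beta
diversity uses Bray-Curtis on raw counts; inference is a permutation
PERMANOVA (pseudo-F on partitioned squared distances) with pairwise tests
adjusted by Benjamini-Hochberg, and a betadisper-style homogeneity test
(ANOVA on distances to group centroids in principal-coordinate space).
Counts are not rarefied; metrics run on the filtered table as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as sps
import skbio
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

from tickmicro.tables_io import CountTable

__all__ = [
    "AlphaReport",
    "BetaReport",
    "alpha_diversity",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "beta_dispersion",
    "jaccard_cluster",
    "venn_sets",
]

ALPHA_METRICS = ("observed_features", "shannon", "pielou", "faith_pd")


@dataclass
class AlphaReport:
    """Per-sample alpha diversity plus per-metric Kruskal-Wallis tests."""

    per_sample: pd.DataFrame  # index sample, columns metrics + group
    kruskal: pd.DataFrame  # index metric, columns H, p


@dataclass
class BetaReport:
    distances: pd.DataFrame
    permanova: dict
    pairwise: pd.DataFrame
    dispersion: dict


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: CountTable, tree: skbio.TreeNode | None = None) -> AlphaReport:
    """Observed features, Shannon (nats), Pielou and Faith's PD per sample.

    Pielou is reported missing (NaN) for samples with <= 1 observed taxon;
    Faith's PD requires ``tree`` and errors if any detected taxon is not a
    tip of it.
    """
    counts = table.matrix().astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")

    observed = (counts > 0).sum(axis=1)
    props = counts / totals[:, None]
    # H = ln(S) - sum p ln(p S): algebraically identical to -sum p ln p but
    # exactly ln(S) (hence Pielou exactly 1) on uniform compositions
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = props * observed[:, None]
        plogp = np.where(props > 0, props * np.log(scaled), 0.0)
    shannon = np.log(observed) - plogp.sum(axis=1)
    pielou = np.full(len(observed), np.nan)
    multi = observed > 1
    pielou[multi] = shannon[multi] / np.log(observed[multi])

    data = {
        "observed_features": observed,
        "shannon": shannon,
        "pielou": pielou,
    }
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        detected = set(table.detected_taxa())
        missing = sorted(detected - tip_names)
        if missing:
            raise ValueError(f"tree is missing detected taxa: {missing}")
        data["faith_pd"] = np.array(
            [
                _skbio_faith_pd(row.astype(int), table.taxon_ids, tree, validate=False)
                for row in counts
            ]
        )

    per_sample = pd.DataFrame(data, index=table.sample_ids)
    per_sample["group"] = table.group.to_numpy()

    rows = {}
    labels = table.group.to_numpy()
    for metric in per_sample.columns.drop("group"):
        vals = per_sample[metric].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        groups = [vals[ok & (labels == g)] for g in table.groups()]
        groups = [g for g in groups if len(g)]
        if len(groups) < 2 or all(np.all(g == groups[0][0]) for g in groups):
            rows[metric] = (np.nan, np.nan)
            continue
        try:
            h, p = sps.kruskal(*groups)
        except ValueError:  # all values identical
            h, p = np.nan, 1.0
        rows[metric] = (h, p)
    kruskal = pd.DataFrame(rows, index=["H", "p"]).T
    return AlphaReport(per_sample, kruskal)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: CountTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity on raw counts, as a symmetric DataFrame."""
    counts = table.matrix().astype(float)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis undefined for empty samples")
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(counts, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _as_square(dist: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    if isinstance(dist, pd.DataFrame):
        return dist.to_numpy(dtype=float), list(dist.index)
    arr = np.asarray(dist, dtype=float)
    return arr, list(range(arr.shape[0]))


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_among, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total - ss_within, ss_within


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutation MANOVA on a distance matrix.

    pseudo-F partitions squared distances among/within groups; p uses the
    (1 + #{F_perm >= F_obs}) / (1 + n_perm) estimator; R2 = SS_among/SS_total.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    d, ids = _as_square(dist)
    labels = np.asarray(pd.Series(groups).reindex(ids).to_numpy() if isinstance(groups, (pd.Series, dict)) else groups)
    if len(labels) != d.shape[0]:
        raise ValueError("group labels do not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2 or np.bincount(codes).min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = d.shape[0]
    d2 = d**2
    ss_among, ss_within = _permanova_ss(d2, codes, a)
    ss_total = ss_among + ss_within
    f_obs = (ss_among / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        sa, sw = _permanova_ss(d2, perm, a)
        f_perm = (sa / (a - 1)) / (sw / (n - a)) if sw > 0 else np.inf
        if f_perm >= f_obs:
            count += 1
    return {
        "pseudo_F": float(f_obs),
        "R2": float(ss_among / ss_total) if ss_total > 0 else np.nan,
        "p": (1 + count) / (1 + n_perm),
        "n_permutations": n_perm,
    }


def pairwise_permanova(
    dist: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """All group-pair PERMANOVAs with Benjamini-Hochberg adjustment."""
    labels = groups.reindex(dist.index)
    uniq = list(dict.fromkeys(labels))
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            pair = (uniq[i], uniq[j])
            mask = labels.isin(pair).to_numpy()
            if min((labels == pair[0]).sum(), (labels == pair[1]).sum()) < 2:
                raise ValueError(f"group pair {pair} has a group with < 2 samples")
            sub = dist.loc[mask, mask]
            res = permanova(sub, labels[mask].to_numpy(), n_perm=n_perm, seed=seed + i * 101 + j)
            rows.append({"group_a": pair[0], "group_b": pair[1], "pseudo_F": res["pseudo_F"], "p": res["p"]})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def beta_dispersion(dist: pd.DataFrame, groups: pd.Series) -> dict:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Samples are embedded by principal coordinates (axes with positive
    eigenvalues); each sample's distance to its group centroid is tested
    across groups with one-way ANOVA. If more than 10% of the total
    eigenvalue mass is negative a warning flag is set in the report.
    """
    d, ids = _as_square(dist)
    labels = groups.reindex(ids).to_numpy()
    dm = skbio.DistanceMatrix(d, ids=[str(i) for i in ids])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ord_res = _skbio_pcoa(dm, method="eigh")
    eig = ord_res.eigvals.to_numpy()
    neg_mass = float(np.abs(eig[eig < 0]).sum() / np.abs(eig).sum()) if np.abs(eig).sum() > 0 else 0.0
    pos = eig > 0
    coords = ord_res.samples.to_numpy()[:, pos]
    dists = np.zeros(len(ids))
    for g in np.unique(labels):
        idx = labels == g
        centroid = coords[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    arrays = [dists[labels == g] for g in np.unique(labels)]
    if np.allclose(dists, 0) or len(arrays) < 2:
        f_stat, p = np.nan, np.nan
    else:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_stat, p = sps.f_oneway(*arrays)
        if not np.isfinite(f_stat):
            f_stat, p = np.nan, np.nan
    return {
        "distance_to_centroid": pd.Series(dists, index=ids),
        "anova_F": float(f_stat) if np.isfinite(f_stat) else np.nan,
        "p": float(p) if np.isfinite(p) else np.nan,
        "negative_eigenvalue_mass": neg_mass,
        "negative_eigenvalue_warning": neg_mass > 0.10,
    }


# ---------------------------------------------------------------------------
# clustering and set comparisons
# ---------------------------------------------------------------------------

def jaccard_distances(table: CountTable) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Jaccard distances on presence/absence; empty samples flagged.

    An empty presence set is assigned distance 1 to every other sample by
    convention; such samples are returned in the second element.
    """
    presence = table.matrix() > 0
    inter = (presence[:, None, :] & presence[None, :, :]).sum(axis=2)
    union = (presence[:, None, :] | presence[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(union > 0, 1.0 - inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    empty = [s for s, e in zip(table.sample_ids, presence.sum(axis=1) == 0) if e]
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids), empty


def jaccard_cluster(table: CountTable, n_clusters: int | None = None) -> dict:
    """Average-linkage hierarchical clustering on Jaccard distances."""
    dmat, empty = jaccard_distances(table)
    from scipy.spatial.distance import squareform

    condensed = squareform(dmat.to_numpy(), checks=False)
    linkage = sch.linkage(condensed, method="average")
    if n_clusters is None:
        n_clusters = len(table.groups())
    flat = sch.fcluster(linkage, t=n_clusters, criterion="maxclust")
    leaves = sch.leaves_list(linkage)
    return {
        "distances": dmat,
        "linkage": linkage,
        "leaf_order": [table.sample_ids[i] for i in leaves],
        "assignment": pd.Series(flat, index=table.sample_ids),
        "empty_samples": empty,
    }


def venn_sets(named_sets: dict[str, set]) -> dict:
    """Partition the union of named sets into exclusive Venn regions.

    Returns ``{"regions": {frozenset(names): sorted members}, "counts": ...}``;
    every element of the union appears in exactly one region.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two named sets")
    universe = set().union(*named_sets.values())
    regions: dict[frozenset, list] = {}
    for item in universe:
        key = frozenset(n for n, s in named_sets.items() if item in s)
        regions.setdefault(key, []).append(item)
    regions = {k: sorted(v) for k, v in regions.items()}
    return {
        "regions": regions,
        "counts": {k: len(v) for k, v in regions.items()},
        "union_size": len(universe),
    }
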