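"""SparCC correlation inference, bootstrap significance and network building.

SparCC estimates taxon-taxon correlations from compositional counts without
access to absolute abundances. Per iteration, fractions are resampled from
Dirichlet(counts + 1); the pairwise log-ratio variance matrix
``T_ij = Var(log x_i / x_j)`` decomposes as
``T_ij = w_i + w_j - 2 rho_ij sqrt(w_i w_j)`` in terms of unobserved basis
variances ``w``. Under the sparsity approximation (most correlations are
weak, so covariance sums are neglected), the row sums of T give a linear
system ``[(d-2) I + J] w = t`` for the basis variances, after which
``rho_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j))``. Strongly correlated
pairs violate the approximation, so the most correlated pair above a
threshold is iteratively excluded from the system and the solve repeated.
The reported correlation is the median over iterations, clipped to [-1, 1].

Significance is assessed against a permutation null: each taxon's counts are
permuted across samples independently (destroying covariance, preserving
margins), SparCC is re-run, and the two-sided empirical p-value per pair is
``(1 + #{|r_null| >= |r_obs|}) / (1 + n_boot)``, Benjamini-Hochberg adjusted
over all pairs. Edges require both |r| >= threshold_r and adjusted p < alpha.

All heavy paths are vectorized over batches of tables (bootstrap replicates
x inner iterations share one batched linear solve), which keeps the
1000-replicate bootstrap tractable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from tickmicro.tables_io import CooccurrenceNetwork, CountTable

__all__ = [
    "SparccResult",
    "sparcc",
    "sparcc_bootstrap",
    "build_network",
    "exclude_taxon_and_reinfer",
    "solve_basis_variances",
]

RESAMPLE_PRIOR = 1.0  # Dirichlet prior for fraction resampling
_OMEGA_FLOOR = 1e-10


@dataclass
class SparccResult:
    """Symmetric correlation matrix with bootstrap p-values.

    ``p``/``p_adj`` are None until :func:`sparcc_bootstrap` fills them.
    """

    r: pd.DataFrame
    p: pd.DataFrame | None = None
    p_adj: pd.DataFrame | None = None
    n_boot: int = 0
    n_sparcc_iter: int = 20
    seed: int = 0

    @property
    def taxa(self) -> list[str]:
        return list(self.r.index)

    def pair_frame(self) -> pd.DataFrame:
        """Upper-triangle pairs as rows (taxon_a, taxon_b, r, p, p_adj)."""
        taxa = self.taxa
        rows = []
        rm = self.r.to_numpy()
        pm = self.p.to_numpy() if self.p is not None else None
        qm = self.p_adj.to_numpy() if self.p_adj is not None else None
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                rows.append(
                    {
                        "taxon_a": taxa[i],
                        "taxon_b": taxa[j],
                        "r": rm[i, j],
                        "p": pm[i, j] if pm is not None else np.nan,
                        "p_adj": qm[i, j] if qm is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# core estimator (batched)
# ---------------------------------------------------------------------------

def _log_ratio_variances(fracs: np.ndarray) -> np.ndarray:
    """T matrices for a batch of fraction tables: (B, n, d) -> (B, d, d)."""
    n = fracs.shape[1]
    logf = np.log(fracs)
    centered = logf - logf.mean(axis=1, keepdims=True)
    cov = np.einsum("bni,bnj->bij", centered, centered) / (n - 1)
    var = np.einsum("bii->bi", cov)
    t_mat = var[:, :, None] + var[:, None, :] - 2.0 * cov
    return t_mat


def _solve_omega(m_mat: np.ndarray, t_vec: np.ndarray) -> np.ndarray:
    """Batched solve of M w = t with pseudo-inverse fallback for singular M."""
    try:
        omega = np.linalg.solve(m_mat, t_vec[..., None])[..., 0]
    except np.linalg.LinAlgError:
        omega = (np.linalg.pinv(m_mat) @ t_vec[..., None])[..., 0]
    return np.clip(omega, _OMEGA_FLOOR, None)


def _correlations_from_t(
    t_mat: np.ndarray,
    exclusion_rounds: int,
    exclusion_threshold: float,
) -> np.ndarray:
    """Basis-variance solve with iterative pair exclusion; (B, d, d) -> rho."""
    b, d, _ = t_mat.shape
    if d < 3:
        raise ValueError("SparCC needs >= 3 taxa (basis system underdetermined)")
    m_mat = np.broadcast_to((d - 2) * np.eye(d) + np.ones((d, d)), (b, d, d)).copy()
    t_vec = t_mat.sum(axis=2)
    excluded = np.zeros((b, d, d), dtype=bool)
    # a taxon may lose at most d-3 pairs (never less than one), or its basis
    # equation degenerates and the clipped correlations saturate at +/-1
    excl_count = np.zeros((b, d), dtype=np.int64)
    max_excl = max(d - 3, 1)
    diag = np.arange(d)
    rho = None
    for rnd in range(exclusion_rounds + 1):
        omega = _solve_omega(m_mat, t_vec)
        if not np.all(np.isfinite(omega)):
            bad = int(np.argwhere(~np.isfinite(omega).all(axis=1))[0][0])
            n_exc = int(excluded[bad].sum() // 2)
            raise ValueError(
                f"basis-variance solve did not converge (replicate {bad}, "
                f"{n_exc} excluded pairs)"
            )
        denom = 2.0 * np.sqrt(omega[:, :, None] * omega[:, None, :])
        rho = (omega[:, :, None] + omega[:, None, :] - t_mat) / denom
        rho = np.clip(rho, -1.0, 1.0)
        rho[:, diag, diag] = 1.0
        if rnd == exclusion_rounds:
            break
        absr = np.abs(rho).copy()
        absr[:, diag, diag] = -np.inf
        absr[excluded] = -np.inf
        saturated = excl_count >= max_excl
        absr[saturated[:, :, None] | saturated[:, None, :]] = -np.inf
        flat = absr.reshape(b, -1)
        best = flat.argmax(axis=1)
        best_val = flat[np.arange(b), best]
        ii, jj = np.unravel_index(best, (d, d))
        active = best_val >= exclusion_threshold
        if not active.any():
            break
        sel = np.flatnonzero(active)
        i_s, j_s = ii[sel], jj[sel]
        m_mat[sel, i_s, i_s] -= 1.0
        m_mat[sel, j_s, j_s] -= 1.0
        m_mat[sel, i_s, j_s] -= 1.0
        m_mat[sel, j_s, i_s] -= 1.0
        tij = t_mat[sel, i_s, j_s]
        t_vec[sel, i_s] -= tij
        t_vec[sel, j_s] -= tij
        excluded[sel, i_s, j_s] = True
        excluded[sel, j_s, i_s] = True
        excl_count[sel, i_s] += 1
        excl_count[sel, j_s] += 1
    return rho


def solve_basis_variances(
    t_mat: np.ndarray,
    excluded_pairs: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Basis variances for a single T matrix and a fixed exclusion set.

    Exposed so the sparsity-approximated linear solve can be checked against
    independent (grid-search) solutions of the same system.
    """
    t_mat = np.asarray(t_mat, dtype=float)
    d = t_mat.shape[0]
    m_mat = (d - 2) * np.eye(d) + np.ones((d, d))
    t_vec = t_mat.sum(axis=1)
    for i, j in excluded_pairs or []:
        m_mat[i, i] -= 1.0
        m_mat[j, j] -= 1.0
        m_mat[i, j] -= 1.0
        m_mat[j, i] -= 1.0
        t_vec[i] -= t_mat[i, j]
        t_vec[j] -= t_mat[i, j]
    return _solve_omega(m_mat[None], t_vec[None])[0]


def _sparcc_r_batch(
    counts: np.ndarray,
    batch: int,
    n_iter: int,
    rng: np.random.Generator,
    exclusion_rounds: int,
    exclusion_threshold: float,
    permute_columns: bool = False,
) -> np.ndarray:
    """Median-over-iterations SparCC correlations for ``batch`` tables.

    With ``permute_columns`` each table is a permutation null: every taxon's
    counts are shuffled across samples independently before resampling.
    """
    n, d = counts.shape
    tables = np.broadcast_to(counts, (batch, n, d))
    if permute_columns:
        tables = rng.permuted(tables, axis=1)
    gamma = rng.gamma(np.broadcast_to(tables + RESAMPLE_PRIOR, (n_iter, batch, n, d)))
    fracs = gamma / gamma.sum(axis=3, keepdims=True)
    t_mat = _log_ratio_variances(fracs.reshape(n_iter * batch, n, d))
    rho = _correlations_from_t(t_mat, exclusion_rounds, exclusion_threshold)
    rho = rho.reshape(n_iter, batch, d, d)
    return np.median(rho, axis=0)


def _validate_table(table: CountTable) -> np.ndarray:
    counts = table.matrix()
    if counts.shape[0] < 4:
        raise ValueError("SparCC needs >= 4 samples")
    if counts.shape[1] < 3:
        raise ValueError("SparCC needs >= 3 taxa")
    zero = counts.sum(axis=0) == 0
    if zero.any():
        bad = [t for t, z in zip(table.taxon_ids, zero) if z]
        raise ValueError(f"all-zero taxa must be filtered before SparCC: {bad}")
    return counts


def sparcc(
    table: CountTable,
    n_iter: int = 20,
    exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> SparccResult:
    """SparCC correlation matrix (no p-values; see :func:`sparcc_bootstrap`)."""
    counts = _validate_table(table)
    rng = np.random.default_rng(seed)
    r = _sparcc_r_batch(counts, 1, n_iter, rng, exclusion_rounds, exclusion_threshold)[0]
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    frame = pd.DataFrame(r, index=table.taxon_ids, columns=table.taxon_ids)
    return SparccResult(frame, n_sparcc_iter=n_iter, seed=seed)


def sparcc_bootstrap(
    table: CountTable,
    n_boot: int = 1000,
    seed: int = 0,
    n_iter: int = 20,
    exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.1,
    chunk: int = 25,
) -> SparccResult:
    """SparCC with permutation-bootstrap p-values and BH adjustment."""
    if n_boot < 99:
        raise ValueError("n_boot must be >= 99")
    counts = _validate_table(table)
    rng = np.random.default_rng(seed)
    r_obs = _sparcc_r_batch(counts, 1, n_iter, rng, exclusion_rounds, exclusion_threshold)[0]
    r_obs = (r_obs + r_obs.T) / 2.0
    np.fill_diagonal(r_obs, 1.0)
    d = counts.shape[1]
    exceed = np.zeros((d, d), dtype=np.int64)
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        r_null = _sparcc_r_batch(
            counts, b, n_iter, rng, exclusion_rounds, exclusion_threshold,
            permute_columns=True,
        )
        exceed += (np.abs(r_null) >= np.abs(r_obs)[None]).sum(axis=0)
        done += b
    p = (1.0 + exceed) / (1.0 + n_boot)
    np.fill_diagonal(p, 1.0)
    iu = np.triu_indices(d, 1)
    p_adj = np.ones((d, d))
    if len(iu[0]):
        adj = multipletests(p[iu], method="fdr_bh")[1]
        p_adj[iu] = adj
        p_adj[(iu[1], iu[0])] = adj
    taxa = table.taxon_ids
    return SparccResult(
        r=pd.DataFrame(r_obs, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        p_adj=pd.DataFrame(p_adj, index=taxa, columns=taxa),
        n_boot=n_boot,
        n_sparcc_iter=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(
    res: SparccResult,
    threshold_r: float = 0.75,
    alpha: float = 0.05,
    taxa: list[str] | None = None,
    include_isolated: bool = False,
    name: str = "",
) -> CooccurrenceNetwork:
    """Threshold a SparCC result into a co-occurrence network.

    An edge requires both |r| >= ``threshold_r`` and adjusted p < ``alpha``.
    By default only taxa incident to at least one edge become nodes; with
    ``include_isolated`` every taxon in ``taxa`` (default: all taxa of the
    result) is a node regardless of degree.
    """
    if res.p_adj is None:
        raise ValueError("SparccResult has no p_adj; run sparcc_bootstrap first")
    universe = list(taxa) if taxa is not None else res.taxa
    rm = res.r.to_numpy()
    qm = res.p_adj.to_numpy()
    idx = {t: i for i, t in enumerate(res.taxa)}
    g = nx.Graph()
    if include_isolated:
        g.add_nodes_from(universe)
    uni = [t for t in universe if t in idx]
    for a_pos in range(len(uni)):
        for b_pos in range(a_pos + 1, len(uni)):
            i, j = idx[uni[a_pos]], idx[uni[b_pos]]
            r = rm[i, j]
            if abs(r) >= threshold_r and qm[i, j] < alpha:
                g.add_edge(
                    uni[a_pos],
                    uni[b_pos],
                    weight=float(r),
                    sign="+" if r > 0 else "-",
                    p_adj=float(qm[i, j]),
                )
    return CooccurrenceNetwork(g, threshold_r=threshold_r, alpha=alpha, name=name)


def exclude_taxon_and_reinfer(
    table: CountTable,
    taxon_id: str,
    n_boot: int = 1000,
    seed: int = 0,
    threshold_r: float = 0.75,
    alpha: float = 0.05,
    include_isolated: bool = False,
    name: str = "",
    **sparcc_kwargs,
) -> tuple[SparccResult, CooccurrenceNetwork]:
    """Drop a taxon's column and re-run the full inference pipeline.

    Re-inference (rather than deleting the node from the existing network)
    is deliberate: removing a dominant taxon changes every log-ratio, so the
    re-inferred network can gain nodes and edges elsewhere. Raises KeyError
    if the taxon is not in the table (e.g. a taxon absent from a season).
    """
    reduced = table.drop_taxon(taxon_id)
    reduced = CountTable(
        reduced.counts.loc[:, reduced.counts.sum(axis=0) > 0], reduced.group
    )
    res = sparcc_bootstrap(reduced, n_boot=n_boot, seed=seed, **sparcc_kwargs)
    net = build_network(
        res,
        threshold_r=threshold_r,
        alpha=alpha,
        include_isolated=include_isolated,
        name=name,
    )
    return res, net
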