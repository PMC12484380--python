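import itertools

import numpy as np
import pandas as pd
import pytest

from tickmicro import cooccurrence, synthdata
from tickmicro.cooccurrence import (
    SparccResult,
    build_network,
    exclude_taxon_and_reinfer,
    solve_basis_variances,
    sparcc,
    sparcc_bootstrap,
)
from tickmicro.tables_io import CountTable


def _table(counts, groups=None, taxa=None):
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i}" for i in range(counts.shape[1])]
    samples = [f"s{i}" for i in range(counts.shape[0])]
    groups = groups or ["g"] * len(samples)
    return CountTable(
        pd.DataFrame(counts, index=samples, columns=taxa),
        pd.Series(groups, index=samples),
    )


def _lognormal_counts(rng, n, d, depth=50000, copies=None):
    log_ab = rng.normal(0, 1, (n, d))
    if copies:
        for src, dst in copies:
            log_ab[:, dst] = log_ab[:, src]
    props = np.exp(log_ab)
    props /= props.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, p) for p in props])


class TestSparccEstimator:
    def test_copied_pair_strongly_correlated(self):
        """Two identical taxa plus an independent one: r_AB near 1."""
        rng = np.random.default_rng(0)
        counts = _lognormal_counts(rng, 100, 3, copies=[(0, 1)])
        res = sparcc(_table(counts, taxa=["A", "B", "C"]), seed=1)
        assert res.r.loc["A", "B"] > 0.9
        assert abs(res.r.loc["A", "C"]) < 0.5

    def test_null_correlations_small(self):
        """Independent log-normal taxa: max |r| < 0.4 in >= 90% of seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts = _lognormal_counts(rng, 200, 5)
            res = sparcc(_table(counts), seed=seed)
            r = res.r.to_numpy()
            if np.abs(r[np.triu_indices(5, 1)]).max() < 0.4:
                hits += 1
        assert hits >= 9

    def test_sample_order_statistical_invariance(self):
        rng = np.random.default_rng(3)
        counts = _lognormal_counts(rng, 120, 6, copies=[(0, 1)])
        t1 = _table(counts)
        perm = np.random.default_rng(0).permutation(120)
        t2 = _table(counts[perm])
        r1 = sparcc(t1, seed=9).r.to_numpy()
        r2 = sparcc(t2, seed=9).r.to_numpy()
        assert np.abs(r1 - r2).max() < 0.15  # Monte-Carlo resampling noise only

    def test_agrees_with_clr_pearson_in_diffuse_regime(self):
        """Documented regime: SparCC tracks Pearson correlation of clr data."""
        table, _, _ = synthdata.generate_seasonal_counts(
            (20, 20, 20), n_taxa=20, n_modules=2, module_correlation=0.9,
            hub_degree=4, seed=2, absent_in_group={}, differential_taxa={},
            tree=False,
        )
        res = sparcc(table, seed=0)
        counts = table.matrix() + 0.5
        logp = np.log(counts / counts.sum(axis=1, keepdims=True))
        clr = logp - logp.mean(axis=1, keepdims=True)
        pear = np.corrcoef(clr.T)
        iu = np.triu_indices(20, 1)
        agreement = np.corrcoef(res.r.to_numpy()[iu], pear[iu])[0, 1]
        assert agreement > 0.9

    def test_input_validation(self):
        with pytest.raises(ValueError, match="all-zero"):
            sparcc(_table([[1, 0, 2]] * 4))
        with pytest.raises(ValueError, match="4 samples"):
            sparcc(_table([[1, 2, 3]] * 3))
        with pytest.raises(ValueError, match="3 taxa"):
            sparcc(_table([[1, 2]] * 5))

    def test_determinism(self):
        rng = np.random.default_rng(7)
        counts = _lognormal_counts(rng, 30, 6)
        t = _table(counts)
        a = sparcc_bootstrap(t, n_boot=99, seed=5)
        b = sparcc_bootstrap(t, n_boot=99, seed=5)
        assert np.array_equal(a.r.to_numpy(), b.r.to_numpy())
        assert np.array_equal(a.p.to_numpy(), b.p.to_numpy())


class TestBasisSolve:
    def _grid_solve(self, t_mat, excluded, bounds, rounds=6, points=13):
        """Independent oracle: shrinking-grid minimizer of ||M w - t||^2."""
        d = t_mat.shape[0]
        m_mat = (d - 2) * np.eye(d) + np.ones((d, d))
        t_vec = t_mat.sum(axis=1)
        for i, j in excluded:
            m_mat[i, i] -= 1
            m_mat[j, j] -= 1
            m_mat[i, j] -= 1
            m_mat[j, i] -= 1
            t_vec[i] -= t_mat[i, j]
            t_vec[j] -= t_mat[i, j]
        lo = np.full(d, bounds[0])
        hi = np.full(d, bounds[1])
        best = None
        for _ in range(rounds):
            axes = [np.linspace(lo[k], hi[k], points) for k in range(d)]
            best_val = np.inf
            for w in itertools.product(*axes):
                w = np.array(w)
                resid = m_mat @ w - t_vec
                val = resid @ resid
                if val < best_val:
                    best_val, best = val, w
            span = (hi - lo) / (points - 1)
            lo = np.maximum(best - 2 * span, 1e-6)
            hi = best + 2 * span
        return best

    def test_exactly_sparse_case_matches_grid_solve(self):
        """4 taxa, one correlated (excluded) pair: linear solve == grid solve."""
        omega = np.array([0.8, 1.3, 0.6, 1.1])
        rho01 = 0.6
        t_mat = omega[:, None] + omega[None, :]
        t_mat[0, 1] -= 2 * rho01 * np.sqrt(omega[0] * omega[1])
        t_mat[1, 0] = t_mat[0, 1]
        np.fill_diagonal(t_mat, 0.0)
        solved = solve_basis_variances(t_mat, excluded_pairs=[(0, 1)])
        gridded = self._grid_solve(t_mat, [(0, 1)], bounds=(0.05, 3.0))
        assert np.all(np.abs(solved - gridded) / gridded < 0.05)
        # and both recover the true basis variances (the system is exact here)
        assert np.all(np.abs(solved - omega) / omega < 0.05)


class TestBootstrap:
    def test_p_bounds_and_bh(self):
        rng = np.random.default_rng(1)
        counts = _lognormal_counts(rng, 40, 5)
        res = sparcc_bootstrap(_table(counts), n_boot=99, seed=0)
        iu = np.triu_indices(5, 1)
        p = res.p.to_numpy()[iu]
        q = res.p_adj.to_numpy()[iu]
        assert p.min() >= 1 / 100 and p.max() <= 1.0
        assert (q >= p - 1e-12).all()

    def test_proportional_pair_hits_p_floor(self):
        """A perfectly proportional pair reaches the minimum attainable p."""
        rng = np.random.default_rng(2)
        base = rng.lognormal(0, 1, 100)
        other = rng.lognormal(0, 1, (100, 8))
        props = np.column_stack([base, 2 * base, other])
        props /= props.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(100000, p) for p in props])
        res = sparcc_bootstrap(_table(counts), n_boot=199, seed=3)
        assert res.p.iloc[0, 1] == pytest.approx(1 / 200)


class TestBuildNetwork:
    def _result(self, r01, q01):
        taxa = ["A", "B", "C"]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r01
        q = np.ones((3, 3))
        q[0, 1] = q[1, 0] = q01
        return SparccResult(
            r=pd.DataFrame(r, index=taxa, columns=taxa),
            p=pd.DataFrame(q, index=taxa, columns=taxa),
            p_adj=pd.DataFrame(q, index=taxa, columns=taxa),
            n_boot=999,
        )

    @pytest.mark.parametrize(
        "r01,q01,n_edges",
        [
            (0.8, 0.2, 0),  # strong but not significant
            (0.74, 0.001, 0),  # significant but below threshold
            (-0.9, 0.01, 1),  # strong negative and significant
            (0.76, 0.049, 1),
        ],
    )
    def test_dual_criterion(self, r01, q01, n_edges):
        net = build_network(self._result(r01, q01))
        assert net.n_edges == n_edges
        if n_edges and r01 < 0:
            assert net.graph["A"]["B"]["sign"] == "-"

    def test_isolated_node_switch(self):
        res = self._result(0.9, 0.001)
        assert build_network(res).n_nodes == 2
        assert build_network(res, include_isolated=True).n_nodes == 3

    def test_requires_p_adj(self):
        res = self._result(0.9, 0.001)
        res.p_adj = None
        with pytest.raises(ValueError, match="p_adj"):
            build_network(res)


class TestExclusion:
    def _module_table(self, seed=0, n=100):
        """5 strongly proportional taxa (a planted module) + 6 independent."""
        rng = np.random.default_rng(seed)
        hub = rng.lognormal(0, 1, n)
        noise = rng.lognormal(0, 0.05, (n, 5))
        module = hub[:, None] * noise  # near-proportional block
        free = rng.lognormal(0, 1, (n, 6))
        props = np.column_stack([module, free])
        props /= props.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(50000, p) for p in props])
        return _table(counts, taxa=[f"m{i}" for i in range(5)] + [f"f{i}" for i in range(6)])

    def test_absent_taxon_errors(self):
        t = self._module_table()
        with pytest.raises(KeyError, match="Rickettsia"):
            exclude_taxon_and_reinfer(t, "Rickettsia", n_boot=99)

    def test_excluding_uncorrelated_taxon_preserves_edges(self):
        t = self._module_table(seed=1)
        base = build_network(sparcc_bootstrap(t, n_boot=999, seed=4))
        _, net = exclude_taxon_and_reinfer(t, "f0", n_boot=999, seed=4)
        e1 = {frozenset(e[:2]) for e in base.edge_tuples()}
        e2 = {frozenset(e[:2]) for e in net.edge_tuples()}
        jacc = len(e1 & e2) / len(e1 | e2)
        assert jacc >= 0.9

    def test_excluding_module_member_reduces_module_edges(self):
        t = self._module_table(seed=2)
        base = build_network(sparcc_bootstrap(t, n_boot=999, seed=5))
        module = {f"m{i}" for i in range(5)}
        n_before = sum(1 for e in base.edge_tuples() if {e[0], e[1]} <= module)
        _, net = exclude_taxon_and_reinfer(t, "m0", n_boot=999, seed=5)
        n_after = sum(1 for e in net.edge_tuples() if {e[0], e[1]} <= module)
        assert n_before >= 3  # the planted module was recovered
        assert n_after < n_before
        assert "m0" not in net.graph
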