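"""NBS machinery: edge contrasts, components, degrees, network sums."""

import numpy as np
import pytest

import wmconn as w
from wmconn.network import (
    NetworkComponent,
    connected_components,
    edge_contrast,
    group_permutation_test,
    nbs,
    network_sum,
    node_degree,
)


def conn_from_windows(base_mat, ret_mat, normalized=True):
    """Two-sample connectivity: sample 0 in baseline, sample 1 in retention."""
    values = np.stack([base_mat, ret_mat]).astype(float)
    return w.ConnectivityTimeseries(
        values=values, time=np.array([-0.25, 0.5]), normalized=normalized
    )


def sym(n, entries):
    m = np.zeros((n, n))
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return m


class TestUnionFindOracle:
    @staticmethod
    def components_by_union_find(adj):
        """Brute-force union-find reference for connected components."""
        n = adj.shape[0]
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j]:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            for j in range(i + 1, n):
                if adj[i, j]:
                    comps.setdefault(find(i), set()).add((i, j))
        return sorted(
            (sorted(edges) for edges in comps.values()),
            key=lambda e: (-len(e), e),
        )

    def test_exact_agreement_on_1000_random_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = 20
            p = rng.uniform(0.02, 0.25)
            upper = rng.random((n, n)) < p
            adj = np.triu(upper, k=1)
            adj = adj | adj.T
            ours = [c.edges for c in connected_components(adj)]
            ref = self.components_by_union_find(adj)
            assert ours == ref


class TestConnectedComponents:
    def test_two_components(self):
        adj = sym(8, {(1, 2): 1, (2, 3): 1, (5, 6): 1})
        comps = connected_components(adj)
        assert [c.n_edges for c in comps] == [2, 1]
        assert comps[0].nodes == [1, 2, 3]
        assert comps[1].edges == [(5, 6)]

    def test_empty_adjacency(self):
        assert connected_components(np.zeros((5, 5))) == []

    def test_complete_graph(self):
        adj = 1 - np.eye(4)
        comps = connected_components(adj)
        assert len(comps) == 1
        assert comps[0].n_edges == 6
        assert all(d == 3 for d in comps[0].node_degree.values())

    def test_asymmetric_rejected(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            connected_components(adj)

    def test_degree_bookkeeping(self):
        rng = np.random.default_rng(5)
        adj = np.triu(rng.random((15, 15)) < 0.2, k=1)
        adj = adj | adj.T
        for comp in connected_components(adj):
            assert sum(comp.node_degree.values()) == 2 * comp.n_edges
            assert comp.n_nodes == len(comp.nodes)
            assert all(d >= 1 for d in comp.node_degree.values())


class TestNodeDegree:
    def test_ranking_with_ties(self):
        comp = NetworkComponent(edges=[(0, 1), (1, 2)])
        assert node_degree(comp) == [(1, 2), (0, 1), (2, 1)]

    def test_single_edge(self):
        comp = NetworkComponent(edges=[(3, 7)])
        assert node_degree(comp) == [(3, 1), (7, 1)]

    def test_star_hub(self):
        comp = NetworkComponent(edges=[(0, k) for k in range(1, 5)])
        assert node_degree(comp)[0] == (0, 4)


class TestEdgeContrast:
    def test_identical_windows_give_zero(self):
        conns = [
            conn_from_windows(sym(3, {(0, 1): v}), sym(3, {(0, 1): v}))
            for v in (1.0, 2.0, 3.0)
        ]
        ec = edge_contrast(conns)
        assert np.all(ec.t_matrix == 0)

    def test_hand_computed_t(self):
        # per-subject retention-baseline differences {1, 2, 3} on edge (0, 1)
        conns = [
            conn_from_windows(sym(3, {(0, 1): 0.0, (0, 2): s * 0.1}),
                              sym(3, {(0, 1): d, (0, 2): 0.0}))
            for s, d in enumerate([1.0, 2.0, 3.0])
        ]
        ec = edge_contrast(conns)
        assert ec.t_matrix[0, 1] == pytest.approx(3.4641, abs=1e-4)
        assert ec.t_matrix[1, 0] == pytest.approx(3.4641, abs=1e-4)

    def test_needs_three_subjects(self):
        conns = [conn_from_windows(sym(3, {}), sym(3, {}))] * 2
        with pytest.raises(ValueError, match="at least 3"):
            edge_contrast(conns)


class TestNBS:
    def _planted_conns(self, n_subj=12, n=10, effect_edges=((0, 1), (1, 2)), seed=0):
        rng = np.random.default_rng(seed)
        conns = []
        for _ in range(n_subj):
            base = np.zeros((n, n))
            ret = rng.standard_normal((n, n)) * 0.1
            ret = (ret + ret.T) / 2
            np.fill_diagonal(ret, 0)
            for i, j in effect_edges:
                ret[i, j] = ret[j, i] = 1.0 + 0.1 * rng.standard_normal()
            conns.append(conn_from_windows(base, ret))
        return conns

    def test_planted_component_significant(self):
        path5 = tuple((i, i + 1) for i in range(5))
        res = nbs(self._planted_conns(effect_edges=path5), n_perm=500, seed=3)
        sig = res.significant_components
        assert len(sig) == 1
        assert set(sig[0].edges) >= set(path5)

    def test_single_noise_edge_not_significant(self):
        res = nbs(self._planted_conns(effect_edges=()), n_perm=500, seed=4)
        for comp in res.components:
            if comp.n_edges == 1:
                assert comp.p_corrected > 0.5

    def test_region_relabeling_permutes_components(self):
        conns = self._planted_conns()
        res = nbs(conns, n_perm=300, seed=5)
        n = conns[0].n_regions
        perm = np.random.default_rng(11).permutation(n)
        conns_p = [
            w.ConnectivityTimeseries(
                values=c.values[:, perm][:, :, perm], time=c.time, normalized=True
            )
            for c in conns
        ]
        res_p = nbs(conns_p, n_perm=300, seed=5)
        remap = np.empty(n, dtype=int)
        remap[perm] = np.arange(n)  # original label -> permuted label
        mapped = sorted(
            sorted(tuple(sorted((remap[i], remap[j]))) for i, j in c.edges)
            for c in res.components
        )
        got = sorted(sorted(map(tuple, c.edges)) for c in res_p.components)
        assert mapped == got
        assert sorted(c.p_corrected for c in res.components) == sorted(
            c.p_corrected for c in res_p.components
        )

    def test_p_monotone_in_component_size(self):
        res = nbs(self._planted_conns(effect_edges=((0, 1), (1, 2), (4, 5))),
                  n_perm=400, seed=6)
        comps = sorted(res.components, key=lambda c: -c.n_edges)
        for big, small in zip(comps, comps[1:]):
            assert big.p_corrected <= small.p_corrected

    def test_determinism(self):
        conns = self._planted_conns()
        r1 = nbs(conns, n_perm=300, seed=8)
        r2 = nbs(conns, n_perm=300, seed=8)
        np.testing.assert_array_equal(r1.null_max_size, r2.null_max_size)

    def test_low_nperm_warning(self):
        res = nbs(self._planted_conns(), n_perm=200, alpha=0.001, seed=1)
        assert any("alpha" in msg for msg in res.warnings)


class TestNetworkSum:
    def test_two_edge_mask(self):
        conn = conn_from_windows(
            sym(4, {}), sym(4, {(0, 1): 1.5, (2, 3): -0.5, (0, 3): 9.0})
        )
        assert network_sum(conn, [(0, 1), (2, 3)]) == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        conn = conn_from_windows(sym(3, {}), sym(3, {}))
        with pytest.raises(ValueError, match="no edges"):
            network_sum(conn, [])

    def test_full_mask_equals_scaled_whole_brain(self):
        rng = np.random.default_rng(2)
        ret = rng.random((5, 5))
        ret = (ret + ret.T) / 2
        np.fill_diagonal(ret, 0)
        conn = conn_from_windows(np.zeros((5, 5)), ret)
        iu = np.triu_indices(5, 1)
        full = list(zip(*iu))
        wb = w.window_average(w.mean_whole_brain(conn), (250.0, 1250.0))
        assert network_sum(conn, full) == pytest.approx(len(full) * wb)

    def test_invalid_edge_rejected(self):
        conn = conn_from_windows(sym(3, {}), sym(3, {}))
        with pytest.raises(ValueError, match="invalid"):
            network_sum(conn, [(0, 5)])


class TestGroupPermutation:
    def test_identical_groups_p_near_one(self):
        vals = np.arange(8.0)
        res = group_permutation_test(vals, vals.copy(), n_perm=500, seed=0)
        assert res.p > 0.9

    def test_fully_separated_groups_smallest_p(self):
        res = group_permutation_test(
            np.full(8, 10.0), np.zeros(8), n_perm=2000, seed=1
        )
        # only the 2 / C(16, 8) exact-partition relabelings tie the observed
        # difference, so p is at or near the attainable floor 1 / (n_perm + 1)
        assert res.p < 0.01
        assert res.p >= 1.0 / 2001.0
        assert res.observed_difference == pytest.approx(10.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.3
        r1 = group_permutation_test(a, b, n_perm=400, seed=5)
        r2 = group_permutation_test(a, b, n_perm=400, seed=5)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)

    def test_group_size_check(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_permutation_test([1.0], [2.0, 3.0])
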