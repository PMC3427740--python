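"""Surrogate ensembles, empirical edge significance, node-strength tests."""

import numpy as np
import pytest

from dynfc.inference import (
    SurrogateEnsemble,
    compare_node_strength,
    edge_significance,
    make_surrogates,
    min_attainable_p,
)
from dynfc.keygraph import key_graph, upper_triangle_index, vectorize


def random_sequence(rng, m, n):
    out = []
    for _ in range(m):
        A = rng.uniform(size=(n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        out.append(A)
    return np.stack(out)


class TestMakeSurrogates:
    def test_identity_permutation_reproduces_original_key(self, rng):
        graphs = random_sequence(rng, 8, 6)
        ens = make_surrogates(
            graphs, n=1, seed=0, permutation_fn=lambda r, size: np.arange(size)
        )
        kg = key_graph(graphs)
        assert np.allclose(ens.surrogate_key_edges[0], kg.edge_vector(), atol=1e-10)

    @pytest.mark.parametrize("mode", ["per_slice", "fixed_permutation"])
    def test_weight_multiset_conserved_per_slice(self, rng, mode):
        graphs = random_sequence(rng, 6, 5)
        Z = np.stack([vectorize(g) for g in graphs])

        seen = []

        def recording_permutation(r, size):
            p = r.permutation(size)
            seen.append(p)
            return p

        make_surrogates(graphs, n=3, mode=mode, seed=1, permutation_fn=recording_permutation)
        # reconstruct each surrogate's slices from the recorded permutations
        # and check multisets directly against the originals
        if mode == "per_slice":
            assert len(seen) == 3 * len(graphs)
            for i, p in enumerate(seen):
                orig = Z[i % len(graphs)]
                assert np.allclose(np.sort(orig[p]), np.sort(orig))
        else:
            assert len(seen) == 3
            for p in seen:
                for row in Z:
                    assert np.allclose(np.sort(row[p]), np.sort(row))

    def test_fixed_permutation_preserves_temporal_profiles(self, rng):
        graphs = random_sequence(rng, 7, 5)
        Z = np.stack([vectorize(g) for g in graphs])
        captured = {}

        def capture(r, size):
            captured["p"] = r.permutation(size)
            return captured["p"]

        ens = make_surrogates(graphs, n=1, mode="fixed_permutation", seed=3, permutation_fn=capture)
        # surrogate key equals original key with edge positions permuted
        kg = key_graph(graphs)
        assert np.allclose(
            ens.surrogate_key_edges[0], kg.edge_vector()[captured["p"]], atol=1e-8
        )

    def test_constant_weight_graphs_invariant(self):
        G = np.full((4, 4), 0.3)
        np.fill_diagonal(G, 0.0)
        graphs = np.stack([G] * 5)
        ens = make_surrogates(graphs, n=4, seed=0)
        kg = key_graph(graphs)
        for s in range(4):
            assert np.allclose(ens.surrogate_key_edges[s], kg.edge_vector(), atol=1e-10)

    def test_deterministic_and_order_independent_substreams(self, rng):
        graphs = random_sequence(rng, 6, 5)
        a = make_surrogates(graphs, n=5, seed=9)
        b = make_surrogates(graphs, n=5, seed=9)
        c = make_surrogates(graphs, n=3, seed=9)
        assert np.array_equal(a.surrogate_key_edges, b.surrogate_key_edges)
        # surrogate s depends only on (seed, s), not on the ensemble size
        assert np.array_equal(a.surrogate_key_edges[:3], c.surrogate_key_edges)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            make_surrogates(random_sequence(rng, 3, 4), n=1, mode="bogus")


class TestEdgeSignificance:
    def ensemble(self, null, n_nodes):
        return SurrogateEnsemble(
            surrogate_key_edges=null, mode="per_slice", seed=0, n_nodes=n_nodes
        )

    def test_extreme_rank_pooled_p(self):
        S, d = 100, 6
        null = np.zeros((S, d))
        obs = np.ones(d)
        mask = edge_significance(obs, self.ensemble(null, 4), pooled=True)
        assert np.allclose(mask.p_values, 1.0 / (1 + S * d))

    def test_median_observation_has_half_p(self, rng):
        null = rng.normal(size=(1999, 1))
        obs = np.array([np.median(null)])
        mask = edge_significance(obs, self.ensemble(null, 2), pooled=False)
        assert mask.p_values[0] == pytest.approx(0.5, abs=0.01)

    def test_p_values_never_zero_and_masks_nested(self, rng):
        null = rng.normal(size=(200, 10))
        obs = rng.normal(size=10) + 3
        for pooled in (True, False):
            mask = edge_significance(obs, self.ensemble(null, 5), pooled=pooled)
            assert np.all(mask.p_values > 0)
            assert np.all(mask.p_values <= 1)
            assert not np.any(mask.mask_001 & ~mask.mask_01)

    def test_min_attainable_p_documented(self):
        assert min_attainable_p(2000, 1891, pooled=True) == pytest.approx(
            1 / (1 + 2000 * 1891)
        )
        assert min_attainable_p(2000, 1891, pooled=False) == pytest.approx(1 / 2001)

    def test_per_edge_null_warns_when_level_unresolvable(self, rng):
        null = rng.normal(size=(50, 4))
        with pytest.warns(UserWarning, match="pool"):
            edge_significance(np.zeros(4), self.ensemble(null, 3), pooled=False)

    def test_mask_adjacency_symmetric(self, rng):
        null = rng.normal(size=(300, 6))
        obs = rng.normal(size=6) + 2
        mask = edge_significance(obs, self.ensemble(null, 4), pooled=True)
        A = mask.mask_adjacency(4, "01")
        assert np.array_equal(A, A.T)
        r, c = upper_triangle_index(4)
        assert np.array_equal(A[r, c], mask.mask_01)


class TestCompareNodeStrength:
    def graph_with_row(self, row, n):
        A = np.zeros((n, n))
        A[0, 1:] = row
        A[1:, 0] = row
        return A

    def test_identical_rows_not_rejected(self):
        row = np.linspace(0.1, 0.9, 9)
        res = compare_node_strength(
            self.graph_with_row(row, 10), self.graph_with_row(row, 10), node=0
        )
        assert res.t_statistic == pytest.approx(0.0)
        assert not res.reject_at_05

    def test_separated_means_rejected(self, rng):
        row_a = 0.9 + rng.normal(0, 0.01, size=61)
        row_b = 0.1 + rng.normal(0, 0.01, size=61)
        res = compare_node_strength(
            self.graph_with_row(row_a, 62), self.graph_with_row(row_b, 62), node=0
        )
        assert res.reject_at_05
        assert res.t_statistic > 0

    def test_matches_textbook_welch_formula(self, rng):
        xa = rng.uniform(size=7)
        xb = rng.uniform(size=7) + 0.2
        res = compare_node_strength(
            self.graph_with_row(xa, 8), self.graph_with_row(xb, 8), node=0
        )
        va, vb = xa.var(ddof=1) / 7, xb.var(ddof=1) / 7
        t = (xa.mean() - xb.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 6 + vb**2 / 6)
        from scipy import stats

        p = 2 * stats.t.sf(abs(t), df)
        assert res.t_statistic == pytest.approx(t, rel=1e-10)
        assert res.df == pytest.approx(df, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_small_graph_rejected(self):
        with pytest.raises(ValueError):
            compare_node_strength(np.zeros((2, 2)), np.zeros((2, 2)), node=0)
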