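"""Spearman edge correlations, NR/ND weights, and the ND permutation filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ngprio as ng
from ngprio.edge_weights import _standardized_ranks


def rank_then_pearson(x, y):
    """Brute-force oracle: mid-rank both vectors, then longhand Pearson."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def two_group_matrix(pairs_a, pairs_b, gene_names=("g1", "g2")):
    """Matrix for one gene pair with given per-group value vectors."""
    values = np.array(
        [np.concatenate([pairs_a[0], pairs_b[0]]),
         np.concatenate([pairs_a[1], pairs_b[1]])]
    )
    n_a, n_b = len(pairs_a[0]), len(pairs_b[0])
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    df = pd.DataFrame(values, index=list(gene_names), columns=cols)
    matrix = ng.ExpressionMatrix(df)
    groups = ng.SampleGroups.from_assignment(
        {c: ("A" if c.startswith("a") else "B") for c in cols}
    )
    return matrix, groups


class TestSpearman:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ng.spearman(x, np.exp(x)) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ng.spearman(x, -x) == pytest.approx(-1.0)

    def test_classic_four_point_example(self):
        r = ng.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_maps_to_zero(self):
        assert ng.spearman([1, 1, 1, 1], [1, 2, 3, 4]) == 0.0

    def test_matches_bruteforce_including_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            x = rng.integers(0, 5, n).astype(float)  # heavy ties
            y = rng.standard_normal(n)
            if np.ptp(x) == 0:
                continue
            assert ng.spearman(x, y) == pytest.approx(
                rank_then_pearson(x, y), abs=1e-12
            )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        r = ng.spearman(x, y)
        assert ng.spearman(np.exp(x), y) == pytest.approx(r, abs=1e-12)
        assert ng.spearman(x, 3 * y + 7) == pytest.approx(r, abs=1e-12)

    def test_vectorized_engine_agrees_with_scalar(self, planted_nr_instance):
        inst = planted_nr_instance
        w = ng.nr_edge_weights(inst.network, inst.matrix, inst.groups)
        sub = w.edges.sample(20, random_state=0)
        a_cols = list(inst.groups.samples_a)
        for _, row in sub.iterrows():
            x = inst.matrix.data.loc[row["gene_a"], a_cols]
            y = inst.matrix.data.loc[row["gene_b"], a_cols]
            assert row["r1"] == pytest.approx(ng.spearman(x, y), abs=1e-10)

    def test_ordinal_fast_path_equals_midranks_when_tie_free(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((5, 12))
        assert np.allclose(
            _standardized_ranks(a, tie_free=True), _standardized_ranks(a), atol=1e-12
        )


class TestEdgeWeights:
    def test_nr_weight_is_absolute_rewiring(self):
        x = np.arange(10.0)
        matrix, groups = two_group_matrix((x, x), (x, -x))  # r1=1, r2=-1
        net = ng.Network.from_edges([("g1", "g2")])
        w = ng.nr_edge_weights(net, matrix, groups)
        assert w.edges["weight"].iloc[0] == pytest.approx(2.0)
        wnd = ng.nd_edge_weights(net, matrix, groups)
        assert wnd.edges["weight"].iloc[0] == pytest.approx(0.0)  # cancellation

    def test_no_rewiring_gives_zero_nr_weight(self):
        x = np.arange(10.0)
        matrix, groups = two_group_matrix((x, x), (x, x))  # r1 = r2 = 1
        net = ng.Network.from_edges([("g1", "g2")])
        w = ng.nr_edge_weights(net, matrix, groups)
        assert w.edges["weight"].iloc[0] == pytest.approx(0.0)
        wnd = ng.nd_edge_weights(net, matrix, groups)
        assert wnd.edges["weight"].iloc[0] == pytest.approx(1.0)

    def test_group_swap_leaves_weights_unchanged(self, planted_nr_instance):
        inst = planted_nr_instance
        swapped = ng.SampleGroups.from_assignment(
            {s: ("z" if g == "groupA" else "a") for s, g in inst.groups.assignment.items()}
        )
        for fn in (ng.nr_edge_weights, ng.nd_edge_weights):
            w1 = fn(inst.network, inst.matrix, inst.groups)
            w2 = fn(inst.network, inst.matrix, swapped)
            assert np.allclose(w1.edges["weight"], w2.edges["weight"], atol=1e-12)

    def test_edges_missing_expression_are_dropped(self, planted_nr_instance):
        inst = planted_nr_instance
        extra = ng.Network.from_edges(
            list(inst.network.edges) + [("NOT_MEASURED", inst.network.nodes[0])]
        )
        w = ng.nr_edge_weights(extra, inst.matrix, inst.groups)
        assert w.n_dropped_missing == 1
        assert w.n_edges == inst.network.n_edges

    def test_planted_nr_module_edges_outweigh_background(self, planted_nr_instance):
        inst = planted_nr_instance
        w = ng.nr_edge_weights(inst.network, inst.matrix, inst.groups)
        hub = inst.truth.planted_hub
        is_module = (w.edges["gene_a"] == hub) | (w.edges["gene_b"] == hub)
        assert w.edges.loc[is_module, "weight"].mean() > 2 * w.edges.loc[
            ~is_module, "weight"
        ].mean()

    def test_planted_nd_module_edges_outweigh_background(self, planted_nd_instance):
        inst = planted_nd_instance
        w = ng.nd_edge_weights(inst.network, inst.matrix, inst.groups)
        hub = inst.truth.planted_hub
        is_module = (w.edges["gene_a"] == hub) | (w.edges["gene_b"] == hub)
        assert w.edges.loc[is_module, "weight"].mean() > 2 * w.edges.loc[
            ~is_module, "weight"
        ].mean()


class TestNDFilter:
    def test_zero_rewiring_edge_retained(self):
        rng = np.random.default_rng(12)
        x_a, x_b = rng.standard_normal(10), rng.standard_normal(10)
        # y == x in both groups: r1 = r2 = 1, observed delta r = 0
        matrix, groups = two_group_matrix((x_a, x_a), (x_b, x_b))
        net = ng.Network.from_edges([("g1", "g2")])
        w = ng.nd_edge_weights(net, matrix, groups)
        filtered = ng.nd_permutation_filter(w, matrix, groups, n_perm=100, seed=0)
        assert filtered.n_edges == 1 and filtered.n_filtered == 0

    def test_strongly_rewired_edge_removed(self):
        rng = np.random.default_rng(13)
        x_a = rng.standard_normal(20)
        x_b = rng.standard_normal(20)
        noise = 0.2 * rng.standard_normal(20)
        # r1 ~ +0.95 in group A, r2 ~ -0.95 in group B
        matrix, groups = two_group_matrix(
            (x_a, x_a + noise), (x_b, -x_b + noise)
        )
        net = ng.Network.from_edges([("g1", "g2")])
        w = ng.nd_edge_weights(net, matrix, groups)
        with pytest.raises(ng.ValidationError, match="every edge"):
            ng.nd_permutation_filter(w, matrix, groups, n_perm=200, seed=0)

    def test_small_n_perm_rejected(self, planted_nd_instance):
        inst = planted_nd_instance
        w = ng.nd_edge_weights(inst.network, inst.matrix, inst.groups)
        with pytest.raises(ng.ValidationError, match="at least 100"):
            ng.nd_permutation_filter(w, inst.matrix, inst.groups, n_perm=50)

    def test_filter_requires_nd_model(self, planted_nd_instance):
        inst = planted_nd_instance
        w = ng.nr_edge_weights(inst.network, inst.matrix, inst.groups)
        with pytest.raises(ng.ValidationError, match="ND"):
            ng.nd_permutation_filter(w, inst.matrix, inst.groups)

    def test_same_seed_reproduces_filter(self, planted_nd_instance):
        inst = planted_nd_instance
        w = ng.nd_edge_weights(inst.network, inst.matrix, inst.groups)
        f1 = ng.nd_permutation_filter(w, inst.matrix, inst.groups, n_perm=200, seed=5)
        f2 = ng.nd_permutation_filter(w, inst.matrix, inst.groups, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(f1.edges, f2.edges)
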