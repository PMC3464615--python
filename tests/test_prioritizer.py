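"""Candidate selection, two-stage scoring, combination, aggregation, stability."""

import numpy as np
import pandas as pd
import pytest

import ngprio as ng


def weighted_star(hub_degree: int) -> ng.WeightedNetwork:
    edges = pd.DataFrame(
        {
            "gene_a": ["HUB"] * hub_degree,
            "gene_b": [f"N{i:02d}" for i in range(hub_degree)],
            "r1": 0.0,
            "r2": 0.5,
            "weight": np.linspace(1.0, 0.1, hub_degree),
        }
    )
    return ng.WeightedNetwork("NR", edges)


class TestSelectCandidates:
    def test_degree_16_hub_passes_threshold_15(self):
        assert ng.select_candidates(weighted_star(16), min_degree=15) == ("HUB",)

    def test_degree_15_hub_is_not_a_candidate(self):
        with pytest.raises(ng.ValidationError, match="more than 15"):
            ng.select_candidates(weighted_star(15), min_degree=15)

    def test_synthetic_hubs_recovered_exactly(self, planted_nr_instance):
        inst = planted_nr_instance
        w = ng.nr_edge_weights(inst.network, inst.matrix, inst.groups)
        hubs = ng.select_candidates(w, min_degree=15)
        truth_net, truth = ng.generate_network(
            n_genes=200, n_hubs=4, hub_degree=20, background_edges=100, seed=7
        )
        deg = w.degrees()
        expected = tuple(sorted(g for g in deg.index if deg[g] > 15))
        assert hubs == expected
        assert set(truth.hubs) <= set(hubs)


class TestStageScoring:
    def test_top_weighted_subnet_maximizes_es(self, planted_nr_instance):
        inst = planted_nr_instance
        w = ng.nr_edge_weights(inst.network, inst.matrix, inst.groups)
        hub = inst.truth.planted_hub
        z_hub, es_hub, trimmed = ng.score_edge_enrichment(hub, w, seed=0)
        assert es_hub > 0.5 and z_hub > 3
        # trimmed edges all touch the candidate
        assert (
            (trimmed["gene_a"] == hub) | (trimmed["gene_b"] == hub)
        ).all()

    def test_null_candidate_scores_small(self, planted_nr_instance):
        inst = planted_nr_instance
        w = ng.nr_edge_weights(inst.network, inst.matrix, inst.groups)
        decoys = [h for h in ng.select_candidates(w) if h != inst.truth.planted_hub]
        z, _, _ = ng.score_edge_enrichment(decoys[0], w, seed=1)
        assert abs(z) < 4

    def test_stage2_prefers_de_interactors(self, planted_nr_instance):
        inst = planted_nr_instance
        w = ng.nr_edge_weights(inst.network, inst.matrix, inst.groups)
        de = ng.de_table(inst.matrix, inst.groups)
        hub = inst.truth.planted_hub
        _, _, trimmed = ng.score_edge_enrichment(hub, w, seed=2)
        z_t, es_t, surviving = ng.score_de_enrichment(hub, trimmed, de, seed=2)
        assert z_t > 3
        assert set(surviving) <= set(inst.truth.module_genes)


class TestCombineScores:
    def test_hand_standardized_two_candidate_example(self):
        df = pd.DataFrame(
            {"gene": ["beta", "alpha"], "z_s": [2.0, 0.0], "z_trimmed": [0.0, 2.0]}
        )
        ranking = ng.combine_scores(df)
        t = ranking.table
        # each column standardizes to +-1; combined ties at 0; lexicographic break
        assert set(t["z_s_norm"]) == {1.0, -1.0}
        assert list(t["gene"]) == ["alpha", "beta"]
        assert np.allclose(t["z_combined"], 0.0)

    def test_normalized_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(30)
        df = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(25)],
                "z_s": rng.standard_normal(25) * 3 + 1,
                "z_trimmed": rng.standard_normal(25),
            }
        )
        t = ng.combine_scores(df).table
        for col in ("z_s_norm", "z_trimmed_norm"):
            assert abs(t[col].mean()) < 1e-9
            assert abs(t[col].std(ddof=0) - 1) < 1e-9

    def test_shifting_a_score_column_preserves_ranking(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "z_s": rng.standard_normal(10),
                "z_trimmed": rng.standard_normal(10),
            }
        )
        shifted = df.assign(z_s=df["z_s"] + 100.0)
        assert ng.combine_scores(df).genes == ng.combine_scores(shifted).genes

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame(
            {"gene": ["a", "b", "c"], "z_s": [1.0, 1.0, 1.0], "z_trimmed": [1, 2, 3.0]}
        )
        with pytest.raises(ng.ValidationError, match="zero variance"):
            ng.combine_scores(df)


class TestRunNGP:
    def test_planted_nr_hub_ranks_first(self, planted_nr_instance):
        inst = planted_nr_instance
        res = ng.run_ngp(
            inst.matrix, inst.groups, inst.network, model="nr",
            params=ng.NGPParams(seed=77, n_perm=500),
        )
        assert res.ranking.rank_of(inst.truth.planted_hub) == 1

    def test_planted_nd_hub_ranks_first(self, planted_nd_instance):
        inst = planted_nd_instance
        res = ng.run_ngp(
            inst.matrix, inst.groups, inst.network, model="nd",
            params=ng.NGPParams(seed=78, n_perm=500, nd_filter_perms=1000),
        )
        assert res.ranking.rank_of(inst.truth.planted_hub) == 1

    def test_identical_runs_are_byte_identical(self, tmp_path, planted_nr_instance):
        inst = planted_nr_instance
        params = ng.NGPParams(seed=79, n_perm=300)
        for tag in ("x", "y"):
            res = ng.run_ngp(inst.matrix, inst.groups, inst.network, "nr", params)
            res.write_outputs(tmp_path / tag)
        for suffix in (".ranking.tsv", ".subnets.tsv", ".manifest.json"):
            assert (tmp_path / f"x{suffix}").read_bytes() == (
                tmp_path / f"y{suffix}"
            ).read_bytes()

    def test_row_order_invariance(self, planted_nr_instance):
        inst = planted_nr_instance
        params = ng.NGPParams(seed=80, n_perm=300)
        res1 = ng.run_ngp(inst.matrix, inst.groups, inst.network, "nr", params)
        shuffled = ng.ExpressionMatrix(
            inst.matrix.data.sample(frac=1.0, random_state=1)
        )
        res2 = ng.run_ngp(shuffled, inst.groups, inst.network, "nr", params)
        pd.testing.assert_frame_equal(res1.ranking.table, res2.ranking.table)


class TestAggregation:
    @staticmethod
    def ranking_from_order(genes):
        df = pd.DataFrame(
            {"gene": list(genes), "score": np.arange(len(genes), 0, -1, dtype=float)}
        )
        return ng.GeneRanking.from_scores(df, "score")

    def test_unanimous_winner_stays_first(self):
        r1 = self.ranking_from_order(["w", "a", "b", "c"])
        r2 = self.ranking_from_order(["w", "c", "b", "a"])
        agg = ng.aggregate_rank_sum([r1, r2])
        assert agg.genes[0] == "w"

    def test_tie_on_rank_sum_breaks_lexicographically(self):
        r1 = self.ranking_from_order(["a", "z", "b", "m"])  # a=1, z=2
        r2 = self.ranking_from_order(["z", "b", "a", "m"])  # z=1, a=3
        agg = ng.aggregate_rank_sum([r1, r2])
        # a: 1+3 = 4; z: 2+1 = 3; b: 3+2 = 5; m: 4+4 = 8
        assert agg.genes == ("z", "a", "b", "m")

    def test_matches_bruteforce_sum_and_sort(self):
        rng = np.random.default_rng(32)
        genes = [f"g{i}" for i in range(30)]
        rankings = [
            self.ranking_from_order(rng.permutation(genes)) for _ in range(3)
        ]
        agg = ng.aggregate_rank_sum(rankings)
        sums = {
            g: sum(r.rank_of(g) for r in rankings) for g in genes
        }
        expected = sorted(genes, key=lambda g: (sums[g], g))
        assert list(agg.genes) == expected

    def test_disjoint_rankings_rejected(self):
        r1 = self.ranking_from_order(["a", "b"])
        r2 = self.ranking_from_order(["c", "d"])
        with pytest.raises(ng.ValidationError, match="every ranking"):
            ng.aggregate_rank_sum([r1, r2])


class TestStability:
    @staticmethod
    def random_ranking(genes, rng):
        order = rng.permutation(list(genes))
        df = pd.DataFrame(
            {"gene": order, "score": np.arange(len(order), 0, -1, dtype=float)}
        )
        return ng.GeneRanking.from_scores(df, "score")

    def test_identical_rankings_are_maximally_stable(self):
        rng = np.random.default_rng(33)
        genes = [f"g{i:03d}" for i in range(120)]
        r = self.random_ranking(genes, rng)
        for k in (10, 25, 50):
            p_ab, p_ba = ng.stability_analysis(r, r, k=k, n_perm=1000, seed=1)
            assert p_ab == pytest.approx(1 / 1001)
            assert p_ba == pytest.approx(1 / 1001)

    def test_reversed_ranking_is_not_stable(self):
        rng = np.random.default_rng(34)
        genes = [f"g{i:03d}" for i in range(120)]
        r = self.random_ranking(genes, rng)
        reversed_df = r.table.iloc[::-1].reset_index(drop=True).copy()
        reversed_df["score"] = np.arange(len(genes), 0, -1, dtype=float)
        r_rev = ng.GeneRanking.from_scores(
            reversed_df[["gene", "score"]], "score"
        )
        p_ab, p_ba = ng.stability_analysis(r, r_rev, k=10, n_perm=500, seed=2)
        assert p_ab > 0.5 and p_ba > 0.5

    def test_k_must_be_smaller_than_candidate_count(self):
        rng = np.random.default_rng(35)
        genes = [f"g{i}" for i in range(20)]
        r = self.random_ranking(genes, rng)
        with pytest.raises(ng.ValidationError, match="top size"):
            ng.stability_analysis(r, r, k=20)

    def test_different_gene_sets_rejected(self):
        rng = np.random.default_rng(36)
        r1 = self.random_ranking([f"g{i}" for i in range(20)], rng)
        r2 = self.random_ranking([f"h{i}" for i in range(20)], rng)
        with pytest.raises(ng.ValidationError, match="same genes"):
            ng.stability_analysis(r1, r2, k=5)
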