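"""Cross-dataset consensus: rank-sum aggregation and top-k stability.

Two independent expression datasets are simulated for the same planted
network, each is ranked with the NR pipeline, and the two rankings are
compared: the rank-sum aggregate should put the planted hub first, and the
stability test measures whether the top-k of one ranking sits high in the
other (both directional p < 0.005 declares the top lists stable).
"""

import ngprio as ng

network, net_truth = ng.generate_network(
    n_genes=500, n_hubs=21, hub_degree=20, background_edges=300, seed=41
)
hub = net_truth.hubs[0]

rankings = []
for data_seed in (42, 43):
    instance = ng.generate_planted_nr(
        network, hub, module_rho=0.8, de_shift=1.0, n_per_group=30,
        seed=data_seed,
    )
    result = ng.run_ngp(
        instance.matrix, instance.groups, instance.network,
        model="nr", params=ng.NGPParams(seed=data_seed),
    )
    rankings.append(result.ranking)
    print(f"dataset seed {data_seed}: planted hub ranked "
          f"#{result.ranking.rank_of(hub)}")

aggregate = ng.aggregate_rank_sum(rankings)
print(f"rank-sum aggregate: planted hub ranked #{aggregate.rank_of(hub)}")

p_ab, p_ba = ng.stability_analysis(rankings[0], rankings[1], k=10,
                                   n_perm=1000, seed=41)
print(f"top-10 stability: p_ab = {p_ab:.4f}, p_ba = {p_ba:.4f} "
      f"(stable if both < 0.005)")
print(
    "\nOnly the planted hub reproduces between the replicates; the other "
    "top-10 slots\nare noise-ranked decoys, so with 21 candidates the "
    "stability p stays moderate."
)
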