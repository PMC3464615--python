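"""The ND model: filter rewired edges, then rank by consistent co-expression.

Simulates a hub whose module is co-expressed in *both* groups (no rewiring)
with differentially expressed members, applies the ND permutation filter
(which removes edges whose correlation change beats the 90th percentile of a
label-permutation null), and runs the ND pipeline.
"""

import ngprio as ng

network, net_truth = ng.generate_network(
    n_genes=500, n_hubs=21, hub_degree=20, background_edges=300, seed=21
)
hub = net_truth.hubs[0]
instance = ng.generate_planted_nd(
    network, hub, module_rho=0.8, de_shift=1.0, n_per_group=30, seed=21
)

result = ng.run_ngp(
    instance.matrix, instance.groups, instance.network,
    model="nd", params=ng.NGPParams(seed=21),
)

w = result.weighted_network
removed = w.n_filtered
kept_pairs = set(zip(w.edges["gene_a"], w.edges["gene_b"]))
module_pairs = [tuple(sorted((hub, g))) for g in instance.truth.module_genes]
surviving = sum(p in kept_pairs for p in module_pairs)

print(f"permutation filter removed {removed} edges "
      f"({removed / (removed + w.n_edges):.1%} of the weighted network)")
print(f"planted module edges surviving the filter: "
      f"{surviving}/{len(module_pairs)}")
print(f"planted hub {hub} ranked #{result.ranking.rank_of(hub)} "
      f"of {len(result.ranking.table)} candidates\n")
print(result.ranking.table.head(3)[
    ["rank", "gene", "z_s", "z_trimmed", "z_combined"]
].to_string(index=False))
print(
    "\nNon-rewired module edges pass the filter (their correlation change "
    "is null-like)\nand their consistently high |mean correlation| drives "
    "the planted hub to rank 1."
)
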