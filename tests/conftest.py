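import numpy as np
import pandas as pd
import pytest

import ngprio as ng


@pytest.fixture
def small_matrix() -> ng.ExpressionMatrix:
    """4 genes x 8 samples, deterministic values."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.standard_normal((4, 8)),
        index=["GA", "GB", "GC", "GD"],
        columns=[f"S{i}" for i in range(1, 9)],
    )
    df.index.name = "gene"
    return ng.ExpressionMatrix(df)


@pytest.fixture
def small_groups(small_matrix) -> ng.SampleGroups:
    assignment = {s: ("normal" if i < 4 else "tumor")
                  for i, s in enumerate(small_matrix.samples)}
    return ng.SampleGroups.from_assignment(assignment)


@pytest.fixture
def star_network() -> ng.Network:
    """One hub of degree 16 plus a disconnected edge."""
    edges = [("HUB", f"N{i:02d}") for i in range(16)] + [("X1", "X2")]
    return ng.Network.from_edges(edges)


def make_ranked_list(scores, member_positions):
    """RankedList over items i00, i01, ... with given descending scores."""
    items = [f"i{k:02d}" for k in range(len(scores))]
    member = [items[p] for p in member_positions]
    return ng.RankedList.from_scores(items, scores, member)


@pytest.fixture
def planted_nr_instance() -> ng.SyntheticInstance:
    net, truth = ng.generate_network(
        n_genes=200, n_hubs=4, hub_degree=20, background_edges=100, seed=7
    )
    return ng.generate_planted_nr(net, truth.hubs[0], n_per_group=30, seed=7)


@pytest.fixture
def planted_nd_instance() -> ng.SyntheticInstance:
    net, truth = ng.generate_network(
        n_genes=200, n_hubs=4, hub_degree=20, background_edges=100, seed=8
    )
    return ng.generate_planted_nd(net, truth.hubs[0], n_per_group=30, seed=8)
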