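"""Seeded synthetic instances with planted hub modules and known truth.

The generators emulate the two statistical situations the pipeline is built
to detect, on a network of star-shaped hub modules plus random background
edges:

* NR (network rewiring): a hub and its module genes share a latent factor in
  *one* group only, so hub-module edges are co-expressed in that group and
  uncorrelated in the other; module genes (not the hub) are additionally
  shifted by ``de_shift`` standard deviations in group B.
* ND (networked differential expression): the latent factor acts in *both*
  groups (no rewiring), and module genes are shifted in group B.

Module gene g is built as sqrt(rho) * factor + sqrt(1 - rho) * noise with the
factor shared across the module, which gives pairwise correlations close to
``module_rho``. All other genes are iid standard normal. Shifts are applied
on the standardized scale (sigma = 1).

Every generator is a pure function of its parameters and seed, and each
instance carries a truth record sufficient to regenerate it bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, Network, SampleGroups, ValidationError

__all__ = [
    "Truth",
    "SyntheticInstance",
    "generate_network",
    "generate_null_dataset",
    "generate_planted_nr",
    "generate_planted_nd",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class Truth:
    """Ground-truth record of a synthetic instance."""

    kind: str  # "null" | "nr" | "nd"
    seed: int
    hubs: tuple[str, ...]  # all star hubs of the network
    planted_hub: str | None  # the hub carrying the planted module (if any)
    module_genes: tuple[str, ...]  # the planted hub's interactors
    module_rho: float
    de_shift: float
    n_per_group: int

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": str(self.seed),
            "hubs": ",".join(self.hubs),
            "planted_hub": self.planted_hub or "",
            "module_genes": ",".join(self.module_genes),
            "module_rho": repr(self.module_rho),
            "de_shift": repr(self.de_shift),
            "n_per_group": str(self.n_per_group),
        }


@dataclass(frozen=True)
class SyntheticInstance:
    matrix: ExpressionMatrix
    groups: SampleGroups
    network: Network
    truth: Truth


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(
    n_genes: int,
    n_hubs: int,
    hub_degree: int,
    background_edges: int,
    seed: int,
) -> tuple[Network, Truth]:
    """Random background graph plus ``n_hubs`` disjoint star modules.

    Hub and module nodes are sampled without replacement, so
    ``n_genes >= n_hubs * (1 + hub_degree)`` is required. Background edges are
    uniform random pairs over all genes, excluding self-loops and duplicates.
    """
    if n_hubs > 0 and hub_degree <= 15:
        raise ValidationError("hub_degree must exceed 15 so hubs are candidates")
    need = n_hubs * (1 + hub_degree)
    if need > n_genes:
        raise ValidationError(
            f"{n_hubs} stars of size {hub_degree} need {need} genes, have {n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    chosen = rng.choice(n_genes, size=need, replace=False)
    edges: list[tuple[str, str]] = []
    hubs: list[str] = []
    k = 0
    for _ in range(n_hubs):
        hub = genes[chosen[k]]
        k += 1
        hubs.append(hub)
        for _ in range(hub_degree):
            edges.append((hub, genes[chosen[k]]))
            k += 1
    existing = {tuple(sorted(e)) for e in edges}
    target = len(existing) + background_edges
    attempts = 0
    while len(existing) < target:
        attempts += 1
        if attempts > 100 * (background_edges + 1):
            raise ValidationError("cannot place the requested background edges")
        a, b = rng.choice(n_genes, size=2, replace=False)
        pair = tuple(sorted((genes[a], genes[b])))
        if pair not in existing:
            existing.add(pair)
            edges.append(pair)
    net = Network.from_edges(edges)
    truth = Truth(
        kind="network",
        seed=seed,
        hubs=tuple(sorted(hubs)),
        planted_hub=None,
        module_genes=(),
        module_rho=0.0,
        de_shift=0.0,
        n_per_group=0,
    )
    return net, truth


def _sample_frame(
    network: Network, n_per_group: int
) -> tuple[list[str], list[str], list[str]]:
    genes = list(network.nodes)
    samples_a = [f"A{i:03d}" for i in range(1, n_per_group + 1)]
    samples_b = [f"B{i:03d}" for i in range(1, n_per_group + 1)]
    return genes, samples_a, samples_b


def _assemble(
    network: Network,
    values: np.ndarray,
    genes: list[str],
    samples_a: list[str],
    samples_b: list[str],
    truth: Truth,
) -> SyntheticInstance:
    df = pd.DataFrame(values, index=genes, columns=samples_a + samples_b)
    df.index.name = "gene"
    matrix = ExpressionMatrix(df)
    assignment = {s: "groupA" for s in samples_a}
    assignment.update({s: "groupB" for s in samples_b})
    groups = SampleGroups.from_assignment(assignment)
    return SyntheticInstance(matrix, groups, network, truth)


def generate_null_dataset(
    network: Network, n_per_group: int = 30, seed: int = 0
) -> SyntheticInstance:
    """All genes iid standard normal: no group effect, no co-expression."""
    rng = np.random.default_rng(seed)
    genes, sa, sb = _sample_frame(network, n_per_group)
    values = rng.standard_normal((len(genes), 2 * n_per_group))
    truth = Truth("null", seed, (), None, (), 0.0, 0.0, n_per_group)
    return _assemble(network, values, genes, sa, sb, truth)


def _planted(
    network: Network,
    hub: str,
    module_rho: float,
    de_shift: float,
    n_per_group: int,
    seed: int,
    both_groups: bool,
) -> SyntheticInstance:
    if hub not in set(network.nodes):
        raise ValidationError(f"hub {hub!r} is not a network node")
    if not (0.0 < module_rho < 1.0):
        raise ValidationError("module_rho must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    genes, sa, sb = _sample_frame(network, n_per_group)
    pos = {g: i for i, g in enumerate(genes)}
    values = rng.standard_normal((len(genes), 2 * n_per_group))

    module = list(network.neighbors(hub))
    member_rows = [pos[hub]] + [pos[g] for g in module]
    a_cols = np.arange(n_per_group)
    b_cols = np.arange(n_per_group, 2 * n_per_group)

    def correlate(cols: np.ndarray) -> None:
        factor = rng.standard_normal(cols.size)
        for r in member_rows:
            noise = rng.standard_normal(cols.size)
            values[r, cols] = np.sqrt(module_rho) * factor + np.sqrt(
                1.0 - module_rho
            ) * noise

    if both_groups:
        correlate(a_cols)
    correlate(b_cols)
    # differential expression of the module genes (not the hub) in group B
    for g in module:
        values[pos[g], b_cols] += de_shift

    truth = Truth(
        "nd" if both_groups else "nr",
        seed,
        (),
        hub,
        tuple(sorted(module)),
        module_rho,
        de_shift,
        n_per_group,
    )
    return _assemble(network, values, genes, sa, sb, truth)


def generate_planted_nr(
    network: Network,
    hub: str,
    module_rho: float = 0.8,
    de_shift: float = 1.0,
    n_per_group: int = 30,
    seed: int = 0,
) -> SyntheticInstance:
    """Hub module co-expressed in group B only; module genes DE-shifted in B."""
    return _planted(network, hub, module_rho, de_shift, n_per_group, seed, False)


def generate_planted_nd(
    network: Network,
    hub: str,
    module_rho: float = 0.8,
    de_shift: float = 1.0,
    n_per_group: int = 30,
    seed: int = 0,
) -> SyntheticInstance:
    """Hub module co-expressed in both groups; module genes DE-shifted in B."""
    return _planted(network, hub, module_rho, de_shift, n_per_group, seed, True)


# --------------------------------------------------------------------------
# Truth manifest round-trip
# --------------------------------------------------------------------------


def write_manifest(truth: Truth, path: str | Path) -> None:
    """Write the truth record as ``key=value`` lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in truth.to_dict().items():
            fh.write(f"{key}={value}\n")


def read_manifest(path: str | Path) -> Truth:
    fields: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, value = line.partition("=")
            fields[key] = value
    return Truth(
        kind=fields["kind"],
        seed=int(fields["seed"]),
        hubs=tuple(g for g in fields["hubs"].split(",") if g),
        planted_hub=fields["planted_hub"] or None,
        module_genes=tuple(g for g in fields["module_genes"].split(",") if g),
        module_rho=float(fields["module_rho"]),
        de_shift=float(fields["de_shift"]),
        n_per_group=int(fields["n_per_group"]),
    )
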