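"""Comparator scores: RIF1/RIF2 and the Taylor interaction-rewiring score.

Both comparators start from the same hub candidates as the main pipeline
(genes with more than ``min_degree`` interactors in the expression-restricted
network) and use *Pearson* correlation within each group, as the original
methods do.

Taylor score of candidate i: the mean over its interactors j of
|r1_ij - r2_ij|, the absolute change of the within-group Pearson correlation.

RIF scores of candidate i, over its differentially expressed interactors j
(selected at BH FDR < ``fdr_cut``):

    RIF1_i = (1/n_DE) sum_j 1/2 (e1_j^2 - e2_j^2) (r1_ij - r2_ij)^2
    RIF2_i = (1/n_DE) sum_j [ (e1_j r1_ij)^2 - (e2_j r2_ij)^2 ]

where e1_j / e2_j are gene j's mean expression in the two groups. RIF1 and
RIF2 are z-score normalized across candidates before ranking.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    GeneRanking,
    Network,
    SampleGroups,
    ValidationError,
)
from .diffexpr import DETable

logger = logging.getLogger(__name__)

__all__ = ["taylor_scores", "rif_scores"]


def _pearson_rows(values: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; constant rows -> zeros (r = 0)."""
    c = values - values.mean(axis=-1, keepdims=True)
    norm = np.sqrt((c**2).sum(axis=-1, keepdims=True))
    return np.divide(c, norm, out=np.zeros_like(c), where=norm > 0)


def _restricted_adjacency(
    network: Network, matrix: ExpressionMatrix
) -> tuple[dict[str, int], list[tuple[int, int]]]:
    pos = {g: i for i, g in enumerate(matrix.genes)}
    edges = [
        (pos[a], pos[b]) for a, b in network.edges if a in pos and b in pos
    ]
    if not edges:
        raise ValidationError("no network edge has both endpoints in the matrix")
    return pos, edges


def _hub_candidates(
    neighbors: dict[int, list[int]], min_degree: int
) -> list[int]:
    return sorted(i for i, nb in neighbors.items() if len(nb) > min_degree)


def _neighbor_map(edges: list[tuple[int, int]]) -> dict[int, list[int]]:
    nb: dict[int, list[int]] = {}
    for a, b in edges:
        nb.setdefault(a, []).append(b)
        nb.setdefault(b, []).append(a)
    return nb


def taylor_scores(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    network: Network,
    min_degree: int = 15,
) -> GeneRanking:
    """Rank hubs by mean |Pearson change| with their interactors."""
    pos, edges = _restricted_adjacency(network, matrix)
    nb = _neighbor_map(edges)
    hubs = _hub_candidates(nb, min_degree)
    if not hubs:
        raise ValidationError(f"no gene has more than {min_degree} interactors")
    za = _pearson_rows(matrix.data[list(groups.samples_a)].to_numpy())
    zb = _pearson_rows(matrix.data[list(groups.samples_b)].to_numpy())
    genes = list(matrix.genes)
    rows = []
    for h in hubs:
        js = np.asarray(nb[h])
        r1 = za[js] @ za[h]
        r2 = zb[js] @ zb[h]
        rows.append({"gene": genes[h], "taylor": float(np.mean(np.abs(r1 - r2)))})
    return GeneRanking.from_scores(pd.DataFrame(rows), "taylor")


def rif_scores(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    network: Network,
    de: DETable,
    fdr_cut: float = 0.01,
    min_degree: int = 15,
) -> tuple[GeneRanking, GeneRanking]:
    """RIF1 and RIF2 rankings over hub candidates.

    A candidate with no differentially expressed interactor (n_DE = 0) is
    excluded from both rankings and logged.
    """
    pos, edges = _restricted_adjacency(network, matrix)
    nb = _neighbor_map(edges)
    hubs = _hub_candidates(nb, min_degree)
    if not hubs:
        raise ValidationError(f"no gene has more than {min_degree} interactors")

    de_set = {g for g in de.de_genes(fdr_cut)}
    genes = list(matrix.genes)
    de_idx = {pos[g] for g in de_set if g in pos}

    a = matrix.data[list(groups.samples_a)].to_numpy()
    b = matrix.data[list(groups.samples_b)].to_numpy()
    e1 = a.mean(axis=1)
    e2 = b.mean(axis=1)
    za = _pearson_rows(a)
    zb = _pearson_rows(b)

    rows = []
    excluded = []
    for h in hubs:
        js = np.asarray([j for j in nb[h] if j in de_idx])
        if js.size == 0:
            excluded.append(genes[h])
            continue
        r1 = za[js] @ za[h]
        r2 = zb[js] @ zb[h]
        rif1 = float(np.mean(0.5 * (e1[js] ** 2 - e2[js] ** 2) * (r1 - r2) ** 2))
        rif2 = float(np.mean((e1[js] * r1) ** 2 - (e2[js] * r2) ** 2))
        rows.append({"gene": genes[h], "rif1_raw": rif1, "rif2_raw": rif2})
    if excluded:
        logger.warning(
            "%d candidate(s) without DE interactors excluded from RIF: %s",
            len(excluded), excluded[:5],
        )
    if len(rows) < 2:
        raise ValidationError("fewer than 2 candidates have DE interactors")

    df = pd.DataFrame(rows)

    def normalize(col: str) -> np.ndarray:
        v = df[col].to_numpy()
        sd = v.std(ddof=0)
        if sd == 0.0:
            raise ValidationError(f"{col} has zero variance across candidates")
        return (v - v.mean()) / sd

    df["rif1"] = normalize("rif1_raw")
    df["rif2"] = normalize("rif2_raw")
    r1 = GeneRanking.from_scores(df[["gene", "rif1_raw", "rif1"]].copy(), "rif1")
    r2 = GeneRanking.from_scores(df[["gene", "rif2_raw", "rif2"]].copy(), "rif2")
    return r1, r2
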