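"""The networked gene prioritization pipeline.

Per dataset the pipeline is:

1. weight the PPI network from two-condition expression (NR: |r1 - r2|;
   ND: |(r1+r2)/2| after removing rewired edges by a permutation filter);
2. select candidates = hub genes with strictly more than ``min_degree``
   interactors in the working (weighted, and for ND filtered) network;
3. stage 1 - for each candidate, test whether its incident edges (the
   subnet) are enriched among the highest-weight edges of the whole network
   (weighted running-sum ES, exponent P = 1, permutation z-score), and trim
   the subnet to the edges in the leading edge;
4. stage 2 - test whether the genes of the trimmed subnet are enriched among
   the most differentially expressed genes (background = all measured genes
   ranked by -log10 p), and trim again; the result is the candidate's DE
   subnet;
5. combine - z-score-normalize the stage-1 and stage-2 z's across candidates
   and rank by their sum.

Cross-dataset utilities: rank-sum aggregation over the genes scored in every
dataset, and a top-k stability test (unweighted enrichment, P = 0, nominal
permutation p; both directional p < 0.005 declares the top lists stable).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    GeneRanking,
    Network,
    SampleGroups,
    ValidationError,
    write_ranking,
)
from .diffexpr import DETable, de_table
from .edge_weights import (
    WeightedNetwork,
    nd_edge_weights,
    nd_permutation_filter,
    nr_edge_weights,
)
from .enrichment import (
    DegenerateNullError,
    RankedList,
    enrichment_score,
    leading_edge,
    nominal_p,
    permutation_z,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NGPParams",
    "DESubnet",
    "NGPResult",
    "select_candidates",
    "score_edge_enrichment",
    "score_de_enrichment",
    "combine_scores",
    "run_ngp",
    "aggregate_rank_sum",
    "stability_analysis",
]


@dataclass(frozen=True)
class NGPParams:
    """Tunable pipeline parameters.

    ``min_degree`` is the hub threshold (a candidate needs strictly more
    interactors than this; 15 matches the conventional minimum objective-set
    size of weighted enrichment analysis). ``weight_exponent`` is the running
    sum exponent P. ``n_perm`` is the permutation count for both z-scores.
    """

    min_degree: int = 15
    weight_exponent: float = 1.0
    n_perm: int = 1000
    nd_filter_perms: int = 10_000
    nd_filter_quantile: float = 0.90
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "min_degree": self.min_degree,
            "weight_exponent": self.weight_exponent,
            "n_perm": self.n_perm,
            "nd_filter_perms": self.nd_filter_perms,
            "nd_filter_quantile": self.nd_filter_quantile,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class DESubnet:
    """A candidate's subnet after both trimming stages."""

    candidate: str
    z_s: float
    z_trimmed: float
    es_s: float
    es_trimmed: float
    surviving_edges: pd.DataFrame  # stage-1 leading-edge edges
    surviving_genes: tuple[str, ...]  # stage-2 leading-edge interactors

    def de_subnet_edges(self) -> pd.DataFrame:
        """Edges connecting the candidate to stage-2 surviving interactors."""
        keep = set(self.surviving_genes)
        e = self.surviving_edges
        other = np.where(e["gene_a"] == self.candidate, e["gene_b"], e["gene_a"])
        return e.loc[pd.Series(other, index=e.index).isin(keep)]


@dataclass(frozen=True)
class NGPResult:
    ranking: GeneRanking
    subnets: dict[str, DESubnet]
    weighted_network: WeightedNetwork
    de: DETable
    dropped: dict[str, str]  # candidate -> reason
    params: NGPParams
    model: str

    def write_outputs(self, prefix: str | Path) -> None:
        """Write ranking, per-candidate DE-subnet edges, and a run manifest."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_ranking(self.ranking, f"{prefix}.ranking.tsv")
        with open(f"{prefix}.subnets.tsv", "w", encoding="utf-8") as fh:
            fh.write("candidate\tgene_a\tgene_b\tweight\n")
            for cand in sorted(self.subnets):
                sub = self.subnets[cand].de_subnet_edges()
                for _, row in sub.iterrows():
                    fh.write(
                        f"{cand}\t{row['gene_a']}\t{row['gene_b']}\t"
                        f"{row['weight']:.17g}\n"
                    )
        manifest = {
            "model": self.model,
            "params": self.params.to_dict(),
            "n_candidates_ranked": len(self.ranking.table),
            "dropped": self.dropped,
        }
        with open(f"{prefix}.manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


# --------------------------------------------------------------------------
# Pipeline stages
# --------------------------------------------------------------------------


def select_candidates(
    weighted: WeightedNetwork, min_degree: int = 15
) -> tuple[str, ...]:
    """Hub genes: strictly more than ``min_degree`` interactors."""
    deg = weighted.degrees()
    hubs = tuple(sorted(deg.index[deg > min_degree]))
    if not hubs:
        raise ValidationError(
            f"no gene has more than {min_degree} interactors; nothing to rank"
        )
    return hubs


def _edge_ids(edges: pd.DataFrame) -> np.ndarray:
    return (edges["gene_a"] + "|" + edges["gene_b"]).to_numpy(dtype=object)


def score_edge_enrichment(
    candidate: str,
    weighted: WeightedNetwork,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed=None,
) -> tuple[float, float, pd.DataFrame]:
    """Stage 1: is the candidate's subnet enriched for high-weight edges?

    Background = every edge of the weighted network ranked by weight;
    objective set = the candidate's incident edges. Returns
    ``(z_s, es, trimmed_edges)`` where ``trimmed_edges`` is the leading edge.
    """
    subnet = weighted.incident_edges(candidate)
    ranked = RankedList.from_scores(
        _edge_ids(weighted.edges),
        weighted.edges["weight"].to_numpy(),
        _edge_ids(subnet),
    )
    es, argmax, _ = enrichment_score(ranked, exponent)
    trimmed_ids = set(leading_edge(ranked, es, argmax))
    if not trimmed_ids:
        raise DegenerateNullError("empty leading edge (ES = 0)")
    z, _ = permutation_z(ranked, exponent, n_perm, seed)
    keep = pd.Series(_edge_ids(weighted.edges), index=weighted.edges.index).isin(
        trimmed_ids
    )
    subnet_keep = weighted.edges.loc[
        keep
        & ((weighted.edges["gene_a"] == candidate) | (weighted.edges["gene_b"] == candidate))
    ]
    return z, es, subnet_keep.reset_index(drop=True)


def score_de_enrichment(
    candidate: str,
    trimmed_edges: pd.DataFrame,
    de: DETable,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed=None,
) -> tuple[float, float, tuple[str, ...]]:
    """Stage 2: are the trimmed subnet's genes enriched among DE genes?

    Background = every measured gene ranked by -log10 p; objective set = the
    interactor genes of the stage-1 surviving edges (excluding the candidate
    itself, which would otherwise sit in every objective set). Returns
    ``(z_trimmed, es, surviving_genes)``.
    """
    interactors = set(trimmed_edges["gene_a"]) | set(trimmed_edges["gene_b"])
    interactors.discard(candidate)
    if not interactors:
        raise DegenerateNullError("stage-1 trim left no interactor genes")
    genes = np.asarray(de.table["gene"], dtype=object)
    scores = de.table["neglogp"].to_numpy()
    members = sorted(interactors & set(genes))
    if not members:
        raise DegenerateNullError("no trimmed interactor is in the DE background")
    ranked = RankedList.from_scores(genes, scores, members)
    es, argmax, _ = enrichment_score(ranked, exponent)
    surviving = leading_edge(ranked, es, argmax)
    z, _ = permutation_z(ranked, exponent, n_perm, seed)
    return z, es, tuple(sorted(surviving))


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0.0:
        raise ValidationError("score column has zero variance; cannot normalize")
    return (v - v.mean()) / sd


def combine_scores(scores: pd.DataFrame) -> GeneRanking:
    """Standardize stage-1 and stage-2 z's across candidates and rank by sum.

    Input needs columns ``gene``, ``z_s``, ``z_trimmed``. Each z column is
    z-score normalized (population sd) so the two stages contribute on the
    same scale; the final score is their sum, ranked descending with
    lexicographic tie-breaking.
    """
    if len(scores) < 2:
        raise ValidationError("need at least 2 scored candidates to combine")
    df = scores.copy()
    df["z_s_norm"] = _zscore(df["z_s"].to_numpy())
    df["z_trimmed_norm"] = _zscore(df["z_trimmed"].to_numpy())
    df["z_combined"] = df["z_s_norm"] + df["z_trimmed_norm"]
    return GeneRanking.from_scores(df, "z_combined")


def run_ngp(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    network: Network,
    model: str = "nr",
    params: NGPParams | None = None,
) -> NGPResult:
    """Run the full per-dataset pipeline and rank all scorable candidates.

    ``model`` is ``"nr"`` or ``"nd"``. All randomness derives from
    ``params.seed``; per-candidate permutation streams are drawn from the
    candidate's position in the sorted candidate list, so results are
    invariant to matrix row order and edge-list line order.
    """
    params = params or NGPParams()
    model = model.lower()
    if model not in ("nr", "nd"):
        raise ValidationError(f"model must be 'nr' or 'nd', got {model!r}")
    root = params.seed if params.seed is not None else int(
        np.random.SeedSequence().generate_state(1)[0] % (2**31)
    )

    if model == "nr":
        weighted = nr_edge_weights(network, matrix, groups)
    else:
        weighted = nd_edge_weights(network, matrix, groups)
        weighted = nd_permutation_filter(
            weighted,
            matrix,
            groups,
            n_perm=params.nd_filter_perms,
            quantile=params.nd_filter_quantile,
            seed=np.random.SeedSequence([root, 0]),
        )

    candidates = select_candidates(weighted, params.min_degree)
    de = de_table(matrix, groups)

    rows = []
    subnets: dict[str, DESubnet] = {}
    dropped: dict[str, str] = {}
    for i, cand in enumerate(candidates):
        try:
            z_s, es_s, trimmed = score_edge_enrichment(
                cand,
                weighted,
                params.weight_exponent,
                params.n_perm,
                seed=np.random.SeedSequence([root, 1, i]),
            )
            z_t, es_t, surviving = score_de_enrichment(
                cand,
                trimmed,
                de,
                params.weight_exponent,
                params.n_perm,
                seed=np.random.SeedSequence([root, 2, i]),
            )
        except DegenerateNullError as exc:
            dropped[cand] = str(exc)
            logger.warning("candidate %s dropped: %s", cand, exc)
            continue
        rows.append({"gene": cand, "z_s": z_s, "z_trimmed": z_t})
        subnets[cand] = DESubnet(cand, z_s, z_t, es_s, es_t, trimmed, surviving)

    if len(rows) < 2:
        raise ValidationError(
            f"only {len(rows)} scorable candidate(s); cannot rank"
        )
    ranking = combine_scores(pd.DataFrame(rows))
    return NGPResult(ranking, subnets, weighted, de, dropped, params, model.upper())


# --------------------------------------------------------------------------
# Cross-dataset analyses
# --------------------------------------------------------------------------


def aggregate_rank_sum(rankings: list[GeneRanking]) -> GeneRanking:
    """Consensus ranking by per-gene rank sum over the shared genes.

    Restricted to genes present in every input ranking; ordered by ascending
    rank sum with lexicographic tie-breaking.
    """
    if len(rankings) < 2:
        raise ValidationError("rank-sum aggregation needs at least 2 rankings")
    shared = set(rankings[0].genes)
    for r in rankings[1:]:
        shared &= set(r.genes)
    if not shared:
        raise ValidationError("no gene is present in every ranking")
    rows = []
    for gene in sorted(shared):
        rows.append(
            {"gene": gene, "rank_sum": sum(r.rank_of(gene) for r in rankings)}
        )
    return GeneRanking.from_scores(pd.DataFrame(rows), "rank_sum", ascending=True)


def stability_analysis(
    ranking_a: GeneRanking,
    ranking_b: GeneRanking,
    k: int,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Are the top-k genes of one dataset highly ranked in the other?

    The top-k of A is the objective set against B's full candidate ranking
    (unweighted running sum, exponent P = 0); significance is the nominal
    permutation p over random membership. Returns ``(p_ab, p_ba)``; both
    below 0.005 is the conventional threshold for calling the top lists
    stable between datasets.
    """
    set_a, set_b = set(ranking_a.genes), set(ranking_b.genes)
    if set_a != set_b:
        raise ValidationError("stability analysis needs rankings over the same genes")
    n = len(set_a)
    if k >= n:
        raise ValidationError(f"top size k={k} must be smaller than the {n} candidates")

    def one_direction(top_from: GeneRanking, background: GeneRanking, subseed) -> float:
        # descending pseudo-score reproduces the background's rank order
        table = background.table
        items = np.asarray(table["gene"], dtype=object)
        scores = (n - table["rank"].to_numpy() + 1).astype(float)
        ranked = RankedList.from_scores(items, scores, list(top_from.top(k)))
        # upper-tail p: only a top set sitting *high* in the other ranking
        # counts as stable; a set at the bottom must not
        return nominal_p(ranked, exponent=0.0, n_perm=n_perm, seed=subseed,
                         sided="greater")

    base = seed if seed is not None else int(
        np.random.SeedSequence().generate_state(1)[0] % (2**31)
    )
    p_ab = one_direction(ranking_a, ranking_b, np.random.SeedSequence([base, 0]))
    p_ba = one_direction(ranking_b, ranking_a, np.random.SeedSequence([base, 1]))
    return p_ab, p_ba
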