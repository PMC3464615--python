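"""Weighted running-sum (GSEA-style) enrichment with permutation statistics.

Given a background of N items ranked by a nonnegative score r_j (descending)
and an objective set S of N_H members, the running sums are

    P_hit(i)  = sum_{j in S, j <= i} r_j^P / NR,   NR = sum_{j in S} r_j^P
    P_miss(i) = sum_{j not in S, j <= i} 1 / (N - N_H)

and the enrichment score ES is the value of P_hit - P_miss at the position of
its maximum absolute deviation (signed). With exponent P = 0 every member
contributes equally and |ES| reduces to the two-sample Kolmogorov-Smirnov
statistic between member and non-member ranks.

Two permutation statistics are provided:

* ``permutation_z``: the null reassigns the multiset of scores to items at
  random and re-sorts; z = (ES - mean(null ES)) / sd(null ES).
* ``nominal_p``: the null redraws the membership (random sets of size N_H);
  the empirical p compares the observed ES with same-sign null values, with
  +1 smoothing so p is never 0.

Because the sorted score vector is invariant under reassigning scores to
items, both nulls reduce to drawing a uniformly random set of member
*positions* on the fixed ranked score vector; this is how they are computed
(vectorized over permutations).

The items of the objective set keep their leading-edge semantics: for ES > 0
the leading edge is the members at ranks <= argmax, for ES < 0 the members at
ranks > argmax. Non-leading-edge members "did not contribute to ES" and are
trimmed away by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ValidationError

__all__ = [
    "DegenerateNullError",
    "RankedList",
    "EnrichmentResult",
    "NullSummary",
    "enrichment_score",
    "leading_edge",
    "permutation_z",
    "nominal_p",
]


class DegenerateNullError(RuntimeError):
    """The permutation null has zero spread; the z-score is undefined."""


@dataclass(frozen=True)
class RankedList:
    """Items sorted by score descending, with membership flags.

    Ties in score are broken lexicographically by item identifier so that a
    ranking is a deterministic function of its inputs.
    """

    items: np.ndarray  # object array of identifiers, ranked best-first
    scores: np.ndarray  # float, descending
    member: np.ndarray  # bool, True where the item belongs to the objective set

    def __post_init__(self) -> None:
        n = len(self.items)
        if not (len(self.scores) == len(self.member) == n):
            raise ValidationError("items, scores and member flags must align")
        if n < 2:
            raise ValidationError("ranked list needs at least 2 items")
        if (np.asarray(self.scores) < 0).any():
            raise ValidationError("ranking scores must be nonnegative")
        if np.any(np.diff(self.scores) > 0):
            raise ValidationError("scores must be sorted descending")
        n_h = int(self.member.sum())
        if not 0 < n_h < n:
            raise ValidationError(
                f"objective set must be a proper nonempty subset (N_H={n_h}, N={n})"
            )

    @classmethod
    def from_scores(
        cls,
        items: Sequence[str],
        scores: Sequence[float],
        member_items: Sequence[str],
    ) -> "RankedList":
        items_arr = np.asarray(items, dtype=object)
        scores_arr = np.asarray(scores, dtype=float)
        if len(set(items)) != len(items_arr):
            raise ValidationError("item identifiers must be unique")
        order = np.lexsort((items_arr.astype(str), -scores_arr))
        member_set = set(member_items)
        unknown = member_set - set(items)
        if unknown:
            raise ValidationError(f"member items not in background: {sorted(unknown)[:5]}")
        items_arr = items_arr[order]
        member = np.array([it in member_set for it in items_arr], dtype=bool)
        return cls(items_arr, scores_arr[order], member)

    @property
    def n(self) -> int:
        return len(self.items)

    @property
    def n_member(self) -> int:
        return int(self.member.sum())


@dataclass(frozen=True)
class NullSummary:
    mean: float
    sd: float
    n_perm: int


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    argmax_rank: int  # 1-based rank of the maximum |P_hit - P_miss|
    leading_edge: tuple[str, ...]
    z: float
    nominal_p: float
    null_summary: NullSummary


def _running_sum(
    member: np.ndarray, weights: np.ndarray, exponent: float
) -> np.ndarray:
    """P_hit - P_miss prefix sums for one ranked list."""
    n = member.size
    n_h = int(member.sum())
    w = weights**exponent
    # accumulate NR in rank order so the running sums are a plain sequential
    # evaluation of the definition
    nr = 0.0
    for v in w[member]:
        nr += float(v)
    if nr == 0.0:
        raise ValidationError("all member scores are zero; NR = 0")
    hit = np.where(member, w / nr, 0.0)
    miss = np.where(member, 0.0, 1.0 / (n - n_h))
    return np.cumsum(hit - miss)


def enrichment_score(
    ranked: RankedList, exponent: float = 1.0
) -> tuple[float, int, np.ndarray]:
    """ES, its 1-based argmax rank, and the full running-sum vector.

    The ES is the *signed* running-sum value at the position of maximal
    absolute deviation; among tied deviations the earliest rank wins.
    """
    running = _running_sum(ranked.member, ranked.scores, exponent)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx + 1, running


def leading_edge(ranked: RankedList, es: float, argmax_rank: int) -> tuple[str, ...]:
    """Members that contribute to the ES extremum.

    ES > 0: members at ranks <= argmax; ES < 0: members at ranks > argmax;
    ES = 0: no member contributes.
    """
    if es == 0.0:
        return ()
    ranks = np.arange(1, ranked.n + 1)
    if es > 0:
        mask = ranked.member & (ranks <= argmax_rank)
    else:
        mask = ranked.member & (ranks > argmax_rank)
    return tuple(ranked.items[mask])


def _null_es(
    sorted_scores: np.ndarray,
    n_member: int,
    exponent: float,
    n_perm: int,
    rng: np.random.Generator,
    max_elements: int = 5_000_000,
) -> np.ndarray:
    """Null ES values for random member positions on the fixed ranked scores."""
    n = sorted_scores.size
    w = sorted_scores**exponent
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, max_elements // n))
    for start in range(0, n_perm, chunk):
        c = min(chunk, n_perm - start)
        # random member positions: first n_member columns of random permutations
        pos = np.argsort(rng.random((c, n)), axis=1)[:, :n_member]
        member = np.zeros((c, n), dtype=bool)
        np.put_along_axis(member, pos, True, axis=1)
        hit = np.where(member, w[None, :], 0.0)
        nr = hit.sum(axis=1)
        if (nr == 0.0).any():
            raise DegenerateNullError("a permutation produced NR = 0")
        running = np.cumsum(
            hit / nr[:, None] - (~member) / (n - n_member), axis=1
        )
        idx = np.abs(running).argmax(axis=1)
        out[start : start + c] = running[np.arange(c), idx]
    return out


def permutation_z(
    ranked: RankedList,
    exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> tuple[float, NullSummary]:
    """Z-score of the observed ES against a score-reassignment null.

    The null shuffles the assignment of scores to items and re-sorts, which on
    the fixed sorted score vector amounts to drawing the member positions
    uniformly at random. z = (ES - mean null) / sd null (sample sd).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    es, _, _ = enrichment_score(ranked, exponent)
    null = _null_es(ranked.scores, ranked.n_member, exponent, n_perm, rng)
    sd = float(null.std(ddof=1))
    mean = float(null.mean())
    if sd == 0.0:
        raise DegenerateNullError("permutation null has zero standard deviation")
    return (es - mean) / sd, NullSummary(mean, sd, n_perm)


def nominal_p(
    ranked: RankedList,
    exponent: float = 0.0,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    sided: str = "same-sign",
) -> float:
    """Empirical p of the observed ES against a membership-permutation null.

    ``sided="same-sign"`` counts null values with the same sign as the
    observed ES that are at least as extreme (enrichment and depletion are
    each significant in their own direction). ``sided="greater"`` asks only
    whether the observed ES is high (null >= observed), so a depleted set
    gets p near 1 — the right question when "high in the other ranking" is
    what matters. +1 smoothing of numerator and denominator keeps p in
    (0, 1].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    es, _, _ = enrichment_score(ranked, exponent)
    null = _null_es(ranked.scores, ranked.n_member, exponent, n_perm, rng)
    if sided == "greater":
        extreme = int((null >= es).sum())
    elif sided == "same-sign":
        if es >= 0:
            extreme = int(((null >= es) & (null >= 0)).sum())
        else:
            extreme = int(((null <= es) & (null < 0)).sum())
    else:
        raise ValidationError(f"unknown sided mode {sided!r}")
    return (1 + extreme) / (1 + n_perm)
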