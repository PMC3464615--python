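# Methods

## Model and assumptions

The pipeline assumes that disease-associated genes act on their network
neighbourhood in one of two ways between the compared conditions:

* **NR (network rewiring)** — the gene's functional couplings change, so the
  rank correlation of its expression with an interactor differs between the
  groups. Edge weight: `|r1 − r2|`, where `r1`, `r2` are within-group
  Spearman coefficients of the edge's endpoints.
* **ND (networked differential expression)** — the gene's couplings are
  unchanged (consistently high correlation in both groups) but its
  dysregulation propagates to interactors' expression levels. Edge weight:
  `|(r1 + r2)/2|`, computed after removing rewired edges (below).

Both weights are absolute values, so all results are invariant to which
group is called A or B. Spearman (rather than Pearson) correlation makes
edge weights invariant to any strictly monotone per-gene transform of the
expression scale. The comparators (Taylor, RIF1/RIF2) use Pearson, as the
original methods do.

Candidates are *hub* genes with strictly more than `min_degree = 15`
interactors in the working network — the conventional minimum objective-set
size for running-sum enrichment, and under ND the degree is counted on the
*filtered* network (filtering precedes subnet construction).

## The ND permutation filter

For each edge the observed `Δr = |r1 − r2|` is compared to a null built by
re-labelling samples: each permutation reassigns the pooled samples to two
pseudo-groups of the original sizes and recomputes both correlations. One
set of `n_perm = 10 000` permutations is drawn from the seeded generator
and shared by all edges: each edge's marginal test is unchanged by sharing,
while the cost drops by orders of magnitude and the result is reproducible
from a single seed. An edge is removed when its observed `Δr` strictly
exceeds the nearest-rank 90th percentile of its null — implemented as
"at least ⌈0.9·n_perm⌉ null values fall strictly below the observed value",
which avoids materializing the full null matrix. Under a true null this
removes ~10% of edges (the type-I calibration test pins it to [0.08, 0.12]
on 500 null edges).

Ranking inside the filter uses mid-ranks; when every gene's values are
pairwise distinct (the generic case for continuous data) an ordinal
double-argsort ranker is used instead — identical output, several-fold
faster — and the null pass runs in float32 (the observed correlations stay
float64; an empirical quantile over 10 000 draws is insensitive to 1e-7
rounding).

## Enrichment scores, trimming, and permutation statistics

Stage 1 ranks all edges of the weighted network by weight (descending, ties
broken lexicographically by the canonical `geneA|geneB` edge id); the
candidate's incident edges are the objective set. Stage 2 ranks all measured
genes by `−log10 p` (two-tailed Welch t-test, unequal variances); the
objective set is the interactor genes of the stage-1 leading edge,
*excluding the candidate itself* — every surviving edge touches the
candidate, so including it would add the same constant bias to every
objective set. The exponent is `P = 1` in both stages; `P = 0` (classic
Kolmogorov–Smirnov form; |ES| then equals the two-sample KS statistic of
member vs non-member ranks) is used by the stability test.

ES is the signed running-sum value at the maximum absolute deviation; among
tied deviations the earliest rank wins. The leading edge is the members at
ranks ≤ argmax for ES > 0, the members at ranks > argmax for ES < 0, and
empty for ES = 0 (such candidates are dropped as unscorable, not given
sentinel scores).

The z-score null permutes the assignment of scores to items and re-sorts.
Because the sorted score vector is invariant under that reassignment, the
null is computed by drawing uniformly random member *positions* on the fixed
ranked scores — mathematically identical when scores are distinct (ties
would make the lexicographic re-sort deviate from uniform positions by a
measure-zero technicality on continuous data). The null mean and sample
standard deviation (ddof = 1) of 1000 such ES values give
`Z = (ES − mean)/sd`; a zero-spread null raises a degenerate-null error and
the candidate is dropped and reported.

The nominal p (used by the stability test) permutes membership instead and
applies +1 smoothing: `p = (1 + #extreme) / (1 + n_perm)`, so p is never 0.
Two sidedness modes exist: `same-sign` (enrichment and depletion each
significant in their own direction — the generic convention) and `greater`
(upper tail only). `stability_analysis` uses `greater`: the question "does
dataset A's top-k sit *high* in dataset B's ranking" is directional, and a
top list concentrated at the *bottom* of the other ranking must come out
non-significant, not significant-by-depletion.

## Combination and cross-dataset analyses

Stage-1 and stage-2 z's are z-score normalized across candidates using the
population standard deviation (ddof = 0) and summed; candidates are ranked
by the sum, ties broken lexicographically. Rank-sum aggregation restricts to
genes present in every input ranking and orders by ascending rank sum.
Stability is declared when both directional p's are below 0.005.

## Differential expression

Welch's two-sample t-test (two-tailed, Satterthwaite df) via
`scipy.stats.ttest_ind(equal_var=False)`, with defined degenerate cases:
both groups constant and equal → t = 0, p = 1; both constant but unequal →
p = smallest positive normal double (≈ 2.2e-308), logged. `−log` uses base
10; the base only rescales a monotone ranking score. Benjamini–Hochberg
FDR goes through `statsmodels.stats.multitest.multipletests`, wrapped with
domain validation (p ∈ (0, 1]). Probe tables are collapsed to genes by
dropping ambiguous probes (mapped to more than one gene) and keeping, per
gene, the probe with the smallest Welch p — ties broken by lexicographically
smallest probe id for determinism.

## Degenerate inputs and numerical choices

* A constant expression vector has no defined correlation; it contributes
  r = 0 (with a warning) rather than aborting a run.
* Missing values are rejected at load time, never imputed; gene identifiers
  are case-sensitive opaque strings (no symbol aliasing, which would
  silently rewrite network topology).
* Group sizes below 4 are rejected (correlation and Welch tests on fewer
  samples are not meaningful); the floor is configurable.
* Per-candidate permutation streams are derived from the run seed and the
  candidate's position in the *sorted* candidate list, making every output
  invariant to matrix row order and edge-list line order, and two runs with
  the same inputs and seed byte-identical.
* Rankings are written with 17 significant digits so a write/read round
  trip is exact.

## Synthetic data: what it emulates and what it does not

The generators build a network of disjoint star modules (hubs) plus uniform
random background edges, and expression in which a planted hub's module
shares a latent factor: module gene = √ρ·factor + √(1−ρ)·noise, giving
pairwise correlation ≈ ρ with the hub — in one group (NR) or both (ND) —
and module genes (not the hub) shifted by `de_shift` σ in group B. All other
genes are iid standard normal. Defaults emulate a modestly powered
two-condition microarray comparison: module size 20, ρ = 0.8, shift = 1 σ,
30 samples per group, 21 hubs (1 planted + 20 decoys) on 500 genes with 300
background edges.

This captures exactly the correlation/DE structure the two models assume,
so recovery tests demonstrate that the pipeline detects what it claims to
detect. It does *not* emulate probe-level noise, batch effects, correlated
backgrounds, overlapping modules, or heavy-tailed expression — passing
tests therefore validate the method's contracts and calibration, not its
field performance on real microarray cohorts.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so the
statistics are well-resolved: recovery over 20 (tests) or 10 (script)
replicate instances per model at the default generator conditions; filter
calibration on 500 null edges with the full 10 000 permutations; stability
calibration over 200 replicates of 200-candidate rankings with 1000
permutations. Permutation counts for stage z-scores default to 1000.

## Known limitations

* The ND filter recomputes correlations for every edge under every
  permutation; for very large networks (tens of thousands of edges and
  genes) a run takes correspondingly longer — the shared-permutation design
  is what keeps it tractable at all.
* Stability analysis requires the two rankings to cover the same candidate
  set; restriction to a common subset is the caller's responsibility.
* With few candidates (e.g. ~20 hubs in a small simulation), the top-k
  stability p cannot be small unless most of the top-k reproduces; a single
  reproducible true positive among noise-ranked decoys yields moderate p —
  visible in `examples/04`.
* Under the ND model, a genuinely non-rewired hub can occasionally lose
  enough edges to the ~10% per-edge null removal of the filter to fall below
  the >15-interactor candidate threshold (for a degree-20 hub this happens
  in a few percent of instances); such a hub is simply absent from that
  dataset's ranking.
* Heat-kernel / random-walk comparator rankings are out of scope.
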