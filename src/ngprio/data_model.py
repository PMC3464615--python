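"""Domain types and plain-text I/O.

Containers for the objects the pipeline moves around: a genes x samples
expression matrix (already normalized, log scale), a two-group sample
labelling, a probe-level table for the probe -> gene collapsing step, an
undirected PPI network, and a ranked gene table. All readers are strict:
missing or non-numeric values are rejected rather than imputed, and gene /
sample / probe identifiers are treated as case-sensitive opaque strings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "FormatError",
    "ExpressionMatrix",
    "SampleGroups",
    "ProbeTable",
    "Network",
    "GeneRanking",
    "read_expression_table",
    "read_group_labels",
    "read_edge_list",
    "read_probe_table",
    "collapse_probes_to_genes",
    "write_ranking",
    "read_ranking",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, group counts...)."""


class FormatError(ValueError):
    """A file cannot be parsed as the expected table layout."""


# --------------------------------------------------------------------------
# Expression matrix
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric matrix on the preprocessed (log) scale.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as the columns. All values must be finite floats.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        values = df.to_numpy()
        if values.dtype.kind not in "fiu":
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)])


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with header ``gene<TAB>sample1<TAB>...``, one row per gene.

    Non-numeric cells and duplicated gene rows are rejected with the offending
    row/column named in the error.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() | raw.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path.name}: non-numeric cell {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    return ExpressionMatrix(numeric)


# --------------------------------------------------------------------------
# Sample groups
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleGroups:
    """Two-group assignment of samples.

    ``group_a`` / ``group_b`` are the two labels, ordered lexicographically so
    that a run is reproducible regardless of file order. Every statistic the
    pipeline computes from them (|delta rho|, |mean rho|, two-tailed p) is
    invariant to swapping the two groups.
    """

    assignment: Mapping[str, str]
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if labels != {self.group_a, self.group_b}:
            raise ValidationError(
                f"assignment labels {sorted(labels)} do not match "
                f"({self.group_a!r}, {self.group_b!r})"
            )

    @classmethod
    def from_assignment(
        cls, assignment: Mapping[str, str], min_group_size: int = 4
    ) -> "SampleGroups":
        labels = sorted(set(assignment.values()))
        if len(labels) != 2:
            raise ValidationError(
                f"expected exactly 2 groups, found {len(labels)}: {labels[:5]}"
            )
        groups = cls(dict(assignment), labels[0], labels[1])
        for label, members in ((labels[0], groups.samples_a), (labels[1], groups.samples_b)):
            if len(members) < min_group_size:
                raise ValidationError(
                    f"group {label!r} has {len(members)} samples; "
                    f"minimum is {min_group_size}"
                )
        return groups

    @property
    def samples_a(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignment.items() if g == self.group_a)

    @property
    def samples_b(self) -> tuple[str, ...]:
        return tuple(s for s, g in self.assignment.items() if g == self.group_b)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.assignment)


def read_group_labels(
    path: str | Path, matrix: ExpressionMatrix, min_group_size: int = 4
) -> SampleGroups:
    """Read a two-column ``sample<TAB>group`` TSV and restrict it to the matrix.

    A header row is detected by its first token not being a sample of the
    matrix. Matrix samples absent from the label file are dropped from the
    analysis with a warning; exactly two groups of at least ``min_group_size``
    samples must remain.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path.name}: expected 2 columns, found {df.shape[1]}")
    if df.iloc[0, 0] not in matrix.samples:
        df = df.iloc[1:]
    assignment = {
        sample: group
        for sample, group in zip(df[0], df[1])
        if sample in set(matrix.samples)
    }
    missing = [s for s in matrix.samples if s not in assignment]
    if missing:
        warnings.warn(
            f"{len(missing)} matrix sample(s) absent from {path.name} and "
            f"dropped from the analysis: {missing[:5]}",
            stacklevel=2,
        )
    if not assignment:
        raise ValidationError(f"{path.name}: no labelled sample matches the matrix")
    return SampleGroups.from_assignment(assignment, min_group_size=min_group_size)


# --------------------------------------------------------------------------
# Probe table and probe -> gene collapsing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeTable:
    """Probe-level expression with a probe -> gene(s) mapping.

    ``genes`` maps each probe to the tuple of gene identifiers it targets;
    a probe mapped to more than one gene is *ambiguous* and excluded from
    the collapsing step.
    """

    values: pd.DataFrame  # probes x samples
    genes: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate probe identifiers")
        missing = [p for p in self.values.index if p not in self.genes]
        if missing:
            raise ValidationError(f"probes without gene mapping: {missing[:5]}")

    def ambiguous_probes(self) -> tuple[str, ...]:
        return tuple(p for p in self.values.index if len(self.genes[p]) > 1)


def read_probe_table(path: str | Path) -> ProbeTable:
    """Read ``probe<TAB>gene[;gene2...]<TAB>sample1...`` (header required)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 3:
        raise FormatError(f"{path.name}: expected probe, gene and value columns")
    probes = raw.iloc[:, 0]
    genes = {
        p: tuple(g.split(";")) for p, g in zip(probes, raw.iloc[:, 1])
    }
    values = raw.iloc[:, 2:].apply(lambda c: pd.to_numeric(c, errors="raise"))
    values.index = pd.Index(probes, name="probe")
    return ProbeTable(values, genes)


def collapse_probes_to_genes(
    probes: ProbeTable, groups: SampleGroups
) -> ExpressionMatrix:
    """Collapse a probe table to one representative probe per gene.

    Ambiguous probes (mapped to more than one gene) are removed; for each
    remaining gene the probe with the smallest Welch two-tailed p between the
    two groups is retained, on the assumption that expression changed between
    conditions so the most differential probe best represents the gene. Ties
    on p are broken by the lexicographically smallest probe id.
    """
    from .diffexpr import welch_t_test

    idx_a = [s for s in groups.samples_a if s in probes.values.columns]
    idx_b = [s for s in groups.samples_b if s in probes.values.columns]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValidationError("probe table lacks the grouped samples")

    best: dict[str, tuple[float, str]] = {}
    for probe in probes.values.index:
        mapped = probes.genes[probe]
        if len(mapped) != 1:
            continue  # ambiguous -> filtered out
        gene = mapped[0]
        x = probes.values.loc[probe, idx_a].to_numpy(dtype=float)
        y = probes.values.loc[probe, idx_b].to_numpy(dtype=float)
        _, p, _ = welch_t_test(x, y)
        key = (p, probe)
        if gene not in best or key < best[gene]:
            best[gene] = key
    if not best:
        raise ValidationError("no unambiguous probe maps to any gene")
    rows = {gene: probes.values.loc[probe] for gene, (_, probe) in sorted(best.items())}
    df = pd.DataFrame(rows).T
    df.index.name = "gene"
    return ExpressionMatrix(df)


# --------------------------------------------------------------------------
# Network
# --------------------------------------------------------------------------

_EDGE_HEADER_TOKENS = {
    "gene", "genea", "gene_a", "gene1", "source", "from", "node", "nodea",
    "node_a", "protein", "proteina", "protein_a", "interactor_a", "geneid",
}


@dataclass(frozen=True)
class Network:
    """Undirected, simple PPI network (no self-loops, no parallel edges)."""

    graph: nx.Graph
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(tuple(sorted(e)) for e in self.graph.edges))

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, gene: str) -> tuple[str, ...]:
        return tuple(sorted(self.graph.neighbors(gene)))

    @classmethod
    def from_edges(cls, pairs: Sequence[tuple[str, str]]) -> "Network":
        g = nx.Graph()
        self_loops = duplicates = 0
        for a, b in pairs:
            if a == b:
                self_loops += 1
                continue
            if g.has_edge(a, b):
                duplicates += 1
                continue
            g.add_edge(a, b)
        return cls(g, self_loops, duplicates)


def read_edge_list(path: str | Path) -> Network:
    """Read a two-column TSV of gene pairs into an undirected simple graph.

    Self-interactions and duplicate pairs (either orientation) are dropped and
    counted. An optional header line is detected by a non-identifier first
    token (``gene``, ``source``, ``protein_a`` and similar).
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path.name}:{lineno}: expected 2 columns, found {len(fields)}"
                )
            if lineno == 1 and fields[0].strip().lower() in _EDGE_HEADER_TOKENS:
                continue
            pairs.append((fields[0].strip(), fields[1].strip()))
    net = Network.from_edges(pairs)
    if net.n_self_loops_dropped or net.n_duplicates_dropped:
        logger.info(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path.name, net.n_self_loops_dropped, net.n_duplicates_dropped,
        )
    return net


# --------------------------------------------------------------------------
# Gene ranking
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered by a score; rank 1 is best; ties broken by gene id."""

    table: pd.DataFrame  # columns: rank, gene, <score columns...>
    score_column: str

    def __post_init__(self) -> None:
        t = self.table
        for col in ("rank", "gene"):
            if col not in t.columns:
                raise ValidationError(f"ranking table lacks column {col!r}")
        n = len(t)
        if sorted(t["rank"]) != list(range(1, n + 1)):
            raise ValidationError("ranks must be exactly 1..n and unique")
        if t["gene"].duplicated().any():
            raise ValidationError("duplicate genes in ranking")
        if self.score_column not in t.columns:
            raise ValidationError(f"score column {self.score_column!r} missing")

    @classmethod
    def from_scores(
        cls,
        scores: pd.DataFrame,
        score_column: str,
        ascending: bool = False,
    ) -> "GeneRanking":
        """Build a ranking from a table with a ``gene`` column.

        Sorted by ``score_column`` (descending unless ``ascending``), ties
        broken lexicographically by gene identifier.
        """
        df = scores.sort_values(
            [score_column, "gene"], ascending=[ascending, True], kind="mergesort"
        ).reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        cols = ["rank", "gene"] + [c for c in df.columns if c not in ("rank", "gene")]
        return cls(df[cols], score_column)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.table["gene"])

    def top(self, k: int) -> tuple[str, ...]:
        return tuple(self.table.nsmallest(k, "rank")["gene"])

    def rank_of(self, gene: str) -> int:
        row = self.table.loc[self.table["gene"] == gene, "rank"]
        if row.empty:
            raise KeyError(gene)
        return int(row.iloc[0])


def write_ranking(ranking: GeneRanking, path: str | Path) -> None:
    """Write a ranking as TSV ``rank<TAB>gene<TAB>scores...``.

    Floats are written with 17 significant digits so a write/read round trip
    reproduces the ranking exactly.
    """
    df = ranking.table.copy()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            out = []
            for col, v in row.items():
                if isinstance(v, (float, np.floating)):
                    out.append(format(float(v), ".17g"))
                else:
                    out.append(str(v))
            fh.write("\t".join(out) + "\n")


def read_ranking(path: str | Path, score_column: str | None = None) -> GeneRanking:
    """Read a ranking TSV written by :func:`write_ranking`.

    ``score_column`` defaults to the last column of the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    df["rank"] = df["rank"].astype(int)
    if score_column is None:
        score_column = df.columns[-1]
    return GeneRanking(df.sort_values("rank").reset_index(drop=True), score_column)
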