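"""Differential expression: Welch t statistics, -log10(p) scores, BH FDR.

The pipeline ranks genes by the magnitude of differential expression,
measured as -log10 of a two-tailed Welch (unequal-variance) t-test p-value
between the two sample groups. The RIF comparators additionally select
"DE genes" at Benjamini-Hochberg FDR < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, SampleGroups, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["DETable", "welch_t_test", "de_table", "bh_fdr"]

# smallest positive normal double; used when two exactly-constant groups differ
_TINY_P = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class DETable:
    """Per-gene differential expression between group A and group B.

    Columns: ``gene``, ``mean_a``, ``mean_b``, ``t``, ``p`` (two-tailed, in
    (0, 1]), ``neglogp`` (-log10 p, >= 0), ``fdr`` (BH-adjusted), and
    ``direction`` (sign of mean_b - mean_a).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "mean_a", "mean_b", "t", "p", "neglogp", "fdr", "direction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"DE table lacks columns {sorted(missing)}")
        p = self.table["p"].to_numpy()
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError("p-values must lie in (0, 1]")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.table["gene"])

    def neglogp_series(self) -> pd.Series:
        return self.table.set_index("gene")["neglogp"]

    def de_genes(self, fdr_cut: float = 0.01) -> tuple[str, ...]:
        sub = self.table.loc[self.table["fdr"] < fdr_cut, "gene"]
        return tuple(sub)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t-test (two-tailed, unequal variances).

    Returns ``(t, p, df)`` with Satterthwaite degrees of freedom. Degenerate
    inputs are defined rather than fatal: two zero-variance groups with equal
    means give ``t = 0, p = 1``; zero-variance groups with unequal means give
    the smallest representable positive p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("welch_t_test requires at least 2 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            logger.debug("welch_t_test: both groups constant and equal; t=0, p=1")
            return 0.0, 1.0, float(x.size + y.size - 2)
        logger.warning(
            "welch_t_test: both groups constant with unequal means; "
            "p set to smallest positive value"
        )
        sign = -1.0 if y.mean() > x.mean() else 1.0
        return sign * np.inf, _TINY_P, float(x.size + y.size - 2)
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    t = float(res.statistic)
    p = float(res.pvalue)
    if p <= 0.0:
        p = _TINY_P
    return t, p, float(res.df)


def de_table(matrix: ExpressionMatrix, groups: SampleGroups) -> DETable:
    """Welch t-test per gene between the two groups; BH FDR over all genes."""
    a = matrix.data[list(groups.samples_a)].to_numpy()
    b = matrix.data[list(groups.samples_b)].to_numpy()
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)

    res = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    # rows where scipy returned nan (zero variance in both groups)
    bad = ~np.isfinite(p)
    for i in np.flatnonzero(bad):
        t[i], p[i], _ = welch_t_test(a[i], b[i])
    p = np.clip(p, _TINY_P, 1.0)

    df = pd.DataFrame(
        {
            "gene": matrix.genes,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "t": t,
            "p": p,
            "neglogp": -np.log10(p),
            "fdr": bh_fdr(p),
            "direction": np.sign(mean_b - mean_a).astype(int),
        }
    )
    return DETable(df.reset_index(drop=True))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bh_fdr expects a non-empty 1-d array")
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
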