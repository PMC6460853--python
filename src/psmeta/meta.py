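"""Fisher's-method combination of branch-level p-values.

Fisher's method combines k independent p-values via

    X^2 = -2 * sum(ln p_i)  ~  chi-square with 2k degrees of freedom

under the joint null. The pipeline applies it at two levels: branch
p-values are first combined within each evolutionary clade, and the
clade-level p-values are then combined across clades into a single
per-gene meta-analysis p-value, followed by BH adjustment over all genes
that could be combined.

Two exclusion rules apply before combining:

* NA entries (genes untestable on a branch) are dropped.
* Entries exactly equal to 1.0 are dropped by default. These arise
  upstream when the likelihood-ratio statistic is degenerate (LRT of 0);
  keeping them would contribute nothing to the statistic while inflating
  the degrees of freedom. ``keep_unit_p=True`` retains them for
  sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CladeMap, PValueMatrix
from .fdr import bh_adjust

__all__ = [
    "FisherCombination",
    "fisher_combine",
    "combine_within_clade",
    "combine_across_clades",
]


@dataclass
class FisherCombination:
    """Result of one Fisher combination: statistic, retained count, p."""

    statistic: float
    retained_k: int
    combined_p: float

    @property
    def df(self) -> int:
        return 2 * self.retained_k


def fisher_combine(
    pvalues,
    keep_unit_p: bool = False,
    zero_floor: float | None = None,
) -> FisherCombination:
    """Combine p-values with Fisher's method.

    Parameters
    ----------
    pvalues
        Iterable of p-values in [0, 1]; NaN marks untestable entries and
        is excluded.
    keep_unit_p
        Retain entries exactly equal to 1.0 (contributing 0 to the
        statistic but 2 degrees of freedom each). Off by default.
    zero_floor
        If given, p-values of exactly 0 are raised to this floor before
        taking logs; otherwise a zero raises, since ln 0 is undefined.

    Returns
    -------
    FisherCombination
        With no retained values, ``(nan, 0, nan)`` — the gene could not
        be combined. With one retained value the combined p equals that
        value exactly (k = 1 identity).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = p[~np.isnan(p)]
    if not keep_unit_p:
        p = p[p < 1.0]
    k = len(p)
    if k == 0:
        return FisherCombination(np.nan, 0, np.nan)
    if np.any(p == 0.0):
        if zero_floor is None:
            raise ValueError(
                "p-value of exactly 0 cannot enter Fisher's method; "
                "set zero_floor (e.g. 1e-300) to floor it"
            )
        p = np.maximum(p, zero_floor)
    stat = float(-2.0 * np.log(p).sum())
    if k == 1:
        return FisherCombination(stat, 1, float(p[0]))
    return FisherCombination(stat, k, float(stats.chi2.sf(stat, df=2 * k)))


def combine_within_clade(
    matrix: PValueMatrix,
    clades: CladeMap,
    keep_unit_p: bool = False,
    zero_floor: float | None = None,
) -> PValueMatrix:
    """Collapse a genes x branches matrix to genes x clades.

    Each entry is the Fisher combination of the gene's branch p-values
    within the clade; clades where a gene retains no values yield NA.
    One-branch clades pass their column through unchanged (k = 1).
    """
    clades.validate_against(matrix)
    out = {}
    for clade, branches in clades.clades.items():
        sub = matrix.data[branches].to_numpy()
        col = np.empty(sub.shape[0])
        for i, row in enumerate(sub):
            res = fisher_combine(row, keep_unit_p=keep_unit_p, zero_floor=zero_floor)
            col[i] = res.combined_p
        out[clade] = col
    df = pd.DataFrame(out, index=matrix.data.index)
    df.index.name = matrix.data.index.name
    return PValueMatrix(df)


def combine_across_clades(
    clade_matrix: PValueMatrix,
    fdr_threshold: float = 0.1,
    keep_unit_p: bool = False,
    zero_floor: float | None = None,
) -> pd.DataFrame:
    """Per-gene Fisher combination across clade columns, with BH adjustment.

    Returns a table with one row per gene: the clade-level inputs, the
    number of retained p-values, the Fisher statistic, the combined p,
    its BH-adjusted value over all combinable genes, and a significance
    flag at ``fdr < fdr_threshold`` (strict). Genes with no combinable
    input get NA rows and are excluded from the BH universe, since they
    were never tested.
    """
    df = clade_matrix.data
    stats_, ks, ps = [], [], []
    for _, row in df.iterrows():
        res = fisher_combine(row.to_numpy(), keep_unit_p=keep_unit_p, zero_floor=zero_floor)
        stats_.append(res.statistic)
        ks.append(res.retained_k)
        ps.append(res.combined_p)
    result = df.copy()
    result["retained_k"] = ks
    result["statistic"] = stats_
    result["combined_p"] = ps
    combined = np.asarray(ps, dtype=float)
    tested = ~np.isnan(combined)
    fdr = np.full(len(combined), np.nan)
    if tested.any():
        fdr[tested] = bh_adjust(combined[tested]).fdr
    result["fdr"] = fdr
    result["significant"] = (fdr < fdr_threshold) & tested
    result = result.reset_index().rename(columns={result.index.name or "index": "gene"})
    return result
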