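"""Benjamini–Hochberg step-up FDR adjustment.

The step-up is computed explicitly, from the largest rank downward:

    FDR_n = p_n
    FDR_i = min(p_i * n / i, FDR_{i+1})    for the sorted p_1 <= ... <= p_n

which is what produces the characteristic runs of tied adjusted values when
several consecutive p_i * n / i terms exceed the cap from above. Results
are returned in the caller's original order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AdjustedPVector", "bh_adjust", "significant"]


@dataclass
class AdjustedPVector:
    """Raw p-values and their BH-adjusted companions, in original order."""

    raw: np.ndarray
    fdr: np.ndarray

    def __len__(self) -> int:
        return len(self.raw)


def bh_adjust(pvalues) -> AdjustedPVector:
    """Benjamini–Hochberg step-up adjustment.

    Parameters
    ----------
    pvalues
        Sequence of p-values, all in [0, 1]. NA entries must be excluded
        by the caller (the adjustment universe is the tested hypotheses).

    Returns
    -------
    AdjustedPVector
        Adjusted values satisfy FDR_i >= p_i, lie in [0, 1], are
        non-decreasing along the sorted p order, and tied raw p-values
        receive identical adjusted values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.any(np.isnan(p)):
        raise ValueError("NA p-values must be excluded before adjustment")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return AdjustedPVector(p, p.copy())
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    fdr_sorted = np.empty(n)
    running = 1.0
    for i in range(n - 1, -1, -1):  # from FDR_n downward
        running = min(running, sorted_p[i] * n / (i + 1))
        fdr_sorted[i] = running
    fdr = np.empty(n)
    fdr[order] = fdr_sorted
    return AdjustedPVector(p.copy(), fdr)


def significant(adjusted: AdjustedPVector, threshold: float) -> set[int]:
    """Indices (original order) with FDR strictly below *threshold*.

    Strict inequality mirrors the "FDR < 0.05" / "FDR < 0.1" calls used
    for branch scans and meta-analysis respectively.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return set(np.flatnonzero(adjusted.fdr < threshold).tolist())
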