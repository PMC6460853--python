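"""Gene-ontology association test against an empirical null.

Given the full pool of per-term enrichment p-values from a GO sweep and a
designated list of terms of interest (e.g. functions whose expression is
known to track maximum-lifespan residuals across mammals), the test asks
whether the designated terms are collectively more enriched than a random
set of terms of the same size.

The observed statistic is Fisher's -2 * sum(ln p) over the m designated
terms found in the pool. The null distribution is built empirically: each
draw samples m p-values from the full pool (without replacement by
default) and recomputes the statistic. The empirical p-value uses the
add-one tail correction and is therefore never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["AssociationResult", "association_test"]

_CHUNK = 4096


@dataclass
class AssociationResult:
    subset_terms: list[str]
    m: int
    statistic: float
    null_draws: np.ndarray
    empirical_p: float
    seed: int


def association_test(
    pool: Mapping[str, float] | pd.Series,
    designated: Sequence[str],
    n_draws: int = 100_000,
    seed: int = 0,
    with_replacement: bool = False,
    zero_floor: float | None = None,
) -> AssociationResult:
    """Test a designated term subset against random drawings from the pool.

    Parameters
    ----------
    pool
        term id -> enrichment p-value (the full sweep, raw p not FDR).
    designated
        Term ids of interest; only those present in the pool enter the
        statistic (m = number found). Raises if none is present.
    n_draws
        Null draws; each samples m pool values uniformly, without
        replacement inside a draw unless *with_replacement*.
    zero_floor
        Floor applied to zero p-values before logs; a zero without a
        floor raises.
    """
    if isinstance(pool, pd.Series):
        pool = pool.to_dict()
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a stable empirical null")
    terms = sorted(pool)
    values = np.array([pool[t] for t in terms], dtype=float)
    if np.any(np.isnan(values)) or np.any((values < 0) | (values > 1)):
        raise ValueError("pool p-values must be in [0, 1] and non-NA")
    if np.any(values == 0.0):
        if zero_floor is None:
            raise ValueError("pool contains p = 0; set zero_floor to proceed")
        values = np.maximum(values, zero_floor)

    present = [t for t in designated if t in pool]
    missing = [t for t in designated if t not in pool]
    if not present:
        raise ValueError(f"no designated term found in the pool; missing: {missing}")
    m = len(present)
    neglog = -2.0 * np.log(values)
    index = {t: i for i, t in enumerate(terms)}
    observed = float(neglog[[index[t] for t in present]].sum())

    rng = np.random.default_rng(seed)
    n_pool = len(terms)
    if m > n_pool:
        raise ValueError("designated subset larger than the pool")
    null = np.empty(n_draws)
    if with_replacement:
        idx = rng.integers(0, n_pool, size=(n_draws, m))
        null[:] = neglog[idx].sum(axis=1)
    elif m == n_pool:
        # every without-replacement draw is the whole pool
        null[:] = neglog.sum()
    else:
        # without-replacement draws, chunked: the m smallest random keys
        # per row index a uniform m-subset of the pool
        done = 0
        while done < n_draws:
            chunk = min(_CHUNK, n_draws - done)
            keys = rng.random((chunk, n_pool))
            sub = np.argpartition(keys, m - 1, axis=1)[:, :m]
            null[done : done + chunk] = neglog[sub].sum(axis=1)
            done += chunk
    empirical_p = (1 + int(np.sum(null >= observed))) / (1 + n_draws)
    return AssociationResult(
        subset_terms=present,
        m=m,
        statistic=observed,
        null_draws=null,
        empirical_p=empirical_p,
        seed=seed,
    )
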