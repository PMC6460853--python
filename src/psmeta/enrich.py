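"""Gene-set enrichment of positively selected genes.

Three testing modes:

* :func:`exact_enrichment` — one-sided hypergeometric (Fisher's exact)
  over-representation test for a single branch with one background
  universe.
* :func:`go_sweep` — exact test per GO term against an annotation map,
  with BH adjustment across the tested terms.
* :func:`resampled_enrichment` — Monte-Carlo null for enrichment across
  multiple branches that have *different* background universes, where a
  single exact test is not applicable. The observed statistic is the sum
  over branches of the overlap between that branch's selected genes and
  the target set; each resample redraws, for every branch, as many genes
  as were selected on it, uniformly without replacement from that
  branch's own background.

Empirical p-values use the add-one correction (1 + m) / (1 + n), so they
are never exactly zero and remain usable inside downstream log-based
combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import invert_annotation
from .fdr import bh_adjust

__all__ = [
    "EnrichmentResult",
    "NullDistribution",
    "exact_enrichment",
    "go_sweep",
    "resampled_enrichment",
]

RESAMPLE_WARN_THRESHOLD = 1000


@dataclass
class EnrichmentResult:
    """Contingency counts and one-sided over-representation p-value."""

    set_name: str
    k_hit: int          # selected genes inside the target set
    k_sel: int          # selected genes
    K_set: int          # target-set genes within the background
    N_bg: int           # background universe size
    p: float
    method: str         # "exact" | "resampled"
    n_resamples: int | None = None


@dataclass
class NullDistribution:
    """Monte-Carlo draws of the enrichment statistic under the null."""

    draws: np.ndarray
    seed: int
    observed: float

    @property
    def empirical_p(self) -> float:
        return (1 + int(np.sum(self.draws >= self.observed))) / (1 + len(self.draws))


def exact_enrichment(selected: set, target: set, background: set, set_name: str = "target") -> EnrichmentResult:
    """One-sided hypergeometric over-representation test.

    The target set is intersected with the background before testing; the
    p-value is the upper tail P(X >= k_hit) for
    X ~ Hypergeom(N_bg, K_set, k_sel). k_hit = 0 gives p = 1 exactly.
    """
    if not background:
        raise ValueError("background universe is empty")
    if not set(selected) <= set(background):
        stray = sorted(set(selected) - set(background))[:3]
        raise ValueError(f"selected genes outside the background, e.g. {stray}")
    target_in_bg = set(target) & set(background)
    k_sel = len(selected)
    K_set = len(target_in_bg)
    N_bg = len(background)
    k_hit = len(set(selected) & target_in_bg)
    # sf(k-1) is the inclusive upper tail P(X >= k)
    p = float(stats.hypergeom.sf(k_hit - 1, N_bg, K_set, k_sel))
    return EnrichmentResult(set_name, k_hit, k_sel, K_set, N_bg, min(p, 1.0), "exact")


def go_sweep(
    selected: set,
    go_map: Mapping[str, set],
    background: set,
    min_set_size: int = 5,
    annotated_only: bool = False,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Exact enrichment test for every sufficiently large GO term.

    Parameters
    ----------
    selected, background
        Selected genes and the gene universe they were drawn from.
    go_map
        gene -> set of term ids (duplicated annotations are harmless:
        term membership is a set).
    min_set_size
        Terms with fewer background genes are skipped.
    annotated_only
        Restrict the background (and selected set) to genes carrying at
        least one annotation before testing.

    Returns a table sorted by (fdr, p) with a strict ``fdr <
    fdr_threshold`` significance flag; empty (with a warning) when no
    term is testable.
    """
    background = set(background)
    selected = set(selected)
    if annotated_only:
        annotated = {g for g, ts in go_map.items() if ts}
        background &= annotated
        selected &= annotated
    term_genes = invert_annotation(go_map)
    rows = []
    for term in sorted(term_genes):
        genes_in_bg = term_genes[term] & background
        if len(genes_in_bg) < min_set_size:
            continue
        res = exact_enrichment(selected, genes_in_bg, background, set_name=term)
        rows.append(res)
    if not rows:
        import warnings

        warnings.warn("no GO term passed min_set_size; empty sweep", stacklevel=2)
        return pd.DataFrame(
            columns=["term", "k_hit", "k_sel", "K_set", "N_bg", "p", "fdr", "significant"]
        )
    table = pd.DataFrame(
        {
            "term": [r.set_name for r in rows],
            "k_hit": [r.k_hit for r in rows],
            "k_sel": [r.k_sel for r in rows],
            "K_set": [r.K_set for r in rows],
            "N_bg": [r.N_bg for r in rows],
            "p": [r.p for r in rows],
        }
    )
    table["fdr"] = bh_adjust(table["p"].to_numpy()).fdr
    table["significant"] = table["fdr"] < fdr_threshold
    table = table.sort_values(["fdr", "p"], kind="stable").reset_index(drop=True)
    return table


def _overlap_statistic(per_branch_selected: Mapping[str, set], backgrounds: Mapping[str, set], target: set, distinct_union: bool) -> float:
    if distinct_union:
        union: set = set()
        for b, sel in per_branch_selected.items():
            union |= set(sel) & target & set(backgrounds[b])
        return float(len(union))
    return float(
        sum(len(set(sel) & target & set(backgrounds[b])) for b, sel in per_branch_selected.items())
    )


def resampled_enrichment(
    per_branch_selected: Mapping[str, set],
    backgrounds: Mapping[str, set],
    target: set,
    n_resamples: int = 100_000,
    seed: int = 0,
    distinct_union: bool = False,
) -> tuple[EnrichmentResult, NullDistribution]:
    """Resampling enrichment test across branches with distinct backgrounds.

    For each branch b the null redraws ``|selected_b|`` genes uniformly
    without replacement from ``background_b``. The default statistic sums
    per-branch target overlaps (a gene selected on two branches counts
    twice — the per-branch draw is the exchangeable unit);
    ``distinct_union=True`` instead counts distinct target genes in the
    union of the redrawn sets.

    The p-value is the add-one empirical tail (1 + #{null >= observed}) /
    (1 + n_resamples); *seed* fully determines the draw sequence.
    """
    import warnings

    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if n_resamples < RESAMPLE_WARN_THRESHOLD:
        warnings.warn(
            f"n_resamples={n_resamples} gives an unstable empirical p; "
            f"use >= {RESAMPLE_WARN_THRESHOLD}",
            stacklevel=2,
        )
    target = set(target)
    branches = sorted(per_branch_selected)
    for b in branches:
        bg = set(backgrounds[b])
        if not bg:
            raise ValueError(f"branch {b!r} has an empty background")
        if not set(per_branch_selected[b]) <= bg:
            raise ValueError(f"selected genes of branch {b!r} are not all in its background")

    observed = _overlap_statistic(per_branch_selected, backgrounds, target, distinct_union)
    rng = np.random.default_rng(seed)

    if not distinct_union:
        # Per-branch overlap counts under uniform without-replacement draws
        # are exactly hypergeometric; the sum statistic needs only the
        # counts, so each branch contributes a vectorised hypergeometric
        # sample of length n_resamples.
        draws = np.zeros(n_resamples, dtype=np.int64)
        for b in branches:
            bg = set(backgrounds[b])
            N = len(bg)
            K = len(target & bg)
            n = len(per_branch_selected[b])
            if n == 0 or K == 0:
                continue
            draws += rng.hypergeometric(K, N - K, n, size=n_resamples)
        null = draws.astype(float)
    else:
        # The union statistic depends on *which* target genes are drawn,
        # so draw the target-gene identities: per branch, the number of
        # target genes drawn is hypergeometric and the identities are a
        # uniform subset of the branch's target genes.
        branch_targets = {b: sorted(target & set(backgrounds[b])) for b in branches}
        counts = {}
        for b in branches:
            bg = set(backgrounds[b])
            N, K, n = len(bg), len(branch_targets[b]), len(per_branch_selected[b])
            counts[b] = (
                rng.hypergeometric(K, N - K, n, size=n_resamples)
                if (K and n)
                else np.zeros(n_resamples, dtype=np.int64)
            )
        null = np.empty(n_resamples)
        for i in range(n_resamples):
            union: set = set()
            for b in branches:
                k = int(counts[b][i])
                if k:
                    tg = branch_targets[b]
                    idx = rng.choice(len(tg), size=k, replace=False)
                    union.update(tg[j] for j in idx)
            null[i] = len(union)

    dist = NullDistribution(draws=null, seed=seed, observed=observed)
    k_sel_total = sum(len(s) for s in per_branch_selected.values())
    result = EnrichmentResult(
        set_name="target",
        k_hit=int(observed),
        k_sel=k_sel_total,
        K_set=len(target),
        N_bg=len(set().union(*(set(backgrounds[b]) for b in branches))),
        p=dist.empirical_p,
        method="resampled",
        n_resamples=n_resamples,
    )
    return result, dist
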