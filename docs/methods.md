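# Methods

## Statistical model

### Two-level Fisher combination

Each gene g carries p-values p_{g,b} from branch-site positive-selection
tests on branches b. Branches are grouped into clades (e.g. one ancestral
branch, three killifish branches, eleven mole-rat branches). Within a
clade c, the gene's branch p-values are combined with Fisher's method:

    X²_{g,c} = −2 · Σ_b ln p_{g,b}   ~   χ² with 2·k_{g,c} df under H₀,

where k_{g,c} counts the retained values. Clade-level p-values are then
combined the same way across clades. Fisher's method assumes independence
of the combined p-values; branch-site tests on disjoint branches satisfy
this to the degree the underlying gene trees do (shared alignment errors
or tree misspecification would induce dependence the method ignores —
a known limitation of this design, not of the implementation).

Two exclusion rules apply before every combination:

* **NA** — the gene was never tested on that branch (missing ortholog,
  failed alignment). Dropping it is the only defensible choice: the gene
  contributes no evidence there.
* **p = 1.0 exactly** — upstream likelihood-ratio tests emit p = 1 when
  the LRT statistic is 0 (a boundary case), not as evidence *against*
  selection. Retaining such entries adds 0 to the statistic while adding
  2 df, mechanically diluting real signal. The default drops them; this
  is the rule that reproduces the packaged reference table (its two rows
  containing a 1.00E+00 entry only match at df = 4). A `keep_unit_p` flag
  retains them for sensitivity analysis.

With k = 1 retained value the combination returns that value exactly.
With k = 0 the result is NA, and the gene is excluded from the BH
universe (it was never tested, so it is not a hypothesis). p = 0 raises
rather than being silently floored, because ln 0 is undefined and a true
zero almost always signals an upstream encoding problem; an explicit
`zero_floor` (suggested 1e-300) is available.

### Benjamini–Hochberg step-up

The adjustment is computed explicitly from the largest rank downward,
FDR_n = p_n, FDR_i = min(p_i·n/i, FDR_{i+1}), and the result is mapped
back to input order. This form makes the well-known runs of tied adjusted
values an explicit consequence of the cascading minimum rather than an
implementation accident. Significance calls use strict `<` (thresholds:
0.05 for per-branch selection, 0.1 for meta-analysis p-values — both
configurable, never hard-coded outside the pipeline defaults). Stable
sorting plus the cascade guarantees tied raw p-values receive identical
adjusted values.

### Enrichment tests

*Single background*: one-sided over-representation only, upper tail
P(X ≥ k_hit) with X ~ Hypergeom(N_bg, K_set, k_sel); the target set is
intersected with the background first. Depletion is never tested — the
scientific question is enrichment.

*GO sweep*: one exact test per term with at least `min_set_size` (default
5) background genes, BH across tested terms, output sorted by (FDR, p).
Terms are flat annotation sets; there is no DAG propagation or
parent–child conditional testing. An `annotated_only` switch restricts
the universe to genes carrying at least one annotation, since which
universe is appropriate depends on how the upstream scan was filtered.

*Multi-branch resampling*: when branches have different testable-gene
universes no single 2×2 table exists. The observed statistic is
Σ_b |selected_b ∩ target ∩ background_b| — a gene selected on two
branches counts twice, because the per-branch draw is the exchangeable
unit under the null. Each resample draws |selected_b| genes uniformly
without replacement from background_b. For this sum statistic only the
per-branch overlap *counts* matter, and the count of target genes in a
uniform without-replacement draw is exactly hypergeometric, so the null
is sampled as independent per-branch hypergeometric variates (a
vectorised, distributionally exact realisation of the gene-level draw).
The alternative "distinct genes in the union" statistic
(`distinct_union=True`) depends on which genes are drawn, so there the
per-branch target-gene identities are drawn explicitly. Both statistics
are offered because the choice is genuinely open; the sum is the default
for its exchangeability rationale.

*Association test*: given the pool of per-term enrichment p-values (raw
p, not FDR — the statistic should aggregate evidence, not thresholded
calls) and a designated term list, the observed statistic is −2 Σ ln p
over the m designated terms found in the pool. The null is empirical:
each of n_draws (default 100,000) draws samples m pool values uniformly
*without replacement within the draw* — this matches "a random subset of
terms of the same size"; with-replacement sampling is available by flag.
The null fixes m at the number of designated terms actually present in
the pool, not at the length of the designated list.

All Monte-Carlo p-values use the add-one tail (1 + #{null ≥ obs}) /
(1 + n), so they are never 0 and remain finite under downstream log
transforms. Every resampling routine takes an integer seed that fully
determines the draw sequence (numpy `default_rng`); identical seed and
inputs give byte-identical null distributions.

## Synthetic-data generator

The generator works at the p-value level, where this pipeline's inference
begins; it does not simulate sequences, alignments or likelihood-ratio
tests. One dataset consists of:

* iid Uniform(0,1) null entries;
* a planted gene set (default 50 of 5,000 genes) whose entries on the
  branches of designated clades follow Beta(α, 1), α ∈ (0, 1] — a
  standard one-parameter skew toward small p-values (α = 1 is the
  uniform null; default α = 0.2, a moderate per-branch signal that
  becomes overwhelming after 15-branch combination);
* a point mass of exact 1.0 entries (default 2%), emulating degenerate
  LRT cases, applied before missingness;
* independent NA masking (default 10% per entry, optionally per clade),
  which also defines the per-branch background universes (a gene is in a
  branch's background iff it is non-NA there).

The default clade design (1, 3, 11 branches) mirrors a study layout of
one ancestral branch, three killifish branches and eleven mole-rat
branches. What passing tests on simulated data do **not** show: behaviour
under dependent branches (shared internal edges), non-uniform null
p-values from misspecified codon models, or informative (non-random)
missingness — all properties real scan output can have.

## Numerical and design choices

* Chi-square tails via `scipy.stats.chi2.sf`; hypergeometric tails via
  `scipy.stats.hypergeom.sf(k−1, N, K, n)`. Tests verify both against
  independent oracles (quadrature of the χ² density to 1e-10;
  big-rational tail enumeration across all background sizes ≤ 60).
* Result TSVs render floats as `%.2E` (three significant digits) and NA
  as a configurable token, so round-trips preserve printed precision and
  missingness exactly; byte determinism of outputs is tested.
* Calibration checks size their configurations so the discrete support
  of the resampling statistic is fine-grained (11 branches, ~1,200-gene
  backgrounds, 150 selected per branch), making a KS comparison against
  Uniform meaningful; with coarse support the add-one empirical p is
  conservative (super-uniform) by construction, which a KS test would
  flag as non-uniformity even though type-I error control holds.
* Power and calibration thresholds in the test suite were fixed once
  after a pilot run and then frozen with fixed seeds, keeping the suite
  deterministic. Study sizes (100 power replicates at 5,000 genes;
  200–300 calibration replicates) were chosen as the smallest giving
  stable fractions.

## Limitations

* Independence across combined p-values is assumed, never estimated; no
  Stouffer/weighted or dependence-adjusted combination is provided.
* GO annotations are flat sets; conditional (parent–child) enrichment is
  out of scope.
* The package consumes p-value tables; it does not parse raw selection-
  scan output, resolve orthology, or estimate selection parameters
  (dN/dS, site posteriors).
* Only BH FDR is implemented; no BY or q-value variants.
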