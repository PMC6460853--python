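"""Synthetic data: plant a selection signal and recover it end to end.

Simulates a p-value matrix over three clades (1 + 3 + 11 branches,
mirroring an LCA / killifish / mole-rat design) with Beta(0.2, 1)
signal in 50 of 5,000 genes, NA missingness and a point mass of exact
1.0 entries, then runs combine -> enrichment and tests the planted set.
"""

from psmeta import (
    SimulationConfig,
    combine_across_clades,
    combine_within_clade,
    exact_enrichment,
    simulate,
)

sim = simulate(SimulationConfig(seed=1))
m = sim.matrix
print(f"simulated {len(m.genes)} genes x {len(m.branches)} branches; "
      f"{len(sim.planted_genes)} planted")

clade_matrix = combine_within_clade(m, sim.clades)
meta = combine_across_clades(clade_matrix, fdr_threshold=0.1)
background = set(meta.loc[meta["combined_p"].notna(), "gene"])
selected = set(meta.loc[meta["significant"], "gene"]) & background
print(f"meta-analysis: {len(selected)} genes at FDR < 0.1 "
      f"(of {len(background)} combinable)")

res = exact_enrichment(selected, sim.planted_genes, background)
recovered = len(selected & sim.planted_genes)
print(f"planted-set enrichment: {res.k_hit}/{res.k_sel} selected genes are "
      f"planted, p = {res.p:.3E}")
print(f"recovered {recovered}/{len(sim.planted_genes)} planted genes")
print("\nwith this effect size the planted set is recovered essentially "
      "completely and its enrichment p-value is vanishingly small.")
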