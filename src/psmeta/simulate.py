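"""Synthetic p-value matrices with the structure the pipeline assumes.

The generator works at the p-value level, where the downstream inference
begins — it does not simulate codon alignments or likelihood-ratio tests.
Its components mirror the features of real branch-site scan output:

* null entries iid Uniform(0, 1);
* a planted gene set whose entries on designated clades follow
  Beta(alpha, 1) with alpha <= 1, a one-parameter skew toward small
  p-values (alpha = 1 recovers the uniform null);
* a point mass of entries forced to exactly 1.0, emulating degenerate
  likelihood-ratio cases where the test statistic is 0;
* independent NA masking, emulating genes untestable on a branch
  (missing orthologs, failed alignments), which also defines the
  per-branch background universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CladeMap, GeneSetCollection, PValueMatrix, ValidationError

__all__ = ["SimulationConfig", "SimulatedData", "simulate", "published_clade_table"]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    clades
        List of (clade name, number of branches). Default (1, 3, 11)
        mirrors a study design of one LCA branch, three killifish
        branches and eleven mole-rat branches.
    effect_alpha
        Beta(alpha, 1) shape for planted entries, in (0, 1]; smaller is
        stronger signal. 1.0 means no signal (Beta(1,1) = Uniform).
    na_rate
        Per-entry missingness probability, scalar or per-clade mapping.
    unit_mass
        Probability an entry is forced to exactly 1.0 (applied to null
        and planted entries alike, before NA masking).
    """

    n_genes: int = 5000
    clades: list[tuple[str, int]] = field(
        default_factory=lambda: [("lca", 1), ("killifish", 3), ("molerat", 11)]
    )
    planted_set_size: int = 50
    planted_clades: list[str] | None = None  # None = all clades
    effect_alpha: float = 0.2
    na_rate: float | dict[str, float] = 0.1
    unit_mass: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_set_size > self.n_genes:
            raise ValidationError("planted_set_size exceeds n_genes")
        if not 0 < self.effect_alpha <= 1:
            raise ValidationError("effect_alpha must lie in (0, 1]")
        if not 0 <= self.unit_mass < 1:
            raise ValidationError("unit_mass must lie in [0, 1)")
        rates = (
            self.na_rate.values() if isinstance(self.na_rate, dict) else [self.na_rate]
        )
        if any(not 0 <= r < 1 for r in rates):
            raise ValidationError("na_rate must lie in [0, 1)")
        names = [c for c, _ in self.clades]
        if len(set(names)) != len(names):
            raise ValidationError("clade names must be unique")
        if self.planted_clades is not None:
            unknown = set(self.planted_clades) - set(names)
            if unknown:
                raise ValidationError(f"unknown planted clades: {sorted(unknown)}")


@dataclass
class SimulatedData:
    matrix: PValueMatrix
    clades: CladeMap
    gene_sets: GeneSetCollection
    planted_genes: set[str]


def simulate(config: SimulationConfig) -> SimulatedData:
    """Generate one synthetic dataset; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    clade_branches = {
        name: [f"{name}_b{j}" for j in range(n)] for name, n in config.clades
    }
    branches = [b for bs in clade_branches.values() for b in bs]
    branch_clade = {b: c for c, bs in clade_branches.items() for b in bs}
    planted_clades = (
        set(config.planted_clades)
        if config.planted_clades is not None
        else {c for c, _ in config.clades}
    )

    values = rng.uniform(size=(config.n_genes, len(branches)))
    planted_idx = rng.choice(config.n_genes, size=config.planted_set_size, replace=False)
    planted = {genes[i] for i in planted_idx}
    for j, b in enumerate(branches):
        clade = branch_clade[b]
        if clade in planted_clades and config.effect_alpha < 1:
            values[planted_idx, j] = rng.beta(
                config.effect_alpha, 1.0, size=len(planted_idx)
            )
    if config.unit_mass > 0:
        unit = rng.uniform(size=values.shape) < config.unit_mass
        values[unit] = 1.0
    for j, b in enumerate(branches):
        clade = branch_clade[b]
        rate = (
            config.na_rate.get(clade, 0.0)
            if isinstance(config.na_rate, dict)
            else config.na_rate
        )
        if rate > 0:
            mask = rng.uniform(size=config.n_genes) < rate
            values[mask, j] = np.nan

    df = pd.DataFrame(values, index=genes, columns=branches)
    df.index.name = "gene"
    matrix = PValueMatrix(df)
    backgrounds = {b: matrix.branch_background(b) for b in branches}
    clade_map = CladeMap(clade_branches, backgrounds)
    # a size-matched random control set, disjoint in expectation, for
    # specificity checks alongside the planted set
    control_idx = rng.choice(config.n_genes, size=config.planted_set_size, replace=False)
    gene_sets = GeneSetCollection(
        {
            "planted": set(planted),
            "random_control": {genes[i] for i in control_idx},
        },
        {"planted": "genes carrying simulated selection signal",
         "random_control": "size-matched random control set"},
    )
    return SimulatedData(matrix, clade_map, gene_sets, planted)


def published_clade_table() -> PValueMatrix:
    """The packaged 7-gene x 3-clade matrix of published branch-level p-values.

    Rows are the seven mitochondrial-biogenesis genes (MTERF1 ... NDUFA9)
    with clade-level p-values for the clownfish LCA, the Nothobranchius
    branches, and the mole-rat branches, exactly as printed (NA where the
    gene could not be tested).
    """
    ref = resources.files("psmeta").joinpath("data/published_clade_pvalues.tsv")
    with resources.as_file(ref) as path:
        from .io import read_pvalue_table

        return read_pvalue_table(Path(path))
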