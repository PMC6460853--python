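"""Core in-memory containers for downstream selection-scan analysis.

The whole pipeline operates on three objects: a genes x branches matrix of
branch-site test p-values (with explicit missingness for genes that could
not be tested on a branch), a grouping of branches into evolutionary clades
together with per-branch background gene universes, and a collection of
named gene sets (GMT-backed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["PValueMatrix", "CladeMap", "GeneSetCollection", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class PValueMatrix:
    """Genes x branches matrix of p-values in [0, 1], NaN marking untestable cells.

    Wraps a float DataFrame whose index is the gene universe and whose
    columns are branch (or clade) identifiers. Construction validates that
    identifiers are unique and every finite entry lies in [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("PValueMatrix wraps a pandas DataFrame")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate branch identifiers: {dups}")
        df = df.astype(float)
        vals = df.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            gi, bi = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValidationError(
                f"p-value out of [0, 1] for gene {df.index[gi]!r}, "
                f"branch {df.columns[bi]!r}: {vals[gi, bi]}"
            )
        self.data = df

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def branches(self) -> list[str]:
        return list(self.data.columns)

    def branch_background(self, branch: str) -> set[str]:
        """Genes testable (non-NA) on *branch* — its background universe."""
        col = self.data[branch]
        return set(col.index[col.notna()])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PValueMatrix({len(self.genes)} genes x {len(self.branches)} branches)"


@dataclass
class CladeMap:
    """Assignment of branches to clades, plus optional per-branch backgrounds.

    Every branch belongs to exactly one clade. ``backgrounds`` maps a branch
    to the set of genes testable on it; when omitted it can be derived from
    the p-value matrix (non-NA entries).
    """

    clades: dict[str, list[str]]
    backgrounds: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for clade, branches in self.clades.items():
            if not branches:
                raise ValidationError(f"clade {clade!r} has no branches")
            for b in branches:
                if b in seen:
                    raise ValidationError(
                        f"branch {b!r} assigned to both {seen[b]!r} and {clade!r}"
                    )
                seen[b] = clade
        self._branch_to_clade = seen

    @property
    def branches(self) -> list[str]:
        return [b for bs in self.clades.values() for b in bs]

    def clade_of(self, branch: str) -> str:
        try:
            return self._branch_to_clade[branch]
        except KeyError:
            raise KeyError(f"branch {branch!r} not assigned to any clade") from None

    def validate_against(self, matrix: PValueMatrix) -> None:
        """Check every matrix branch is assigned and backgrounds are subsets."""
        unknown = [b for b in matrix.branches if b not in self._branch_to_clade]
        if unknown:
            raise ValidationError(f"matrix branches without clade assignment: {unknown}")
        universe = set(matrix.genes)
        for branch, bg in self.backgrounds.items():
            extra = bg - universe
            if extra:
                raise ValidationError(
                    f"background of branch {branch!r} contains genes outside "
                    f"the matrix universe, e.g. {sorted(extra)[:3]}"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets; names unique, sets non-empty.

    ``descriptions`` preserves the GMT description field for round-trips.
    """

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def union(self, names: Iterable[str] | None = None) -> set[str]:
        """Union of the named sets (all sets when *names* is None).

        This mirrors how a composite functional gene set is built from
        several GO terms, e.g. the mitochondrial-biogenesis set used for
        the enrichment tests.
        """
        picked = self.names() if names is None else list(names)
        out: set[str] = set()
        for n in picked:
            out |= self.sets[n]
        return out


def invert_annotation(go_map: Mapping[str, set[str]]) -> dict[str, set[str]]:
    """Invert a gene -> terms mapping into term -> genes."""
    inv: dict[str, set[str]] = {}
    for gene, terms in go_map.items():
        for t in terms:
            inv.setdefault(t, set()).add(gene)
    return inv
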