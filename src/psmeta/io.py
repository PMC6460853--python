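"""Readers and writers for the pipeline's external file formats.

Formats are deliberately plain: tab-separated p-value matrices (header row
``gene`` + branch ids), standard GMT gene-set files, two-column gene->GO
annotation TSVs, a small YAML document for the clade map, and TSV result
tables rendered in scientific notation.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import CladeMap, GeneSetCollection, PValueMatrix, ValidationError

__all__ = [
    "read_pvalue_table",
    "write_pvalue_table",
    "read_gmt",
    "write_gmt",
    "read_go_map",
    "read_clade_map",
    "write_clade_map",
    "write_results",
]

_GO_ID = re.compile(r"^GO:\d{7}$")


def read_pvalue_table(path: str | Path, na_token: str = "NA", sep: str = "\t") -> PValueMatrix:
    """Read a genes x branches p-value table.

    First header column is the gene id; remaining columns are branch ids.
    Entries equal to *na_token* become NA. Raises on ragged rows, duplicate
    ids, or p-values outside [0, 1].
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValidationError(f"{path}: empty p-value table")
    lines = text.splitlines()
    header = lines[0].split(sep)
    ncol = len(header)
    if ncol < 2:
        raise ValidationError(f"{path}: header must name a gene column and >= 1 branch")
    branches = header[1:]
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(sep)
        if len(fields) != ncol:
            raise ValidationError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {ncol}"
            )
        genes.append(fields[0])
        row = []
        for branch, tok in zip(branches, fields[1:]):
            if tok == na_token or tok == "":
                row.append(np.nan)
            else:
                try:
                    row.append(float(tok))
                except ValueError:
                    raise ValidationError(
                        f"{path}: line {lineno}, branch {branch!r}: "
                        f"unparseable p-value {tok!r}"
                    ) from None
        rows.append(row)
    df = pd.DataFrame(rows, index=genes, columns=branches)
    df.index.name = header[0]
    return PValueMatrix(df)


def write_pvalue_table(
    path: str | Path, matrix: PValueMatrix, na_token: str = "NA", fmt: str = "%.2E"
) -> None:
    """Write a p-value matrix as TSV, NA cells rendered as *na_token*."""
    df = matrix.data
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in df.iterrows():
            cells = [na_token if pd.isna(v) else fmt % v for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, then gene ids)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}: line {lineno} has {len(fields)} fields; GMT requires "
                "name, description and >= 1 gene"
            )
        name, desc, genes = fields[0], fields[1], fields[2:]
        if name in sets:
            raise ValidationError(f"{path}: duplicate gene-set name {name!r} (line {lineno})")
        sets[name] = set(g for g in genes if g)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    """Write a GeneSetCollection as GMT; genes sorted for determinism."""
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>GO-term annotation file.

    Multiple rows per gene accumulate; duplicates deduplicate. A term id
    not of the form ``GO:`` + 7 digits triggers a warning but the row is
    kept verbatim (annotation sources vary in id style).
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ValidationError(
                f"{path}: line {lineno} has {len(fields)} fields, expected 2"
            )
        gene, term = fields
        if not _GO_ID.match(term):
            warnings.warn(
                f"{path}: line {lineno}: {term!r} is not a canonical GO id; keeping",
                stacklevel=2,
            )
        mapping.setdefault(gene, set()).add(term)
    return mapping


def read_clade_map(path: str | Path) -> CladeMap:
    """Read a YAML clade map: ``clades: {name: [branch, ...]}`` plus optional
    ``backgrounds: {branch: [gene, ...]}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "clades" not in doc:
        raise ValidationError(f"{path}: expected a mapping with a 'clades' key")
    backgrounds = {b: set(g) for b, g in doc.get("backgrounds", {}).items()}
    return CladeMap({c: list(bs) for c, bs in doc["clades"].items()}, backgrounds)


def write_clade_map(path: str | Path, clades: CladeMap) -> None:
    doc: dict = {"clades": {c: list(bs) for c, bs in clades.clades.items()}}
    if clades.backgrounds:
        doc["backgrounds"] = {b: sorted(g) for b, g in clades.backgrounds.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_results(path: str | Path, results: pd.DataFrame, na_token: str = "NA") -> None:
    """Write a result table as TSV with 3-significant-digit scientific notation.

    Column order is preserved; float cells are rendered ``%.2E`` (three
    significant digits) and missing values as *na_token*. Output is
    deterministic for fixed input.
    """

    def render(v) -> str:
        if pd.isna(v):
            return na_token
        if isinstance(v, (float, np.floating)):
            return "%.2E" % v
        if isinstance(v, (bool, np.bool_)):
            return str(bool(v))
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(map(str, results.columns)) + "\n")
        for _, row in results.iterrows():
            fh.write("\t".join(render(v) for v in row) + "\n")
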