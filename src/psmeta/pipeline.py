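"""End-to-end pipeline: combine -> enrich -> resample -> associate.

Mirrors the analysis workflow of a cross-clade positive-selection study:
branch-level p-values are combined within clades and then across clades
with Fisher's method, meta-significant genes are tested for target
gene-set enrichment (exact test on the shared background, resampling
test across branches with distinct backgrounds), a GO sweep and an
association test run when annotations are supplied.

Every filter step logs (input count, output count, threshold); the log
alone suffices to audit a run. A negative-control mode re-runs the same
machinery on signal-free input and is expected to report nothing.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_test
from .containers import CladeMap, GeneSetCollection, PValueMatrix
from .enrich import exact_enrichment, go_sweep, resampled_enrichment
from .fdr import bh_adjust
from .io import (
    read_clade_map,
    read_gmt,
    read_go_map,
    read_pvalue_table,
    write_pvalue_table,
    write_results,
)
from .meta import combine_across_clades, combine_within_clade
from .simulate import SimulationConfig, simulate

__all__ = ["run_all", "load_config"]

DEFAULTS: dict[str, Any] = {
    "branch_fdr": 0.05,
    "meta_fdr": 0.1,
    "n_resamples": 100_000,
    "n_draws": 100_000,
    "seed": 17,
    "keep_unit_p": False,
    "min_set_size": 5,
    "negative_control": False,
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = {**DEFAULTS, **cfg}
    return merged


def _resolve_inputs(cfg: dict[str, Any], log: list[str]) -> tuple[PValueMatrix, CladeMap, GeneSetCollection | None, set[str] | None]:
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", cfg["seed"])
        if "clades" in sim_kwargs:
            sim_kwargs["clades"] = [tuple(c) for c in sim_kwargs["clades"]]
        if cfg["negative_control"]:
            sim_kwargs["effect_alpha"] = 1.0
            log.append("negative control: simulated signal disabled (effect_alpha = 1)")
        sim = simulate(SimulationConfig(**sim_kwargs))
        return sim.matrix, sim.clades, sim.gene_sets, sim.planted_genes
    pv_key = "control_pvalues" if cfg["negative_control"] and "control_pvalues" in cfg else "pvalues"
    if pv_key == "control_pvalues":
        log.append(f"negative control: using control branch table {cfg[pv_key]}")
    for key in (pv_key, "clades"):
        if key not in cfg or not Path(cfg[key]).exists():
            raise FileNotFoundError(f"config key {key!r} missing or file not found")
    matrix = read_pvalue_table(cfg[pv_key])
    clades = read_clade_map(cfg["clades"])
    gene_sets = read_gmt(cfg["target_gmt"]) if "target_gmt" in cfg else None
    return matrix, clades, gene_sets, None


def run_all(config: dict[str, Any] | str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Run the full pipeline; returns the machine-readable summary.

    *config* is a YAML path or an already-merged dict (see DEFAULTS).
    Writes into *out_dir*: the clade-level matrix, the combined-p table,
    enrichment tables, the association report, a plain-text log and a
    JSON summary. Identical config and seeds give identical bytes.
    """
    cfg = load_config(config) if not isinstance(config, dict) else {**DEFAULTS, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"psmeta {__version__} (python {sys.version.split()[0]}, numpy {np.__version__})",
        f"seed: {cfg['seed']}",
    ]
    summary: dict[str, Any] = {"version": __version__, "seed": cfg["seed"]}

    matrix, clades, gene_sets, planted = _resolve_inputs(cfg, log)
    log.append(f"input: {len(matrix.genes)} genes x {len(matrix.branches)} branches")

    # stage 1: within-clade combination
    clade_matrix = combine_within_clade(matrix, clades, keep_unit_p=cfg["keep_unit_p"])
    write_pvalue_table(out / "clade_pvalues.tsv", clade_matrix)

    # stage 2: cross-clade meta-analysis + BH
    meta = combine_across_clades(
        clade_matrix, fdr_threshold=cfg["meta_fdr"], keep_unit_p=cfg["keep_unit_p"]
    )
    write_results(out / "meta_combined.tsv", meta)
    combinable = meta["combined_p"].notna()
    meta_selected = set(meta.loc[meta["significant"], "gene"])
    log.append(
        f"meta-analysis: {int(combinable.sum())}/{len(meta)} genes combinable; "
        f"{len(meta_selected)} significant at FDR < {cfg['meta_fdr']}"
    )
    summary["n_genes"] = len(meta)
    summary["n_combinable"] = int(combinable.sum())
    summary["n_meta_significant"] = len(meta_selected)

    # target gene set: named set or union of all sets in the collection
    target: set[str] | None = None
    if gene_sets is not None:
        name = cfg.get("target_set") or ("planted" if "simulate" in cfg else None)
        target = gene_sets[name] if name else gene_sets.union()

    if target is not None:
        background = set(meta.loc[combinable, "gene"])
        res = exact_enrichment(meta_selected, target, background, set_name="target")
        write_results(
            out / "enrichment_meta.tsv",
            pd.DataFrame(
                [
                    {
                        "set": res.set_name,
                        "k_hit": res.k_hit,
                        "k_sel": res.k_sel,
                        "K_set": res.K_set,
                        "N_bg": res.N_bg,
                        "p": res.p,
                        "method": res.method,
                    }
                ]
            ),
        )
        log.append(
            f"meta-set enrichment: {res.k_hit}/{res.k_sel} selected in target "
            f"(K={res.K_set}, N={res.N_bg}), p = {res.p:.3E}"
        )
        summary["meta_enrichment_p"] = res.p

        # stage 3: per-branch selection + resampling enrichment
        per_branch_selected: dict[str, set[str]] = {}
        backgrounds: dict[str, set[str]] = {}
        for b in matrix.branches:
            col = matrix.data[b].dropna()
            if col.empty:
                continue
            adj = bh_adjust(col.to_numpy())
            sel = set(col.index[adj.fdr < cfg["branch_fdr"]])
            per_branch_selected[b] = sel
            backgrounds[b] = clades.backgrounds.get(b) or set(col.index)
            log.append(
                f"branch {b}: {len(col)} testable -> {len(sel)} selected "
                f"at FDR < {cfg['branch_fdr']}"
            )
        res2, dist = resampled_enrichment(
            per_branch_selected,
            backgrounds,
            target,
            n_resamples=cfg["n_resamples"],
            seed=cfg["seed"],
        )
        write_results(
            out / "enrichment_resampled.tsv",
            pd.DataFrame(
                [
                    {
                        "set": res2.set_name,
                        "observed": dist.observed,
                        "null_mean": float(dist.draws.mean()),
                        "p": res2.p,
                        "n_resamples": res2.n_resamples,
                        "method": res2.method,
                    }
                ]
            ),
        )
        log.append(
            f"resampling enrichment: observed {dist.observed:.0f}, "
            f"null mean {dist.draws.mean():.2f}, p = {res2.p:.3E} "
            f"({cfg['n_resamples']} resamples)"
        )
        summary["resampled_enrichment_p"] = res2.p

    # stage 4: GO sweep + association (file-based runs with annotations)
    if "go_map" in cfg:
        go_map = read_go_map(cfg["go_map"])
        background = set(meta.loc[combinable, "gene"])
        sweep = go_sweep(
            meta_selected,
            go_map,
            background,
            min_set_size=cfg["min_set_size"],
            fdr_threshold=cfg["meta_fdr"],
        )
        write_results(out / "go_sweep.tsv", sweep)
        log.append(
            f"GO sweep: {len(sweep)} terms tested, "
            f"{int(sweep['significant'].sum()) if len(sweep) else 0} at FDR < {cfg['meta_fdr']}"
        )
        summary["n_go_terms_tested"] = len(sweep)
        summary["n_go_significant"] = int(sweep["significant"].sum()) if len(sweep) else 0
        if "designated_terms" in cfg and len(sweep):
            designated = [
                line.strip()
                for line in Path(cfg["designated_terms"]).read_text().splitlines()
                if line.strip()
            ]
            pool = dict(zip(sweep["term"], sweep["p"]))
            assoc = association_test(
                pool, designated, n_draws=cfg["n_draws"], seed=cfg["seed"]
            )
            write_results(
                out / "association.tsv",
                pd.DataFrame(
                    [
                        {
                            "m": assoc.m,
                            "statistic": assoc.statistic,
                            "empirical_p": assoc.empirical_p,
                            "n_draws": cfg["n_draws"],
                        }
                    ]
                ),
            )
            log.append(
                f"association: m = {assoc.m} designated terms, "
                f"statistic {assoc.statistic:.2f}, empirical p = {assoc.empirical_p:.3E}"
            )
            summary["association_p"] = assoc.empirical_p

    if planted is not None and target is not None:
        summary["planted_recovered"] = len(meta_selected & planted)
        log.append(f"planted-set recovery: {len(meta_selected & planted)}/{len(planted)}")

    (out / "run.log").write_text("\n".join(log) + "\n")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
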