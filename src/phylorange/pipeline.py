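"""End-to-end orchestration of the comparative analysis.

A pipeline run goes: inputs (synthetic or user-supplied) -> trait table ->
design -> collinearity screen -> BM and OU PGLS with likelihood-ratio
comparison -> partial-R^2 decomposition -> phylogenetically weighted
regression -> tabular outputs (``table1.tsv``, ``table2.tsv``,
``pwr_effects.tsv``, ``fit.json``) plus a run log.  Re-running with the same
configuration is bit-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import gls, niche, phylo, pwr, simulate
from .tables import read_table, write_table

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("phylorange")


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run (see ``examples/`` for YAML layouts)."""

    mode: str = "synthetic"  # {"synthetic", "user"}
    output_dir: str = "phylorange_out"
    # synthetic mode
    n_tips: int = 369
    seed: int = 0
    # user mode inputs
    tree: Optional[str] = None
    traits: Optional[str] = None
    occurrences: Optional[str] = None
    env_grid: Optional[str] = None
    grid_resolution: Optional[float] = None  # degrees
    host_tree: Optional[str] = None
    host_table: Optional[str] = None
    habitat_table: Optional[str] = None
    wingspan_table: Optional[str] = None
    dispersal_table: Optional[str] = None
    # analysis options
    cap: Optional[int] = 50
    n_replicates: int = 10
    pwr_bandwidth: object = "optimize"
    min_label_overlap: float = 0.9
    seeds: dict = field(default_factory=dict)  # per-stage overrides

    def stage_seed(self, stage: str) -> int:
        return int(self.seeds.get(stage, self.seed))


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def _reconcile_labels(tree, traits: pd.DataFrame, min_overlap: float):
    """Prune tree and table to their common species, aborting on poor overlap."""
    tree_labels = set(phylo.tip_labels(tree))
    table_labels = set(traits.index)
    common = tree_labels & table_labels
    overlap = len(common) / max(len(tree_labels), len(table_labels))
    if overlap < min_overlap:
        diff = sorted(tree_labels ^ table_labels)
        raise ValueError(
            f"tree/table label overlap {overlap:.0%} below {min_overlap:.0%}; "
            f"symmetric difference: {diff}"
        )
    dropped = sorted(tree_labels ^ table_labels)
    if dropped:
        log.warning("dropping %d species absent from tree or table: %s", len(dropped), dropped)
        tree = tree.extract_tree_with_taxa_labels(common)
    order = phylo.tip_labels(tree)
    return tree, traits.loc[order]


def compute_trait_table(config: PipelineConfig) -> pd.DataFrame:
    """Build the trait table from raw upstream inputs (user mode)."""
    occ = niche.clean_occurrences(read_table(config.occurrences))
    grid = read_table(config.env_grid)
    pca = niche.env_pca_project(grid, seed=config.stage_seed("pca"))
    res = config.grid_resolution or 5.0 / 60.0
    unconstrained = niche.climate_niche_breadth(
        occ, grid, pca, res, cap=None, seed=config.stage_seed("hypervolume")
    )
    traits = unconstrained[["climate_nb"]].copy()
    if config.cap is not None:
        capped = niche.climate_niche_breadth(
            occ, grid, pca, res, cap=config.cap,
            n_replicates=config.n_replicates, seed=config.stage_seed("hypervolume"),
        )
        traits = traits.join(capped.drop(columns=["imputed"]))
    host_tree = phylo.read_newick(config.host_tree)
    host_df = read_table(config.host_table)
    host_map = {sp: set(blk["genus"]) for sp, blk in host_df.groupby("species")}
    traits = traits.join(niche.diet_niche_breadth(host_map, host_tree))
    hab_df = read_table(config.habitat_table)
    hab_map = {sp: set(blk["habitat_type"]) for sp, blk in hab_df.groupby("species")}
    traits = traits.join(niche.habitat_niche_breadth(hab_map))
    traits = traits.join(niche.wingspan_index(read_table(config.wingspan_table)))
    disp = read_table(config.dispersal_table, index_col="species")
    traits = traits.join(disp["raw"].map(niche.dispersal_class).rename("dispersal_class"))
    range_df = read_table(config.traits, index_col="species")
    traits = traits.join(range_df[["range_size_km2"]])
    return traits


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all artifacts to ``config.output_dir``.

    Returns a result bundle with the trait table, fits, tables and PWR
    output.  Species ordering in every output is the tree's tip order.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    import phylorange

    log.info("phylorange %s; mode=%s; seed=%d", phylorange.__version__, config.mode, config.seed)
    log.info("seeds: %s", {s: config.stage_seed(s) for s in ("simulate", "pca", "hypervolume", "pwr")})

    if config.mode == "synthetic":
        sim = simulate.SimulationConfig(
            n_tips=config.n_tips, seed=config.stage_seed("simulate")
        )
        dataset = simulate.simulate_range_dataset(sim)
        tree, traits = dataset.tree, dataset.traits
        dataset.write(out / "tree.nwk", out / "trait_table.tsv", out / "truth.json")
        log.info("simulated dataset with %d tips", config.n_tips)
    elif config.mode == "user":
        if config.tree is None:
            raise ValueError("user mode requires a tree path")
        tree = phylo.read_newick(config.tree)
        if config.traits and config.occurrences is None:
            traits = read_table(config.traits, index_col="species")
        elif config.occurrences is not None:
            traits = compute_trait_table(config)
            write_table(traits, out / "trait_table.tsv", index_label="species")
        else:
            raise ValueError("user mode requires a trait table or full raw inputs")
        tree, traits = _reconcile_labels(tree, traits, config.min_label_overlap)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    phylo.scale_to_unit_height(tree)
    order = phylo.tip_labels(tree)
    traits = traits.loc[order]

    dm = design_mod.prepare_design(traits)
    screen = design_mod.collinearity_screen(dm)
    for _, row in screen[screen["flagged"]].iterrows():
        log.warning("collinear pair %s ~ %s (%s=%.2f)",
                    row["var1"], row["var2"], row["method"], row["coefficient"])

    D = phylo.patristic_distances(tree)
    fit_bm = gls.fit_pgls_ml(dm.y, dm.X, tree, model="BM")
    fit_ou = gls.fit_pgls_ml(dm.y, dm.X, tree, model="OU", distances=D.to_numpy())
    lrt = gls.likelihood_ratio_test(fit_bm, fit_ou)
    log.info("BM vs OU LRT: chi2=%.2f df=%d p=%.3g; alpha=%.3g",
             lrt["chi2"], lrt["df"], lrt["p"], fit_ou.alpha)

    table1 = gls.partial_r2_table(traits, tree, cap_mode="unconstrained")
    rep_cols = [c for c in traits.columns if c.startswith("climate_nb_rep")]
    table2 = gls.coefficient_table(fit_ou).drop(index="intercept", errors="ignore")
    constrained = {}
    if rep_cols:
        t1c = gls.partial_r2_table(traits, tree, cap_mode="constrained")
        table1 = table1.join(t1c.add_prefix("constrained_"))
        rep_fits = [
            gls.fit_pgls_ml(
                dmr.y, dmr.X, tree, model="OU", distances=D.to_numpy()
            )
            for dmr in (design_mod.prepare_design(traits, climate_column=c) for c in rep_cols)
        ]
        t2c = gls.average_replicate_fits(rep_fits)
        t2c.index = [gls.PRETTY.get(n, n) for n in t2c.index]
        table2 = table2.join(
            t2c.drop(index="intercept", errors="ignore").add_prefix("constrained_")
        )
        constrained = {"n_replicates": len(rep_cols)}
    write_table(table1, out / "table1.tsv", index_label="component")
    write_table(table2, out / "table2.tsv", index_label="component")

    pwr_X = dm.X.drop(columns=["intercept"])
    pwr_X.insert(0, "intercept", 1.0)
    result = pwr.pwr_fit(dm.y, pwr_X, D, bandwidth=config.pwr_bandwidth)
    effects = result.table.drop(
        columns=[c for c in result.table.columns if c.startswith("intercept")]
    )
    write_table(effects, out / "pwr_effects.tsv", index_label="species")
    counts = pwr.classify_effects(result).drop(index="intercept", errors="ignore")
    log.info("PWR bandwidth %.4g; effect counts:\n%s", result.bandwidth, counts)

    fit_info = {
        "model": "OU",
        "alpha": fit_ou.alpha,
        "sigma2": fit_ou.sigma2,
        "loglik_ou": fit_ou.loglik,
        "loglik_bm": fit_bm.loglik,
        "lrt": lrt,
        "pwr_bandwidth": result.bandwidth,
        "pwr_effect_counts": {k: counts.loc[k].to_dict() for k in counts.index},
        "n_species": len(order),
        "seeds": {s: config.stage_seed(s) for s in ("simulate", "pca", "hypervolume", "pwr")},
        **constrained,
    }
    with open(out / "fit.json", "w", encoding="utf-8") as fh:
        json.dump(fit_info, fh, indent=2, sort_keys=True)

    return {
        "tree": tree,
        "traits": traits,
        "design": dm,
        "screen": screen,
        "fit_bm": fit_bm,
        "fit_ou": fit_ou,
        "lrt": lrt,
        "table1": table1,
        "table2": table2,
        "pwr": result,
        "pwr_counts": counts,
    }
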