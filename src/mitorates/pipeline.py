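"""End-to-end orchestration: inputs -> category supermatrices -> ML branch
lengths -> rate tables -> group statistics -> gene-family reports.

The pipeline runs either on a synthetic study (generated in-process from a
:class:`~mitorates.simulate.SimulationConfig`) or on user-supplied files
(Newick chronogram, per-orthogroup FASTAs with ``species|gene_id`` headers,
species-metadata TSV, marker-list TSV, optional copy-number TSV).  Every
stage is a pure function of (inputs, config, seed); a JSON manifest with the
exact config and per-stage log accompanies the outputs so any table can be
reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from .alignment import ProteinAlignment
from .families import branch_change_summary, reconstruct_ancestral_counts, \
    run_group_contrasts
from .likelihood import select_model
from .models import poisson_model, read_paml_matrix
from .rates import build_rate_table
from .simulate import SimulationConfig, SpeciesMeta, default_config, \
    simulate_study
from .stats import category_correlations, kruskal_wallis_with_posthoc
from .trees import TimeTree
from .trim import trim_blocks

logger = logging.getLogger("mitorates")

__all__ = ["RunConfig", "RunResult", "PipelineStageError", "run_full_analysis"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration for one full run; defaults follow the
    package-wide conventions (block >= 6 / 50% conservation trimming, Poisson
    +F model with 4 gamma categories, 80% presence filter, alpha 0.05
    post hoc, 500-tree shadow-feature selection)."""

    mode: str = "synthetic"                 # "synthetic" | "files"
    simulation: SimulationConfig | None = None
    # files mode
    tree_path: str | None = None
    meta_path: str | None = None
    orthogroup_dir: str | None = None
    markers_path: str | None = None
    complex2_markers_path: str | None = None
    copy_numbers_path: str | None = None
    # analysis parameters
    min_fraction: float = 0.8               # background presence filter
    trim: bool = True
    min_block_len: int = 6
    conservation_threshold: float = 0.5
    allow_gaps: bool = True
    model_files: list[str] = field(default_factory=list)
    use_empirical_frequencies: bool = True
    n_gamma_categories: int = 4
    optimizer_tol: float = 1e-6
    optimizer_max_rounds: int = 20
    reference_category: str = "mtOXPHOS"
    posthoc_alpha: float = 0.05
    family_iterations: int = 30
    family_fwer: float = 0.01
    family_trees: int = 500
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")
        if self.mode == "files":
            missing = [
                n for n in ("tree_path", "meta_path", "orthogroup_dir",
                            "markers_path")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(f"files mode needs {', '.join(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            from .simulate import BiasSpec, CategorySpec

            cats = [CategorySpec(**c) for c in sim.pop("categories", [])]
            biased = [BiasSpec(**b) for b in sim.pop("biased_families", [])]
            cfg.simulation = SimulationConfig(
                categories=cats, biased_families=biased, **sim
            )
        return cfg


@dataclass
class RunResult:
    tree: TimeTree
    meta: SpeciesMeta
    category_map: cat.CategoryMap
    rate_table: pd.DataFrame
    model_tables: dict[str, pd.DataFrame]
    group_tests: pd.DataFrame
    correlations: pd.DataFrame
    family_decisions: dict[str, pd.DataFrame]
    branch_changes: pd.DataFrame | None
    manifest: dict[str, Any]


def _load_inputs(config: RunConfig):
    if config.mode == "synthetic":
        sim = config.simulation or default_config(config.seed)
        bundle = simulate_study(sim)
        groups = [g for gs in bundle.orthogroups.values() for g in gs]
        return (bundle.tree, bundle.meta, groups, bundle.marker_lists,
                bundle.complex2_markers, bundle.copy_numbers)
    tree = TimeTree.read_newick(config.tree_path)
    meta = SpeciesMeta.read_tsv(config.meta_path)
    groups = [
        cat.OrthologGroup.from_fasta(p)
        for p in sorted(Path(config.orthogroup_dir).glob("*.fasta"))
    ]
    mdf = pd.read_csv(config.markers_path, sep="\t")
    markers: dict[str, set[str]] = {}
    for _, row in mdf.iterrows():
        markers.setdefault(row["category"], set()).add(row["gene_id"])
    complex2: set[str] = set()
    if config.complex2_markers_path:
        complex2 = set(
            pd.read_csv(config.complex2_markers_path, sep="\t")["gene_id"]
        )
    copy_numbers = None
    if config.copy_numbers_path:
        copy_numbers = pd.read_csv(
            config.copy_numbers_path, sep="\t", index_col=0
        )
    return tree, meta, groups, markers, complex2, copy_numbers


def _category_alignment(groups, species, seed):
    blocks = []
    for g in groups:
        chosen = cat.resolve_paralogs(g, seed)
        blocks.append((g.group_id, {sp: r.sequence for sp, r in chosen.items()}))
    return cat.concatenate(blocks, species)


def run_full_analysis(config: RunConfig) -> RunResult:
    """Execute the full analysis; see the module docstring for the stages.

    Per-stage failures raise :class:`PipelineStageError` naming the stage;
    outputs written before the failure are left in place.
    """
    t_start = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    stage_log: list[dict[str, Any]] = []

    def run_stage(name, fn):
        t0 = time.time()
        logger.info("stage %s ...", name)
        try:
            out = fn()
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        stage_log.append({"stage": name, "seconds": round(time.time() - t0, 3)})
        return out

    seeds = np.random.SeedSequence(config.seed).spawn(3)
    paralog_seed = int(seeds[0].generate_state(1)[0] % (2**31 - 1))
    family_seed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))

    tree, meta, groups, markers, complex2, copy_numbers = run_stage(
        "inputs", lambda: _load_inputs(config)
    )
    species = tree.tip_labels

    def build_catalog():
        cmap = cat.assign_categories(groups, markers, complex2)
        by_id = {g.group_id: g for g in groups}
        if "nucControl" in cmap.categories:
            ok = cat.select_background(
                [by_id[i] for i in cmap.categories["nucControl"]], species,
                config.min_fraction,
            )
            cmap.categories["nucControl"] &= ok
        if "nucControlSingle" in cmap.categories:
            ok = cat.select_single_copy(
                [by_id[i] for i in cmap.categories["nucControlSingle"]], species
            )
            dropped = cmap.categories["nucControlSingle"] - ok
            if dropped:
                logger.info(
                    "nucControlSingle: %d group(s) not strictly single-copy "
                    "retained the filter's survivors only", len(dropped)
                )
            cmap.categories["nucControlSingle"] &= ok
        # derived complex-2 splits of nucOXPHOS (both need >= 1 gene)
        if cmap.complex2:
            nuc = cmap.categories.get("nucOXPHOS", set())
            c2 = cmap.complex2 & nuc
            rest = nuc - c2
            if c2 and rest:
                cmap.categories["nucOXPHOS_C2"] = c2
                cmap.categories["nucOXPHOS_noC2"] = rest
        return cmap

    cmap = run_stage("catalog", build_catalog)
    if outdir:
        cmap.write_tsv(outdir / "category_map.tsv")

    by_id = {g.group_id: g for g in groups}

    def build_matrices():
        out: dict[str, ProteinAlignment] = {}
        for name, gids in cmap.categories.items():
            if not gids:
                warnings.warn(f"category {name!r} is empty; skipped")
                continue
            glist = [by_id[i] for i in sorted(gids)]
            msa, blocks = _category_alignment(glist, species, paralog_seed)
            if config.trim:
                msa, _ = trim_blocks(
                    msa, config.min_block_len, config.conservation_threshold,
                    config.allow_gaps,
                )
            out[name] = msa
            if outdir:
                blocks.to_csv(outdir / f"blocks_{name}.tsv", sep="\t",
                              index=False)
        return out

    matrices = run_stage("concatenate+trim", build_matrices)

    def fit_all():
        candidates = [
            poisson_model(alpha=1.0, n_categories=config.n_gamma_categories)
        ] + [
            read_paml_matrix(p, n_categories=config.n_gamma_categories)
            for p in config.model_files
        ]
        trees, tables = {}, {}
        for name, msa in matrices.items():
            model, table, fitted = select_model(
                msa, tree, candidates,
                use_empirical_frequencies=config.use_empirical_frequencies,
                tol=config.optimizer_tol,
                max_rounds=config.optimizer_max_rounds,
            )
            trees[name] = fitted
            tables[name] = table
            logger.info("category %s: model %s logL %.2f", name, model.name,
                        fitted.log_likelihood)
            if outdir:
                fitted.write_newick(outdir / f"tree_{name}.nwk")
        return trees, tables

    category_trees, model_tables = run_stage("fit", fit_all)

    rate_table = run_stage(
        "rates", lambda: build_rate_table(category_trees, tree, meta)
    )
    if outdir:
        rate_table.to_csv(outdir / "rate_table.tsv", sep="\t", index=False)

    def group_stats():
        # both rate types are reported: terminal rates give a calibrated rank
        # test (disjoint branches), root-to-tip rates mirror the descriptive
        # whole-history comparison but are non-independent across species
        rows = []
        for name in matrices:
            sub = rate_table[rate_table["category"] == name]
            for rate_type in ("terminal_rate", "root_to_tip_rate"):
                by_group = {
                    g: s[rate_type].to_numpy()
                    for g, s in sub.groupby("group")
                    if len(s) > 0
                }
                if len(by_group) < 2:
                    continue
                res = kruskal_wallis_with_posthoc(by_group,
                                                  config.posthoc_alpha)
                for _, pr in res.posthoc.iterrows():
                    rows.append(
                        {"category": name, "rate_type": rate_type,
                         "H": res.H, "p_value": res.p_value,
                         "group_a": pr["group_a"], "group_b": pr["group_b"],
                         "pair_significant": pr["significant"]}
                    )
        return pd.DataFrame(rows)

    group_tests = run_stage("stats:groups", group_stats)
    if outdir:
        group_tests.to_csv(outdir / "group_tests.tsv", sep="\t", index=False)

    def correlations():
        if config.reference_category not in matrices:
            return pd.DataFrame()
        return category_correlations(rate_table, config.reference_category)

    corr = run_stage("stats:correlations", correlations)
    if outdir and len(corr):
        corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)

    def families_stage():
        if copy_numbers is None or len(copy_numbers) == 0:
            logger.info("no copy-number matrix supplied; gene-family stages "
                        "skipped")
            return {}, None
        decisions = run_group_contrasts(
            copy_numbers, meta, n_iterations=config.family_iterations,
            fwer=config.family_fwer, seed=family_seed,
            n_trees=config.family_trees,
        )
        frames = {k: d.to_frame() for k, d in decisions.items()}
        recs = {
            fid: reconstruct_ancestral_counts(
                copy_numbers.loc[fid].to_dict(), tree, family=fid
            )
            for fid in copy_numbers.index
        }
        changes = branch_change_summary(recs, tree, meta)
        if outdir:
            for k, f in frames.items():
                f.to_csv(outdir / f"families_{k}.tsv", sep="\t", index=False)
            changes.to_csv(outdir / "branch_changes.tsv", sep="\t", index=False)
        return frames, changes

    family_frames, branch_changes = run_stage("families", families_stage)

    manifest = {
        "config": _jsonable(dataclasses.asdict(config)),
        "seed": config.seed,
        "n_species": len(species),
        "categories": sorted(matrices),
        "stages": stage_log,
        "total_seconds": round(time.time() - t_start, 3),
    }
    if outdir:
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        tree.write_newick(outdir / "chronogram.nwk")
        meta.write_tsv(outdir / "species_meta.tsv")
    return RunResult(tree, meta, cmap, rate_table, model_tables, group_tests,
                     corr, family_frames, branch_changes, manifest)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
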