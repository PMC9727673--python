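"""End-to-end driver: simulate -> model -> features -> prioritize -> assess.

Each stage writes its canonical CSV outputs under the configured output
directory and the driver collects a manifest (file hashes, seed, headline
summary) so a run is reproducible bit-for-bit from its config + seed.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assess, io, phylo, prioritize, sdm
from .config import PipelineConfig
from .grid import PresenceMatrix
from .synthetic import SyntheticLandscape, simulate_landscape

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> SyntheticLandscape:
    land = simulate_landscape(cfg.simulation)
    io.write_grid(land.grid, outdir / "grid.csv")
    io.write_climate(land.climate, outdir / "climate_current.csv")
    io.write_climate(land.future_climate, outdir / "climate_future.csv")
    io.write_tree(land.tree, outdir / "tree.nwk")
    io.write_presences(land.presences, outdir / "presences.csv")
    io.write_layer(land.pa_fraction, outdir / "pa_fraction.csv", "pa_fraction")
    io.write_layer(land.hmi, outdir / "hmi.csv", "hmi")
    return land


def _stage_sdm(cfg: PipelineConfig, land: SyntheticLandscape, outdir: Path
               ) -> tuple[PresenceMatrix, PresenceMatrix, list[dict]]:
    presences = sdm.min_occurrence_filter(land.presences, cfg.min_occ)
    eval_rows, cur_rows, fut_rows = [], [], []
    cur_occ, fut_occ, kept = [], [], []
    rng = np.random.default_rng(cfg.seed)
    for sp in presences.species:
        sp_seed = int(rng.integers(2**31 - 1))
        res = sdm.model_species(
            sp, presences.cells_of(sp), land.climate, land.future_climate,
            land.grid, seed=sp_seed, n_repeats=cfg.n_repeats,
            train_frac=cfg.train_frac, min_tss=cfg.tss_min,
            absence_ratio=cfg.absence_ratio, buffer_km=cfg.buffer_km,
        )
        for ev in res.evaluations:
            eval_rows.append({
                "species": sp, "replicate": ev.replicate,
                "tss": round(ev.tss, 6), "threshold": round(ev.threshold, 6),
                "retained": ev.tss >= cfg.tss_min,
            })
        if not res.modellable:
            continue
        cur = np.zeros(land.grid.n_cells, dtype=bool)
        cur[list(res.current.cells)] = True
        fut = np.zeros(land.grid.n_cells, dtype=bool)
        fut[list(res.future[cfg.dispersal].cells)] = True
        cur_occ.append(cur)
        fut_occ.append(fut)
        kept.append(sp)
    n_unmod = presences.n_species - len(kept)
    if n_unmod:
        logger.info("sdm stage: %d species unmodellable (no TSS >= %.2f model)",
                    n_unmod, cfg.tss_min)
    pd.DataFrame(eval_rows).to_csv(outdir / "evaluations.csv", index=False)
    current = PresenceMatrix(np.array(cur_occ), kept)
    future = PresenceMatrix(np.array(fut_occ), kept)
    io.write_presences(current, outdir / "ranges_current.csv")
    io.write_presences(future, outdir / "ranges_future.csv")
    return current, future


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    land = _stage_simulate(cfg, outdir)
    current, future = _stage_sdm(cfg, land, outdir)

    # species kept by modelling but possibly with empty modelled ranges
    nonempty = [s for s in current.species
                if current.cells_of(s).size and future.cells_of(s).size]
    current, future = current.subset(nonempty), future.subset(nonempty)
    tree = land.tree.clone(depth=1)
    tree.retain_taxa_with_labels(nonempty)

    branches_cur = phylo.branch_occurrences(tree, current)
    branches_fut = phylo.branch_occurrences(tree, future)
    io.write_features(branches_cur, outdir / "branches_current.csv")
    io.write_features(branches_fut, outdir / "branches_future.csv")
    pd_cur = phylo.faith_pd_per_cell(tree, current)
    pd_fut = phylo.faith_pd_per_cell(tree, future)
    io.write_layer(pd_cur, outdir / "pd_current.csv", "pd")
    io.write_layer(pd_fut, outdir / "pd_future.csv", "pd")
    pd_classes = phylo.pd_quantile_classes(pd_cur)

    csh_records = [
        phylo.compute_csh(current.cells_of(s).size, future.cells_of(s).size,
                          unit_id=s, expand_threshold=cfg.csh_expand)
        for s in current.species
    ]
    csh_branch = [
        phylo.compute_csh(len(bc.cells), len(bf.cells), unit_id=bc.branch_id,
                          expand_threshold=cfg.csh_expand)
        for bc, bf in zip(branches_cur, branches_fut)
    ]

    protected = assess.protected_cells(land.pa_fraction, cfg.pa_cutoff)
    occ_cur, w_cur, ids_cur = phylo.branch_matrix(branches_cur, current.n_cells)
    occ_fut, w_fut, ids_fut = phylo.branch_matrix(branches_fut, future.n_cells)
    fs_cur = prioritize.FeatureSet(occ_cur, w_cur, feature_ids=ids_cur)
    fs_fut = prioritize.FeatureSet(occ_fut, w_fut, feature_ids=ids_fut)
    fs_masked = prioritize.FeatureSet(occ_cur, w_cur, feature_ids=ids_cur,
                                      mask=protected.astype(int))
    rank_cur, curves_cur = prioritize.run_prioritization(fs_cur, cfg.rule, cfg.seed)
    rank_fut, _ = prioritize.run_prioritization(fs_fut, cfg.rule, cfg.seed)
    rank_masked, _ = prioritize.run_prioritization(fs_masked, cfg.rule, cfg.seed)
    io.write_rank(rank_cur, outdir / "rank_current.csv")
    io.write_rank(rank_fut, outdir / "rank_future.csv")
    io.write_rank(rank_masked, outdir / "rank_masked.csv")
    io.write_curves(curves_cur, outdir / "curves_current.csv",
                    every=max(1, land.grid.n_cells // 100))

    prot_set = set(np.flatnonzero(protected).tolist())
    overlaps = {}
    priority_protection = {}
    for f in cfg.top_fractions:
        top_c = prioritize.top_fraction(rank_cur, f)
        top_f = prioritize.top_fraction(rank_fut, f)
        parts = prioritize.scenario_overlap(top_c, top_f)
        overlaps[f] = {k: len(v) for k, v in parts.items()}
        priority_protection[f] = len(top_c & prot_set) / len(top_c)

    gap_records = assess.gap_table(
        {s: set(current.cells_of(s).tolist()) for s in current.species},
        protected, cell_area=float(land.grid.area[0]),
        lower=cfg.target_lower_km2, upper=cfg.target_upper_km2,
        floor=cfg.target_floor,
    )
    gap_branches = assess.gap_table(
        branches_cur, protected, cell_area=float(land.grid.area[0]),
        lower=cfg.target_lower_km2, upper=cfg.target_upper_km2,
        floor=cfg.target_floor,
    )
    pd.DataFrame([r.__dict__ | {"kind": kind}
                  for kind, recs in (("species", gap_records),
                                     ("branch", gap_branches))
                  for r in recs]).to_csv(outdir / "gap_table.csv", index=False)

    expansion = assess.expansion_report(
        rank_masked, protected, branches_cur, pd_classes, cfg.add_fractions)
    hmi_groups = {}
    if cfg.add_fractions:
        exp_cells = expansion[cfg.add_fractions[0]]["expansion_cells"]
        non_pa = set(range(land.grid.n_cells)) - prot_set - exp_cells
        hmi_groups = assess.group_hmi_summary(
            land.hmi, {"existing_pa": prot_set, "expansion": exp_cells,
                       "non_pa": non_pa})

    novel = assess.aoa_novel_climate(land.climate, land.future_climate,
                                     cfg.aoa_quantile)
    io.write_layer(novel.astype(int), outdir / "aoa_novel.csv", "novel")

    def _share(records, label):
        return float(np.mean([r.label == label for r in records]))

    summary = {
        "seed": cfg.seed,
        "n_species_modelled": current.n_species,
        "n_branches": len(branches_cur),
        "protected_cell_share": float(protected.mean()),
        "mean_branch_coverage_baseline": assess.mean_branch_coverage(
            branches_cur, protected),
        "mean_branch_coverage_after": {
            str(a): expansion[a]["coverage_after"] for a in cfg.add_fractions},
        "gap_shares_species": {c: _share(gap_records, c)
                               for c in assess.GAP_CLASSES},
        "gap_shares_branches": {c: _share(gap_branches, c)
                                for c in assess.GAP_CLASSES},
        "csh_lost_share_species": _share(csh_records, "lost"),
        "csh_greatly_expanded_share_species": _share(csh_records,
                                                     "greatly_expanded"),
        "csh_lost_share_branches": _share(csh_branch, "lost"),
        "priority_overlap": {str(k): v for k, v in overlaps.items()},
        "priority_protection": {str(k): v for k, v in priority_protection.items()},
        "pd_class_protection": {str(k): v for k, v in
                                assess.pd_class_protection(pd_classes,
                                                           protected).items()},
        "hmi_groups": hmi_groups,
        "novel_climate_share": float(novel.mean()),
    }
    io.write_json(summary, outdir / "summary.json")

    files = sorted(p.name for p in outdir.iterdir() if p.is_file())
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "outputs": {name: _sha256(outdir / name) for name in files
                    if name != "manifest.json"},
        "summary": summary,
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
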