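"""End-to-end orchestration: simulate -> variance -> phenotypes -> scan ->
classify -> hotspot -> report.

A run is driven by one :class:`~plastiqtl.config.PipelineConfig` plus either
a simulation section or real-data file paths. Outputs are plain TSV/CSV/JSON
under one directory, together with a run manifest (config snapshot, seed,
input hashes, stage timings, output list) that makes reruns reproducible:
identical manifest inputs give bit-identical outputs. Each stage draws its
randomness from a seed derived by hashing the stage name with the global
seed, so re-running one stage never perturbs the others.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, hotspot, phenotypes as phen_mod, scan, simulate, variance
from .config import PipelineConfig
from .core_io import (FLOAT_FMT, ExpressionDataset, GeneticMap, GenotypeMatrix,
                      read_expression, read_genetic_map, read_genotypes,
                      write_expression, write_genetic_map, write_genotypes,
                      write_table)
from .simulate import PARENT_A_ID, PARENT_B_ID, ArchitectureConfig

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SimulationPlan:
    """Desk-scale defaults emulating the study population's structure:
    ~210 F8 lines on five chromosomes of 100/70/80/80/100 cM, two
    treatments x two replicates, with cis effects, a pleiotropic trans
    hotspot on chromosome 2 and opposing-sign plasticity pairs. Marker
    spacing is coarsened from the study's 0.17 cM to keep desk runs fast."""

    n_lines: int = 210
    n_transcripts: int = 300
    chromosome_lengths: tuple = (100.0, 70.0, 80.0, 80.0, 100.0)
    marker_spacing: float = 2.0
    n_replicates: int = 2
    architecture: ArchitectureConfig = dataclasses.field(
        default_factory=ArchitectureConfig)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir,
                 sim_plan: SimulationPlan | None = None,
                 map_path=None, geno_path=None, expr_path=None, meta_path=None,
                 gene_positions: pd.DataFrame | None = None,
                 paralogs: pd.DataFrame | None = None,
                 parent_ids=(PARENT_A_ID, PARENT_B_ID)) -> dict:
    """Execute every stage and write all outputs under ``outdir``.

    Returns the run manifest (also written as ``manifest.json``). In
    simulation mode the planted architecture is written as ground truth and
    gene positions come from the simulated transcript placement; in
    real-data mode ``gene_positions`` must carry transcript/chromosome/cM.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "warnings": [],
    }
    t_all = time.time()

    # ----- stage: inputs (simulate or load) --------------------------------
    t0 = time.time()
    if sim_plan is not None:
        gmap = simulate.make_map(list(sim_plan.chromosome_lengths),
                                 sim_plan.marker_spacing)
        geno = simulate.simulate_ril_genotypes(
            gmap, sim_plan.n_lines, config.stage_seed("genotypes"))
        arch = simulate.plant_architecture(
            gmap, sim_plan.n_transcripts, sim_plan.architecture,
            config.stage_seed("architecture"))
        dataset = simulate.simulate_expression(
            geno, arch, sim_plan.n_replicates,
            config.stage_seed("expression"), include_parents=True)
        gene_positions = arch.transcript_positions.rename(
            columns={"position_cM": "cM"})
        write_genetic_map(gmap, outdir / "map.csv")
        write_genotypes(geno, outdir / "genotypes.csv")
        write_expression(dataset, outdir / "expression.tsv",
                         outdir / "samples.tsv")
        arch.to_frame().to_csv(outdir / "planted_truth.tsv", sep="\t",
                               index=False, float_format=FLOAT_FMT)
        manifest["inputs"] = {"mode": "simulation",
                              "plan": _hash_obj(dataclasses.asdict(sim_plan))}
    else:
        gmap = read_genetic_map(map_path)
        geno = read_genotypes(geno_path, gmap, config.genotype_codes)
        dataset = read_expression(expr_path, meta_path)
        arch = None
        manifest["inputs"] = {
            "mode": "real",
            "hashes": {str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()
                       for p in (map_path, geno_path, expr_path, meta_path)},
        }
    if config.log_transform:
        dataset = ExpressionDataset(np.log2(dataset.values + 1.0),
                                    dataset.metadata)
    manifest["stages"]["inputs"] = round(time.time() - t0, 3)

    ril_ids = [g for g in dataset.genotypes if g not in parent_ids]
    has_parents = all(p in dataset.genotypes for p in parent_ids)

    # ----- stage: variance -------------------------------------------------
    t0 = time.time()
    groups = {"rils": dataset.subset_genotypes(ril_ids)}
    if has_parents:
        groups["parents"] = dataset.subset_genotypes(list(parent_ids))
    variance_summary = {}
    for name, sub in groups.items():
        decomp = variance.decompose_variance(sub)
        table = decomp.table.copy()
        usable = (~table["degenerate"]).sum()
        if usable >= config.kmeans_k:
            labels, _ = variance.cluster_variance_profiles(
                decomp, config.kmeans_k, config.stage_seed("kmeans"),
                config.kmeans_restarts)
            table["cluster"] = labels.reindex(table.index).astype("Int64")
        write_table(table, outdir / f"variance_{name}.tsv",
                    index_label="transcript")
        variance_summary[name] = variance.summarize_variance(decomp).to_dict()
    manifest["stages"]["variance"] = round(time.time() - t0, 3)

    # ----- stage: phenotypes ----------------------------------------------
    t0 = time.time()
    phen = phen_mod.build_phenotypes(dataset, floor=config.delta_floor)
    for name, table in phen.items():
        write_table(table, outdir / f"phenotype_{name}.tsv")
    scores, _, evr = phen_mod.pca_transcriptomes(phen.control.dropna())
    write_table(scores, outdir / "pca_scores_control.tsv")
    transgression = None
    if has_parents:
        transgression = phen_mod.transgression_summary(phen, parent_ids)
        write_table(transgression, outdir / "transgression.tsv",
                    index_label="transcript")
    manifest["stages"]["phenotypes"] = round(time.time() - t0, 3)

    # ----- stage: scan (RILs only, as in the mapping analysis) -------------
    t0 = time.time()
    probs = scan.genotype_probabilities(geno, gmap)
    ril_probs = probs.loc[[i for i in probs.index if i in set(ril_ids)]]
    ril_phen = phen_mod.PhenotypeSet(
        phen.control.loc[ril_probs.index.intersection(phen.control.index)],
        phen.SA.loc[ril_probs.index.intersection(phen.SA.index)],
        phen.delta.loc[ril_probs.index.intersection(phen.delta.index)])
    eqtl = scan.scan_all(ril_probs, ril_phen, gmap,
                         lod_threshold=config.lod_threshold,
                         min_peak_separation_cM=config.min_peak_separation_cM,
                         lod_cap=config.lod_cap, peak_drop=config.peak_drop_lod)
    eqtl.to_csv(outdir / "eqtl.tsv", sep="\t", index=False,
                float_format=FLOAT_FMT)
    manifest["stages"]["scan"] = round(time.time() - t0, 3)

    # ----- stage: classify -------------------------------------------------
    t0 = time.time()
    merged = classify.merge_all(eqtl, window=config.merge_window_cM)
    if gene_positions is not None:
        classify.attach_cis_trans(merged, gene_positions,
                                  window=config.cis_window_cM)
    classify.attach_effect_sizes(merged, ril_probs, ril_phen, gmap)
    manifest["stages"]["classify"] = round(time.time() - t0, 3)

    # ----- stage: hotspot --------------------------------------------------
    t0 = time.time()
    profiles = {}
    hotspot_rows, window_rows = [], []
    for phen_name in ("control", "SA", "delta"):
        positions = pd.DataFrame(
            [{"chromosome": m.chromosome, "position_cM": m.consensus_cM}
             for m in merged
             if m.cis_trans == "trans" and phen_name in m.membership])
        if positions.empty:
            positions = pd.DataFrame(columns=["chromosome", "position_cM"])
        prof = hotspot.hotspot_profile(
            positions, gmap, config.hotspot_window_cM, config.hotspot_step_cM,
            config.n_permutations, config.permutation_percentile,
            config.stage_seed(f"hotspot:{phen_name}"),
            config.permutation_marker_weighted)
        profiles[phen_name] = prof
        window_rows.append(prof.windows.assign(phenotype=phen_name))
        hotspot_rows.append(prof.intervals.assign(phenotype=phen_name))
    pd.concat(window_rows).to_csv(outdir / "hotspot_windows.tsv", sep="\t",
                                  index=False, float_format=FLOAT_FMT)
    nonempty = [f for f in hotspot_rows if not f.empty]
    intervals = (pd.concat(nonempty) if nonempty else
                 hotspot_rows[0])
    intervals.to_csv(outdir / "hotspot_intervals.tsv", sep="\t", index=False,
                     float_format=FLOAT_FMT)
    manifest["stages"]["hotspot"] = round(time.time() - t0, 3)

    # hotspot membership + paralog annotation against the called intervals
    regions = [(r["chromosome"], r["start"], r["end"])
               for _, r in intervals.iterrows()]
    classify.annotate_paralogs(merged, paralogs, regions,
                               config.paralog_window_cM,
                               config.hotspot_membership_window_cM)
    merged_frame = classify.merged_to_frame(merged)
    merged_frame.to_csv(outdir / "merged_eqtl.tsv", sep="\t", index=False,
                        float_format=FLOAT_FMT)

    # ----- report ----------------------------------------------------------
    summary = {
        "variance_mean_proportions": variance_summary,
        "pca_pc1_explained": float(evr[0]) if len(evr) else np.nan,
        "eqtl_counts": ({p: int((eqtl["phenotype"] == p).sum())
                         for p in ("control", "SA", "delta")}
                        if not eqtl.empty else
                        {"control": 0, "SA": 0, "delta": 0}),
        "cis_trans": (classify.summarize_cis_trans(merged) if merged
                      else {"overall": {"n_cis": 0, "n_trans": 0,
                                        "trans_proportion": float("nan")}}),
        "hotspots": {p: profiles[p].intervals.to_dict("records")
                     for p in profiles},
        "hotspot_thresholds": {p: profiles[p].threshold for p in profiles},
    }
    if transgression is not None:
        summary["mean_fraction_transgressive"] = {
            p: float(transgression[f"{p}_frac_outside"].mean())
            for p in ("control", "SA", "delta")}
    if merged:
        summary["paralog_by_effect_quartile"] = _paralog_by_quartile(merged_frame)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir()
                                 if p.name != "manifest.json")
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    manifest["manifest_hash"] = _hash_obj(
        {k: manifest[k] for k in ("config", "seed", "inputs")})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return {"manifest": manifest, "summary": summary, "eqtl": eqtl,
            "merged": merged, "profiles": profiles,
            "truth": arch, "map": gmap, "phenotypes": phen}


def _paralog_by_quartile(merged_frame: pd.DataFrame) -> dict:
    """Fraction of paralog-flagged eQTLs within each effect-size quartile."""
    placed = merged_frame[merged_frame["cis_trans"].isin(["cis", "trans"])]
    placed = placed.dropna(subset=["r2_mean"])
    if placed.empty:
        return {}
    quartile = pd.qcut(placed["r2_mean"].rank(method="first"), 4,
                       labels=["Q1", "Q2", "Q3", "Q4"])
    out = {}
    for q, sub in placed.groupby(quartile, observed=True):
        out[str(q)] = {"n": int(len(sub)),
                       "paralog_fraction": float(sub["paralog_flag"].mean()),
                       "mean_r2": float(sub["r2_mean"].mean())}
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
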