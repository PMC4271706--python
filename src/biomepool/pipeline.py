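"""End-to-end orchestration: data -> biogeography -> events -> climate -> PD.

The pipeline chains every stage of the species-pool analysis: obtain a dated
tree ensemble plus species ranges, climate occurrences (from files or the
synthetic generator), fit the biogeographic model (or use fixed parameters),
estimate marginal ancestral ranges per ensemble tree, extract dated
expansion/restriction events for the focal area, compute dispersal rates and
the rate inflection, reconstruct ancestral climate and classify evolutionary
lags for every restriction, estimate diversification rates, and partition the
focal region's phylogenetic diversity into in-situ vs dispersal components.

All randomness flows from one master seed through named per-stage substreams;
a fixed seed yields a byte-identical report (modulo timing fields).
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .biogeo import (
    BiogeoParams,
    EpochSchedule,
    RangeStateSpace,
    ancestral_ranges,
    compare_models,
    fit_biogeo,
    mask_from_areas,
)
from .climate import (
    DEFAULT_THRESHOLDS,
    ThresholdSpec,
    assign_groups,
    bm_ancestral_ml,
    lag_table,
    pgls_group_test,
    species_climate_means,
)
from .diversification import (
    compare_dispersal_vs_diversification,
    fit_bd,
    mpd_partition,
    scan_shifts,
)
from .events import (
    assign_introductions,
    dispersal_rate,
    extract_events,
    find_inflection,
    summarize_ensemble,
)
from .simulate import (
    SimulationConfig,
    make_tree_ensemble,
    simulate_bd_tree,
    simulate_bm_traits,
    simulate_occurrences,
    simulate_range_history,
)
from .trees import DatedTree, TreeEnsemble

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (generate data) or the input paths
    (``trees_path`` + ``ranges_path`` [+ ``occurrences_path``]) is active.
    """

    simulation: SimulationConfig | None = None
    trees_path: str | None = None
    ranges_path: str | None = None
    occurrences_path: str | None = None
    genus_totals_path: str | None = None

    focal_area: str = "Me"
    thresholds: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    age_convention: str = "stem"
    n_trees: int = 10
    age_jitter_sd: float = 0.05
    fit_models: tuple = ("DEC", "DEC+J")
    fixed_params: BiogeoParams | None = None
    sampling_fraction: float = 1.0
    run_shift_scan: bool = True
    pgls_max_trees: int = 10
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        sim_mode = self.simulation is not None
        file_mode = self.trees_path is not None
        if sim_mode == file_mode:
            raise ValueError("exactly one of simulation config or input "
                             "paths must be given")
        if file_mode and self.ranges_path is None:
            raise ValueError("file mode requires a ranges_path")


def validate_inputs(ensemble: TreeEnsemble, ranges: pd.DataFrame,
                    profile: pd.DataFrame | None = None) -> dict:
    """Tip-label concordance report across trees, range table, and climate
    profile.  Fatal (raises) when the label intersection is empty."""
    tree_labels = ensemble.tip_label_universe
    range_labels = set(ranges.index)
    report = {
        "n_tree_tips": len(tree_labels),
        "n_range_species": len(range_labels),
        "tree_not_in_ranges": sorted(tree_labels - range_labels),
        "ranges_not_in_tree": sorted(range_labels - tree_labels),
    }
    usable = tree_labels & range_labels
    if profile is not None:
        prof_labels = set(profile.index)
        report["tree_not_in_profile"] = sorted(tree_labels - prof_labels)
        report["n_profile_species"] = len(prof_labels)
    if not usable:
        raise ValueError("no species shared between trees and range table")
    report["n_usable"] = len(usable)
    return report


def _load_inputs(config: PipelineConfig):
    """Return (ensemble, ranges DF, occurrences DF|None, truth|None, schedule,
    space, areas)."""
    if config.simulation is not None:
        sim = config.simulation
        seed = config.seed
        tree = simulate_bd_tree(sim.birth_rate, sim.death_rate, sim.n_tips,
                                stage_seed(seed, "tree"))
        schedule = sim.epoch_schedule
        space = RangeStateSpace(
            tuple(_schedule_areas(schedule)), sim.max_range)
        tip_ranges, truth = simulate_range_history(
            tree, sim.biogeo_params, schedule,
            mask_from_areas([sim.root_area], space.areas),
            stage_seed(seed, "ranges"), space=space)
        truth.tree_for_truth = tree  # pre-pruning tree: node ids match the log
        extinct = set(truth.extinct_tips)
        if extinct:
            tree = tree.prune_tips(extinct)
        truth.pruned_tree = tree
        ensemble = make_tree_ensemble(tree, config.n_trees,
                                      config.age_jitter_sd,
                                      stage_seed(seed, "ensemble"))
        ranges = pd.DataFrame(
            {area: [1 if tip_ranges[sp] >> i & 1 else 0
                    for sp in tree.tip_labels]
             for i, area in enumerate(space.areas)},
            index=tree.tip_labels)
        ranges.index.name = "species"
        tip_vals = {}
        for k, trait in enumerate(sim.bm_sigma2):
            vals = simulate_bm_traits(tree, sim.bm_sigma2[trait],
                                      sim.bm_root[trait],
                                      stage_seed(seed, f"bm-{trait}"))
            tip_vals[trait] = pd.Series(
                {tree.labels[i]: vals[i] for i in tree.tip_indices})
        occurrences = simulate_occurrences(pd.DataFrame(tip_vals),
                                           sim.occurrence_k,
                                           sim.occurrence_noise_sd,
                                           stage_seed(seed, "occurrences"))
        return ensemble, ranges, occurrences, truth, schedule, space
    ensemble = TreeEnsemble.from_newick_file(config.trees_path)
    ranges = pd.read_csv(config.ranges_path, sep="\t", index_col=0)
    occurrences = (pd.read_csv(config.occurrences_path)
                   if config.occurrences_path else None)
    areas = tuple(ranges.columns)
    max_range = int(ranges.sum(axis=1).max())
    space = RangeStateSpace(areas, max_range)
    from .biogeo import example_epoch_schedule
    schedule = (example_epoch_schedule(areas) if set(areas) >=
                {"SA", "CA", "Me", "Ca"} else EpochSchedule.uniform(len(areas)))
    return ensemble, ranges, occurrences, None, schedule, space


def _schedule_areas(schedule: EpochSchedule):
    from .biogeo import DEFAULT_AREAS
    n = schedule.n_areas
    return (DEFAULT_AREAS[:n] if n <= len(DEFAULT_AREAS)
            else tuple(f"A{i}" for i in range(n)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the JSON-serializable run report."""
    t_all = time.time()
    report: dict = {"version": __version__, "seed": config.seed,
                    "stages": {}, "timings_s": {}}

    def stage(name):
        report["timings_s"][name] = time.time()
        return name

    # ---- data ----------------------------------------------------------
    name = stage("data")
    ensemble, ranges, occurrences, truth, schedule, space = _load_inputs(config)
    areas = space.areas
    focal = config.focal_area
    if focal not in areas:
        raise ValueError(f"focal area {focal!r} not among areas {areas}")
    profile = (species_climate_means(occurrences)
               if occurrences is not None else None)
    validation = validate_inputs(ensemble, ranges, profile)
    # species in the tree without range data are pruned before fitting
    trees = []
    for t in ensemble:
        missing = [l for l in t.tip_labels if l not in ranges.index]
        trees.append(t.prune_tips(missing) if missing else t)
    ensemble = TreeEnsemble(trees)
    tip_masks = {sp: mask_from_areas(
        [a for a in areas if ranges.loc[sp, a]], areas)
        for sp in ranges.index}
    report["stages"]["data"] = {
        "n_trees": len(ensemble),
        "n_species": ensemble[0].n_tips,
        "areas": list(areas),
        "validation": validation,
    }
    report["timings_s"][name] = round(time.time() - report["timings_s"][name], 3)

    # ---- biogeographic model fit --------------------------------------
    name = stage("fit_biogeo")
    if config.fixed_params is not None:
        params = config.fixed_params
        report["stages"]["fit_biogeo"] = {
            "mode": "fixed", "d": params.d, "e": params.e, "j": params.j,
            "variant": params.cladogenesis_variant}
    else:
        fits = [fit_biogeo(ensemble[0], tip_masks, variant, schedule,
                           space=space, seed=stage_seed(config.seed, "fit"))
                for variant in config.fit_models]
        table = compare_models(fits)
        best = fits[int(table["AIC"].idxmin())]
        params = best.params
        report["stages"]["fit_biogeo"] = {
            "mode": "ml", "best_model": best.variant,
            "d": params.d, "e": params.e, "j": params.j,
            "model_comparison": table.to_dict(orient="records")}
    report["timings_s"][name] = round(time.time() - report["timings_s"][name], 3)

    # ---- ancestral ranges and events ----------------------------------
    name = stage("events")
    per_tree = {"expansions": [], "restrictions": [], "rate": [],
                "inflection": [], "rate_before": [], "rate_after": [],
                "fold": []}
    events_by_tree = []
    tables_by_tree = []
    for k, t in enumerate(ensemble):
        table = ancestral_ranges(t, tip_masks, params, schedule, space)
        tables_by_tree.append(table)
        ev = extract_events(t, table, focal, areas, config.age_convention)
        events_by_tree.append(ev)
        exp_ages = ev.loc[ev["type"] == "expansion", "event_age"].to_numpy()
        per_tree["expansions"].append(int((ev["type"] == "expansion").sum()))
        per_tree["restrictions"].append(int((ev["type"] == "restriction").sum()))
        rate = dispersal_rate(exp_ages)
        per_tree["rate"].append(rate.rate if rate.defined else np.nan)
        if exp_ages.size >= 5:
            infl = find_inflection(exp_ages)
            per_tree["inflection"].append(
                infl.t_star if not infl.degenerate else np.nan)
            per_tree["rate_before"].append(infl.rate_before or np.nan)
            per_tree["rate_after"].append(infl.rate_after or np.nan)
            per_tree["fold"].append(infl.fold_change or np.nan)
        else:
            for key in ("inflection", "rate_before", "rate_after", "fold"):
                per_tree[key].append(np.nan)

    def summ(vals):
        vals = [v for v in vals if np.isfinite(v)]
        if not vals:
            return None
        s = summarize_ensemble(vals)
        return {"mean": s.mean, "q025": s.q025, "q975": s.q975,
                "n_trees": len(vals)}

    report["stages"]["events"] = {k: summ(v) for k, v in per_tree.items()}
    report["stages"]["events"]["per_tree"] = {
        k: [None if not np.isfinite(v) else float(v) for v in vals]
        for k, vals in per_tree.items()}
    report["timings_s"][name] = round(time.time() - report["timings_s"][name], 3)

    # ---- climate: PGLS, ancestral reconstruction, lags -----------------
    name = stage("climate")
    climate_report: dict = {}
    if profile is not None:
        labels = assign_groups(ranges.loc[[s for s in profile.index
                                           if s in ranges.index]], focal)
        traits = [c for c in profile.columns if c != "n_records"]
        pgls_out = {}
        for trait in traits:
            ps = []
            for t in ensemble[:config.pgls_max_trees]:
                try:
                    res = pgls_group_test(t, profile, labels, trait)
                    if len(res.contrasts):
                        ps.append(res.contrasts["p"].min())
                except ValueError:
                    continue
            pgls_out[trait] = {
                "n_trees": len(ps),
                "frac_significant": (float(np.mean([p < 0.05 for p in ps]))
                                     if ps else None)}
        climate_report["pgls"] = pgls_out
        lag_summaries = {}
        class_counts: dict = {}
        for trait in traits:
            for theta in config.thresholds.get(trait, ()):  # per threshold
                spec_t = ThresholdSpec(trait, theta)
                lags_all, classes_all = [], []
                for t, ev in zip(ensemble, events_by_tree):
                    vals = {l: profile.loc[l, trait]
                            for l in t.tip_labels if l in profile.index}
                    if len(vals) < t.n_tips:
                        continue
                    fitbm = bm_ancestral_ml(t, vals)
                    restr = ev[ev["type"] == "restriction"]
                    lt = lag_table(t, fitbm.node_values, restr, spec_t)
                    lags_all.extend([x for x in lt["lag"] if x is not None
                                     and np.isfinite(x)])
                    classes_all.extend(list(lt["class"]))
                key = f"{trait}<={theta:g}"
                lag_summaries[key] = (summ(lags_all) if lags_all else None)
                class_counts[key] = {c: classes_all.count(c) for c in
                                     ("pre_adapted", "concurrent", "in_situ")}
        climate_report["lag"] = lag_summaries
        climate_report["lag_classes"] = class_counts
    report["stages"]["climate"] = climate_report
    report["timings_s"][name] = round(time.time() - report["timings_s"][name], 3)

    # ---- diversification and phylogenetic diversity -------------------
    name = stage("diversification")
    tree0 = ensemble[0]
    bd = fit_bd(tree0, config.sampling_fraction,
                seed=stage_seed(config.seed, "bd"))
    div_report = {"lambda": bd.params.lam, "mu": bd.params.mu,
                  "r": bd.params.r, "loglik": bd.loglik,
                  "converged": bd.converged}
    if config.run_shift_scan:
        scan = scan_shifts(tree0, seed=stage_seed(config.seed, "scan"))
        div_report["n_shifts"] = len(scan.shifts)
        div_report["shifts"] = [
            {"node": s["node"], "n_tips": s["n_tips"],
             "delta_aic": s["delta_aic"],
             "clade_r": s["clade_params"].r,
             "background_r": s["background_params"].r}
            for s in scan.shifts]
    focal_bit = 1 << list(areas).index(focal)
    focal_tips = [l for l in tree0.tip_labels if tip_masks[l] & focal_bit]
    intro = assign_introductions(tree0, events_by_tree[0], focal_tips)
    if len(intro) >= 2:
        pd_cmp = mpd_partition(tree0, intro)
        div_report["mpd_in_situ"] = pd_cmp.mpd_in_situ
        div_report["mpd_between"] = pd_cmp.mpd_between
        div_report["mpd_in_situ_half"] = pd_cmp.mpd_in_situ_half
        div_report["mpd_between_half"] = pd_cmp.mpd_between_half
        div_report["n_introductions"] = len(set(intro.values()))
    rates_after = [v for v in per_tree["rate_after"] if np.isfinite(v)]
    if rates_after and bd.params.r > 0:
        div_report["dispersal_vs_diversification"] = \
            compare_dispersal_vs_diversification(rates_after, [bd.params.r])
    report["stages"]["diversification"] = div_report
    report["timings_s"][name] = round(time.time() - report["timings_s"][name], 3)

    # ---- truth comparison (simulation mode) ----------------------------
    if truth is not None:
        full_tree = getattr(truth, "tree_for_truth", ensemble[0])
        true_ev = truth.true_events(full_tree, focal)
        obs_ev = truth.events_on_pruned(getattr(truth, "pruned_tree", full_tree),
                                        focal)
        report["stages"]["truth"] = {
            "true_expansions": int((true_ev["type"] == "expansion").sum()),
            "true_restrictions": int((true_ev["type"] == "restriction").sum()),
            "observable_expansions": int((obs_ev["type"] == "expansion").sum()),
            "observable_restrictions": int((obs_ev["type"] == "restriction").sum()),
        }

    report["total_time_s"] = round(time.time() - t_all, 3)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)
        events_by_tree[0].to_csv(out / "events_tree0.tsv", sep="\t", index=False)
        tables_by_tree[0].to_csv(out / "ancestral_ranges_tree0.tsv", sep="\t",
                                 index=False)
        ensemble.to_newick_file(out / "ensemble.nwk")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
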