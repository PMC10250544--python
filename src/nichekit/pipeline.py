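"""End-to-end orchestration of the niche-comparison workflow on a
two-range scenario.

A :class:`RunConfig` (a plain YAML-serializable mapping) declares the
synthetic scenario and every stage parameter; :func:`run_pipeline`
executes prep -> E-space -> 2-D overlap -> 3-D overlap -> candidate
calibration -> scenario transfer/agreement -> spread classification, and
writes tidy tables, logs and metadata into a run directory.  Per-stage
seeds are spawned from the master seed with ``numpy.random.SeedSequence``
so reruns are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings
import numpy as np
import pandas as pd
import yaml

from . import espace, overlap2d, overlap3d, prep, projection, sdm, selection
from .raster import EnvStack
from .synthetic import (LandscapeSpec, VirtualSpecies, make_landscape,
                        make_paleo_stack, sample_occurrences)

__all__ = ["default_config", "synth_demo_config", "load_config",
           "run_pipeline", "buffer_mask"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    """Full-scale defaults for every stage parameter."""
    return {
        "seed": 0,
        "synthetic": {
            "n_rows": 120, "n_cols": 160, "cell_size": 1.0, "n_layers": 4,
            "autocorr_range": 10.0, "barrier_frac": 0.08,
            "niche_mean_west": [0.0, 0.0, 0.0, 0.0],
            "niche_shift_east": [0.0, 0.0, 0.0, 0.0],
            "niche_sd": 0.6, "n_west": 200, "n_east": 200,
        },
        "prep": {"dmin": 1.5, "trials": 10},
        "espace": {"R": 100, "buffer_radius": 25.0},
        "overlap2d": {"reps": 100},
        "overlap3d": {"draws": 10000, "nprob": 1000,
                      "alphas": [0.95, 0.99], "k": 3},
        "sdm": {
            "rm_values": selection.default_rm_values(),
            "class_subsets": selection.all_class_subsets(),
            "predictor_sets": {"pc1-2": ["pc1", "pc2"],
                               "pc1-3": ["pc1", "pc2", "pc3"]},
            "E": 0.05, "n_boot": 500, "n_knots": 10,
        },
        "projection": {
            "replicates": 30, "threshold": 0.5,
            "paleo_shift": [0.5, -0.3, 0.0, 0.0], "paleo_noise_sd": 0.2,
        },
    }


def synth_demo_config(seed: int = 0) -> dict:
    """A desk-scale demo scenario: same full workflow, smaller grids and
    candidate axes so the run finishes in minutes on one CPU."""
    cfg = default_config()
    cfg["seed"] = seed
    cfg["synthetic"].update(n_rows=70, n_cols=110, n_west=120, n_east=120,
                            autocorr_range=6.0)
    cfg["overlap2d"]["reps"] = 50
    cfg["overlap3d"].update(draws=3000, nprob=400)
    cfg["sdm"].update(rm_values=[0.5, 1.0, 2.0],
                      class_subsets=["l", "lq", "lqp"],
                      n_boot=100)
    cfg["projection"]["replicates"] = 10
    return cfg


def load_config(path: str) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def buffer_mask(stack: EnvStack, occ: prep.OccurrenceSet,
                radius: float) -> np.ndarray:
    """Background definition: cells whose center lies within ``radius``
    map units of any occurrence (the calibration-buffer rule)."""
    nr, nc = stack.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cx, cy = stack.xy(rows, cols)
    pts = occ.xy
    mask = np.zeros((nr, nc), dtype=bool)
    for px, py in pts:
        mask |= (cx - px) ** 2 + (cy - py) ** 2 <= radius ** 2
    return mask


def _spawn_seeds(master: int, names: list[str]) -> dict[str, int]:
    """Documented seed-splitting rule: SeedSequence(master).spawn, one
    child per stage, reduced to a 31-bit integer."""
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


def _range_masks(stack: EnvStack, barrier_frac: float):
    """West / east halves separated by an impassable central band."""
    nc = stack.shape[1]
    half_band = max(1, int(round(barrier_frac * nc / 2)))
    mid = nc // 2
    west = np.zeros(stack.shape, dtype=bool)
    east = np.zeros(stack.shape, dtype=bool)
    west[:, :mid - half_band] = True
    east[:, mid + half_band:] = True
    return west, east


def run_pipeline(config: dict, outdir: str) -> dict:
    """Execute the full synthetic two-range analysis; returns a summary
    dict (also written to ``outdir`` together with all stage tables)."""
    os.makedirs(outdir, exist_ok=True)
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    seeds = _spawn_seeds(config["seed"],
                         ["landscape", "occ_west", "occ_east", "thin",
                          "overlap2d", "overlap3d", "calibration",
                          "transfer", "paleo"])
    summary: dict = {"config_hash": cfg_hash, "seeds": seeds}

    # ---- synthetic scenario ---------------------------------------------
    syn = config["synthetic"]
    spec = LandscapeSpec(syn["n_rows"], syn["n_cols"], syn["cell_size"],
                         syn["n_layers"], syn["autocorr_range"],
                         seed=seeds["landscape"])
    stack = make_landscape(spec)
    west_mask, east_mask = _range_masks(stack, syn["barrier_frac"])
    mu_w = np.asarray(syn["niche_mean_west"], float)[:syn["n_layers"]]
    mu_e = mu_w + np.asarray(syn["niche_shift_east"],
                             float)[:syn["n_layers"]]
    cov = (syn["niche_sd"] ** 2) * np.eye(syn["n_layers"])
    sp_w = VirtualSpecies(mu_w, cov, label="west")
    sp_e = VirtualSpecies(mu_e, cov, label="east")
    occ_w = sample_occurrences(sp_w, stack, syn["n_west"], west_mask,
                               seed=seeds["occ_west"], range_label="west")
    occ_e = sample_occurrences(sp_e, stack, syn["n_east"], east_mask,
                               seed=seeds["occ_east"], range_label="east")

    # ---- prep ------------------------------------------------------------
    pp = config["prep"]
    counts = {"west_raw": len(occ_w), "east_raw": len(occ_e)}
    occ_w = prep.dedupe_per_cell(occ_w, stack)
    occ_e = prep.dedupe_per_cell(occ_e, stack)
    occ_w = prep.thin_min_distance(occ_w, pp["dmin"], pp["trials"],
                                   seed=seeds["thin"])
    occ_e = prep.thin_min_distance(occ_e, pp["dmin"], pp["trials"],
                                   seed=seeds["thin"] + 1)
    counts.update(west_clean=len(occ_w), east_clean=len(occ_e))
    logger.info("prep: %s", counts)
    summary["prep_counts"] = counts
    welch = prep.welch_compare(occ_w, occ_e, stack)
    welch.to_csv(os.path.join(outdir, "welch_range_climates.csv"),
                 index=False)
    summary["welch_n_significant"] = int((welch["p"] < 0.05).sum())

    # ---- E-space ---------------------------------------------------------
    es = config["espace"]
    bg_w = buffer_mask(stack, occ_w, es["buffer_radius"]) & west_mask
    bg_e = buffer_mask(stack, occ_e, es["buffer_radius"]) & east_mask
    model = espace.fit_pca([stack, stack], [bg_w, bg_e])
    summary["pca_explained_2d"] = float(model.explained[:2].sum())
    summary["pca_explained_3d"] = float(model.explained[:3].sum())
    sc_w = espace.project(model, stack.extract(*occ_w.xy.T))
    sc_e = espace.project(model, stack.extract(*occ_e.xy.T))
    sb_w = espace.project(model, stack.table(bg_w))
    sb_e = espace.project(model, stack.table(bg_e))

    # ---- 2-D overlap (Table-1-shaped) ------------------------------------
    o2 = config["overlap2d"]
    ranges = espace.pooled_axis_ranges(np.vstack([sb_w, sb_e])[:, :2])
    g_w = espace.occupancy_grid(sc_w, sb_w, R=es["R"], axis_ranges=ranges)
    g_e = espace.occupancy_grid(sc_e, sb_e, R=es["R"], axis_ranges=ranges)
    D = overlap2d.schoener_D(g_w, g_e)
    rows = []
    for a_name, b_name, gA, gB, oA, oB, bA, bB in [
            ("east", "west", g_e, g_w, sc_e, sc_w, sb_e, sb_w),
            ("west", "east", g_w, g_e, sc_w, sc_e, sb_w, sb_e)]:
        dyn = overlap2d.niche_dynamics(gA, gB)
        row = {"comparison": f"{a_name}-{b_name}", "D": D,
               "unfilling": dyn.unfilling, "stability": dyn.stability,
               "expansion": dyn.expansion}
        if o2["reps"] > 0:
            eq = overlap2d.equivalency_test(
                oA, oB, bA, bB, R=es["R"], reps=o2["reps"],
                seed=seeds["overlap2d"])
            sim = overlap2d.similarity_test(
                oA, oB, bA, bB, R=es["R"], reps=o2["reps"],
                seed=seeds["overlap2d"] + 1)
            row.update(similarity_p_div=sim.p_divergence,
                       similarity_p_con=sim.p_conservatism,
                       equivalency_p_div=eq.p_divergence,
                       equivalency_p_con=eq.p_conservatism)
        else:
            row.update(similarity_p_div=np.nan, similarity_p_con=np.nan,
                       equivalency_p_div=np.nan, equivalency_p_con=np.nan)
        rows.append(row)
    t1 = pd.DataFrame(rows)
    t1.to_csv(os.path.join(outdir, "overlap_2d.csv"), index=False)
    summary["schoener_D"] = D
    summary["dynamics"] = t1[["comparison", "unfilling", "stability",
                              "expansion"]].to_dict("records")

    # ---- 3-D overlap (Table-2-shaped) ------------------------------------
    o3 = config["overlap3d"]
    k3 = o3["k"]
    hull_w = overlap3d.hull_niche(sc_w, k=k3)
    hull_e = overlap3d.hull_niche(sc_e, k=k3)
    pct_e_in_w, pct_w_in_e, shared = overlap3d.hull_overlap(hull_e, hull_w)
    post_w = overlap3d.posterior_niche(sc_w[:, :k3], o3["draws"],
                                       seed=seeds["overlap3d"])
    post_e = overlap3d.posterior_niche(sc_e[:, :k3], o3["draws"],
                                       seed=seeds["overlap3d"] + 1)
    rows = []
    for name, pa, pb, pct in [("east-west", post_e, post_w, pct_e_in_w),
                              ("west-east", post_w, post_e, pct_w_in_e)]:
        row = {"comparison": name, "hull_pct_overlap": pct,
               "cpv_a": (hull_e if name.startswith("east") else hull_w).volume,
               "shared_volume": shared}
        for alpha in o3["alphas"]:
            ov = overlap3d.ellipsoid_overlap(pa, pb, alpha, o3["nprob"],
                                             seed=seeds["overlap3d"] + 2)
            tag = f"alpha{int(round(alpha * 100))}"
            row[f"ellipsoid_pct_{tag}"] = 100 * ov.mean
            row[f"ci_low_{tag}"] = 100 * ov.ci[0]
            row[f"ci_high_{tag}"] = 100 * ov.ci[1]
        rows.append(row)
    t2 = pd.DataFrame(rows)
    t2.to_csv(os.path.join(outdir, "overlap_3d.csv"), index=False)
    summary["hull_pct"] = {"east_in_west": pct_e_in_w,
                           "west_in_east": pct_w_in_e}
    summary["ellipsoid_pct_alpha95"] = {
        r["comparison"]: r["ellipsoid_pct_alpha95"] for r in rows}

    # ---- SDM calibration (Table-3-shaped) ---------------------------------
    sd_cfg = config["sdm"]
    pc_stack = espace.project_stack(model, stack)
    pred_sets = sd_cfg["predictor_sets"]
    cands = selection.candidate_grid(sd_cfg["rm_values"],
                                     sd_cfg["class_subsets"],
                                     list(pred_sets))
    datasets = {
        "west": (occ_w, bg_w), "east": (occ_e, bg_e),
        "continental": (occ_w.concat(occ_e), bg_w | bg_e),
    }
    best = {}
    t3_rows = []
    for region, (occ, bgmask) in datasets.items():
        pres = pc_stack.extract(*occ.xy.T).dropna()
        bg = pc_stack.table(bgmask)
        table = selection.run_calibration(
            pres, bg, cands, pred_sets, E=sd_cfg["E"],
            n_boot=sd_cfg["n_boot"], n_knots=sd_cfg["n_knots"],
            seed=seeds["calibration"])
        table.insert(0, "region", region)
        table.insert(1, "sample_size", len(pres))
        t3_rows.append(table)
        sel = table[table["selected"]]
        pick = (sel if len(sel) else table).sort_values("aicc").iloc[0]
        best[region] = {"spec": selection.CandidateSpec(
            pick["rm"], pick["classes"], pick["predictor_set"]),
            "pres": pres, "bg": bg, "mask": bgmask, "occ": occ,
            "n_selected": int(table["selected"].sum())}
    t3 = pd.concat(t3_rows, ignore_index=True)
    t3.to_csv(os.path.join(outdir, "sdm_calibration.csv"), index=False)
    summary["n_candidates"] = len(cands)
    summary["n_selected"] = {r: b["n_selected"] for r, b in best.items()}

    # ---- transfer, agreement, spread --------------------------------------
    pj = config["projection"]
    paleo = make_paleo_stack(stack, pj["paleo_shift"][:syn["n_layers"]],
                             pj["paleo_noise_sd"], seed=seeds["paleo"])
    paleo_pc = espace.project_stack(model, paleo)
    maps_current, maps_paleo = {}, {}
    for region in ("west", "east", "continental"):
        b = best[region]
        spec_b = b["spec"]
        preds = pred_sets[spec_b.predictor_set]
        fs = sdm.build_features(b["bg"][preds], spec_b.classes,
                                sd_cfg["n_knots"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps_current[region] = projection.transfer(
                b["pres"][preds], b["bg"][preds], fs, spec_b.rm, pc_stack,
                replicates=pj["replicates"], seed=seeds["transfer"])
            if region != "continental":
                maps_paleo[region] = projection.transfer(
                    b["pres"][preds], b["bg"][preds], fs, spec_b.rm,
                    paleo_pc, replicates=pj["replicates"],
                    seed=seeds["transfer"] + 1)
    agree, n_common = projection.agreement_map(
        maps_paleo["west"], maps_paleo["east"], pj["threshold"])
    summary["paleo_common_cells"] = n_common
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spread = projection.classify_spread(
            best["west"]["occ"], maps_current["west"],
            maps_current["continental"], pj["threshold"])
    spread.table.to_csv(os.path.join(outdir, "spread_classification.csv"),
                        index=False)
    summary["spread_fractions"] = {
        k: float(v) for k, v in spread.fractions().items()}

    with open(os.path.join(outdir, "run_metadata.json"), "w") as fh:
        json.dump({"config": config, "summary": _jsonable(summary)},
                  fh, indent=2, default=str)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
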