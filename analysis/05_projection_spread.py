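"""Scenario transfer, cross-model agreement, and spread-stage status.

Transfers the best west- and east-range models to a perturbed "paleo"
stack with bootstrap replicates, maps where both predict suitable
conditions, and classifies each western occurrence into sink /
stabilizing / adaptation / colonization by comparing the local (west)
model against the continental model at the 0.5 threshold.
"""

import sys
sys.path.insert(0, __file__.rsplit("/", 1)[0])

import warnings

import numpy as np
from common import build_scenario, results_path

from nichekit import espace, projection, sdm, selection
from nichekit.synthetic import make_paleo_stack


def best_model_inputs(sc, region, occ, bgmask):
    """Small calibration per dataset; returns the winning setup."""
    cfg = sc["config"]["sdm"]
    pc_stack = espace.project_stack(sc["espace"], sc["stack"])
    pres = pc_stack.extract(*occ.xy.T).dropna()
    bg = pc_stack.table(bgmask)
    cands = selection.candidate_grid(cfg["rm_values"],
                                     cfg["class_subsets"],
                                     list(cfg["predictor_sets"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = selection.run_calibration(
            pres, bg, cands, cfg["predictor_sets"], E=cfg["E"],
            n_boot=cfg["n_boot"], seed=sc["seeds"]["calibration"])
    sel = table[table["selected"]]
    pick = (sel if len(sel) else table).sort_values("aicc").iloc[0]
    preds = cfg["predictor_sets"][pick["predictor_set"]]
    fs = sdm.build_features(bg[preds], pick["classes"], cfg["n_knots"])
    return pres[preds], bg[preds], fs, pick["rm"], pc_stack


def main():
    sc = build_scenario()
    pj = sc["config"]["projection"]
    paleo = make_paleo_stack(sc["stack"], pj["paleo_shift"],
                             pj["paleo_noise_sd"], seed=sc["seeds"]["paleo"])
    paleo_pc = espace.project_stack(sc["espace"], paleo)
    occ_all = sc["occ_west"].concat(sc["occ_east"])
    bg_all = sc["bg_west"] | sc["bg_east"]
    maps_paleo, maps_current = {}, {}
    for region, occ, bgmask in [("west", sc["occ_west"], sc["bg_west"]),
                                ("east", sc["occ_east"], sc["bg_east"]),
                                ("continental", occ_all, bg_all)]:
        pres, bg, fs, rm, pc_stack = best_model_inputs(sc, region, occ,
                                                       bgmask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps_current[region] = projection.transfer(
                pres, bg, fs, rm, pc_stack,
                replicates=pj["replicates"], seed=sc["seeds"]["transfer"])
            if region != "continental":
                maps_paleo[region] = projection.transfer(
                    pres, bg, fs, rm, paleo_pc,
                    replicates=pj["replicates"],
                    seed=sc["seeds"]["transfer"] + 1)
    binary, n_common = projection.agreement_map(
        maps_paleo["west"], maps_paleo["east"], pj["threshold"])
    print(f"paleo agreement: {n_common} cells predicted suitable by both "
          "range models")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spread = projection.classify_spread(
            sc["occ_west"], maps_current["west"],
            maps_current["continental"], pj["threshold"])
    spread.table.to_csv(results_path("spread_classification.csv"),
                        index=False)
    frac = spread.fractions()
    print("western spread stages: "
          + ", ".join(f"{k} {v:.2f}" for k, v in frac.items() if v > 0))
    np.savetxt(results_path("paleo_agreement_mask.txt"),
               binary.astype(int), fmt="%d")
    print("wrote results/spread_classification.csv, "
          "paleo_agreement_mask.txt")


if __name__ == "__main__":
    main()
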