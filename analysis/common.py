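"""Shared scenario assembly for the numbered analysis scripts.

All scripts analyze the same seeded two-range virtual-species scenario
(the packaged demo configuration) so their tables are mutually
consistent; each script recomputes its own stage from the library.
"""

from __future__ import annotations

import os

import numpy as np

from nichekit import espace, prep
from nichekit.pipeline import (_range_masks, _spawn_seeds, buffer_mask,
                               synth_demo_config)
from nichekit.synthetic import (LandscapeSpec, VirtualSpecies,
                                make_landscape, sample_occurrences)

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

SEED = 1


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def build_scenario(seed: int = SEED, shift=None):
    """Landscape, cleaned two-range occurrences, backgrounds, E-space."""
    cfg = synth_demo_config(seed)
    if shift is not None:
        cfg["synthetic"]["niche_shift_east"] = list(shift)
    syn = cfg["synthetic"]
    seeds = _spawn_seeds(cfg["seed"],
                         ["landscape", "occ_west", "occ_east", "thin",
                          "overlap2d", "overlap3d", "calibration",
                          "transfer", "paleo"])
    stack = make_landscape(LandscapeSpec(
        syn["n_rows"], syn["n_cols"], syn["cell_size"], syn["n_layers"],
        syn["autocorr_range"], seed=seeds["landscape"]))
    west_mask, east_mask = _range_masks(stack, syn["barrier_frac"])
    mu_w = np.asarray(syn["niche_mean_west"], float)
    mu_e = mu_w + np.asarray(syn["niche_shift_east"], float)
    cov = syn["niche_sd"] ** 2 * np.eye(syn["n_layers"])
    occ_w = sample_occurrences(VirtualSpecies(mu_w, cov, label="west"),
                               stack, syn["n_west"], west_mask,
                               seed=seeds["occ_west"], range_label="west")
    occ_e = sample_occurrences(VirtualSpecies(mu_e, cov, label="east"),
                               stack, syn["n_east"], east_mask,
                               seed=seeds["occ_east"], range_label="east")
    pp = cfg["prep"]
    occ_w = prep.thin_min_distance(prep.dedupe_per_cell(occ_w, stack),
                                   pp["dmin"], pp["trials"],
                                   seed=seeds["thin"])
    occ_e = prep.thin_min_distance(prep.dedupe_per_cell(occ_e, stack),
                                   pp["dmin"], pp["trials"],
                                   seed=seeds["thin"] + 1)
    bg_w = buffer_mask(stack, occ_w, cfg["espace"]["buffer_radius"]) \
        & west_mask
    bg_e = buffer_mask(stack, occ_e, cfg["espace"]["buffer_radius"]) \
        & east_mask
    model = espace.fit_pca([stack, stack], [bg_w, bg_e])
    return {
        "config": cfg, "seeds": seeds, "stack": stack,
        "occ_west": occ_w, "occ_east": occ_e,
        "bg_west": bg_w, "bg_east": bg_e, "espace": model,
        "scores_occ_west": espace.project(model,
                                          stack.extract(*occ_w.xy.T)),
        "scores_occ_east": espace.project(model,
                                          stack.extract(*occ_e.xy.T)),
        "scores_bg_west": espace.project(model, stack.table(bg_w)),
        "scores_bg_east": espace.project(model, stack.table(bg_e)),
    }
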