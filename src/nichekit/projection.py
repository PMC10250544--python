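"""Scenario transfer, cross-model agreement maps, and spread-stage
classification.

Transfer refits the selected model on bootstrap resamples of the
presences and projects each replicate onto the scenario stack with the
no-extrapolation mask, summarizing cell-wise by the mean (sd stored).
Spread stages compare, per occurrence, the suitability predicted by the
local-range model against the continental model at a 0.5 threshold:
stabilizing (high/high), adaptation (high local only), colonization (high
continental only), sink (low/low).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import OccurrenceSet
from .raster import EnvStack
from .sdm import FeatureSet, SuitabilityMap, fit_maxent, predict

__all__ = ["SpreadClassification", "transfer", "agreement_map",
           "classify_spread", "SPREAD_CATEGORIES"]

SPREAD_CATEGORIES = ("sink", "stabilizing", "adaptation", "colonization")


@dataclass
class SpreadClassification:
    table: pd.DataFrame       # id, x, y, local_suit, continental_suit, category
    threshold: float

    def counts(self) -> pd.Series:
        cats = list(SPREAD_CATEGORIES) + ["unscored"]
        return self.table["category"].value_counts().reindex(
            cats, fill_value=0)

    def fractions(self) -> pd.Series:
        c = self.counts()
        return c / c.sum()


def transfer(presence_values: pd.DataFrame, background_values: pd.DataFrame,
             features: FeatureSet, rm: float, scenario: EnvStack,
             replicates: int = 30, seed: int | None = 0,
             output: str = "cloglog", summary: str = "mean"
             ) -> SuitabilityMap:
    """Bootstrap-replicated projection of a model onto a scenario stack.

    Each replicate refits on a resample (with replacement) of the presence
    records and predicts with ``extrapolation="mask"``; masked cells
    propagate (a cell masked in any replicate is masked in the summary).
    ``replicates=1`` predicts once on the original presences.
    """
    missing = [n for n in features.predictor_names
               if n not in scenario.layer_names]
    if missing:
        raise ValueError(f"scenario lacks predictor layers {missing}")
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    rng = np.random.default_rng(seed)
    n = len(presence_values)
    maps = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for r in range(replicates):
            if replicates == 1:
                pres = presence_values
            else:
                pres = presence_values.iloc[rng.integers(0, n, size=n)]
            model = fit_maxent(pres, background_values, features, rm=rm)
            maps.append(predict(model, scenario, output=output,
                                extrapolation="mask").values)
    stackv = np.stack(maps)
    vals = (np.mean(stackv, axis=0) if summary == "mean"
            else np.median(stackv, axis=0))
    sd = np.std(stackv, axis=0) if replicates > 1 else None
    masked_frac = float(np.mean(~np.isfinite(vals)))
    if masked_frac > 0.5:
        warnings.warn(f"{100 * masked_frac:.0f}% of scenario cells masked "
                      "as outside the calibration range", stacklevel=2)
    return SuitabilityMap(vals, scenario, output,
                          provenance={"replicates": replicates,
                                      "summary": summary,
                                      "masked_fraction": masked_frac},
                          sd=sd)


def agreement_map(a: SuitabilityMap, b: SuitabilityMap,
                  threshold: float = 0.5):
    """Cells where both maps are unmasked and at or above the threshold.

    Returns (binary raster, common cell count).
    """
    if a.values.shape != b.values.shape:
        raise ValueError("suitability maps do not share a grid")
    both = (np.isfinite(a.values) & np.isfinite(b.values)
            & (a.values >= threshold) & (b.values >= threshold))
    return both, int(both.sum())


def classify_spread(occ: OccurrenceSet, local_map: SuitabilityMap,
                    continental_map: SuitabilityMap,
                    threshold: float = 0.5) -> SpreadClassification:
    """Four-way spread stage per occurrence from paired suitabilities.

    The boundary value (exactly ``threshold``) counts as high.  Records on
    masked cells in either map are categorized "unscored" with a warning.
    """
    x = occ.df["x"].to_numpy(float)
    y = occ.df["y"].to_numpy(float)
    loc = local_map.at_points(x, y)
    con = continental_map.at_points(x, y)
    ok = np.isfinite(loc) & np.isfinite(con)
    hi_l = loc >= threshold
    hi_c = con >= threshold
    category = np.where(hi_l & hi_c, "stabilizing",
                        np.where(hi_l, "adaptation",
                                 np.where(hi_c, "colonization", "sink")))
    category = np.where(ok, category, "unscored")
    n_unscored = int((~ok).sum())
    if n_unscored:
        warnings.warn(f"{n_unscored} occurrence(s) on masked cells left "
                      "unscored", stacklevel=2)
    table = pd.DataFrame({
        "id": occ.df["id"].to_numpy(), "x": x, "y": y,
        "local_suit": loc, "continental_suit": con, "category": category,
    })
    return SpreadClassification(table, threshold)
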