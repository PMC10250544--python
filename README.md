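# nichekit

Climatic-niche comparison and presence–background distribution modelling
for two-range species, with a fully synthetic "virtual species" workflow
whose ground truth is known analytically.

## The problem

When a species occupies two disjoint geographic ranges — for instance a
native range and a range it was introduced to long ago — two questions
recur in biogeography:

1. **Do the two populations use the same climate?** Even when the raw
   climates of the regions differ, the *conditions actually used* may
   overlap (niche conservatism).
2. **Where and when could the species have spread from?** Distribution
   models calibrated in each range and projected onto other climate
   scenarios (e.g. past periods) identify candidate source areas, and
   comparing local vs continental suitability at each occurrence
   classifies its spread stage.

`nichekit` implements the full analysis chain: occurrence cleaning,
environmental-space (E-space) construction, 2-D and 3-D niche-overlap
statistics with randomization/Bayesian inference, maximum-entropy
suitability modelling with formal candidate selection, cross-scenario
transfer, and spread-stage classification. Because real occurrence
datasets of this kind are rarely redistributable, the package ships a
first-class synthetic-data module: virtual landscapes with controlled
spatial autocorrelation and virtual species with known Gaussian niches,
so every estimate can be checked against an analytic answer.

## The statistics

- **Occupancy grids.** Occurrences and background cells are projected on
  the first two PCs of the pooled background climate and kernel-smoothed
  on an R×R grid (R = 100 by default): occurrence density *o*, available
  density *e*, corrected occupancy *z* = (o/e)/max(o/e), and its
  normalization *Z*.
- **Schoener's D** = 1 − ½ Σ |Z₁ − Z₂| over grid cells (0 = disjoint
  niches, 1 = identical).
- **Equivalency test**: pool the occurrences, re-split at random into the
  original group sizes, recompute D; p = (#{D_null ≤ D_obs}+1)/(reps+1)
  for divergence, the ≥ count for conservatism.
- **Similarity test**: translate one range's occupancy surface at random
  within its background envelope and recompute D — does the observed
  overlap exceed what the available environment alone produces?
- **Niche dynamics**: expansion (occupancy of the new range in cells the
  source range does not use), stability = 1 − expansion, and unfilling
  (source occupancy not yet used in the new range), over analogue
  environments.
- **3-D overlap**: convex polyhedra connecting extreme occurrences in
  PC1–3 with exact intersection volumes; and Bayesian niche regions —
  the normal–inverse-Wishart posterior of (μ, Σ) sampled 10 000 times,
  with the overlap of niche A onto B's α-probability ellipsoid
  (α = 0.95 / 0.99) reported with 95% credible intervals.
- **Maximum-entropy SDM**: P(cell) ∝ exp(βᵀh(x)) over background cells,
  with linear/quadratic/product/hinge/threshold features h and per-feature
  L1 penalties scaled by a regularization multiplier (RM); cloglog output
  1 − exp(−e^H · P̂). Candidates over 17 RM values × 31 feature-class
  subsets × predictor sets are filtered by significant partial ROC,
  omission rate < 5% (on a common 75/25 split) and ΔAICc ≤ 2.
- **Spread stages**: each occurrence's local vs continental suitability
  at a 0.5 threshold → stabilizing (high/high), adaptation (high local
  only), colonization (high continental only), sink (low/low).

## Worked example

The numbered scripts under `analysis/` run the complete workflow on the
packaged two-range virtual-species scenario (a 70×110 landscape, two
ranges separated by a barrier, one shared Gaussian niche):

```bash
python analysis/01_simulate.py
python analysis/02_overlap_2d.py
python analysis/03_overlap_3d.py
python analysis/04_sdm_calibration.py
python analysis/05_projection_spread.py
```

which prints, among other lines:

```
cleaned occurrences: west 86, east 85
Schoener's D = 0.675 (PCs 1-2 explain 60.4%)
west-east: stability 0.972, expansion 0.028, unfilling 0.175; similarity p(CON) 0.039, equivalency p(DIV) 0.176
west-east alpha=0.95: 76.3% [64.2, 87.0]
west: 1 selected; best RM=2.0, classes=lq, set=pc1-3, OR=0.045, AICc=1272.8
western spread stages: sink 0.21, stabilizing 0.65, adaptation 0.14
```

Read: the two ranges share one generating niche, so the analysis finds
high overlap (D = 0.675 on the 2-D grid; 76–95% of one niche inside the
other's 95% Bayesian region), stability near 1 with negligible
expansion, a similarity test that detects conservatism (p = 0.039) while
the equivalency test cannot reject interchangeability (p = 0.176), and a
spread classification dominated by stabilizing (equilibrium) populations
— exactly the signature expected for a long-established introduction.
Tables land in `results/`.

The same workflow is scriptable from a single YAML config:

```bash
nichekit synth-demo --seed 1 --out demo.yaml
nichekit run demo.yaml --out my_run
```

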