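# Methods

This note documents the models and procedures `nichekit` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a user should know about.

## Synthetic landscapes and virtual species

Landscapes are stacks of standardized smoothed-noise fields: independent
Gaussian white noise per layer, smoothed with a Gaussian kernel whose sd
equals `autocorr_range / cell_size`, re-standardized, and mixed by the
Cholesky factor of the requested inter-layer correlation matrix. This
reproduces the two statistical properties that matter for the analyses —
spatial autocorrelation and collinearity between layers — at a fraction
of the cost of an exact Gaussian-process simulation. It does **not**
emulate physical climate: no gradients with latitude or elevation, no
heavy tails, no cross-scale anisotropy. Passing tests on these
landscapes therefore validate the statistical machinery, not robustness
to every pathology of real climate grids.

A virtual species is a Gaussian niche: suitability
`exp(-(x-μ)ᵀΣ⁻¹(x-μ)/2)` in environment units. Occurrences are drawn
without replacement at cell resolution with probability proportional to
suitability inside a range mask, so per-pixel deduplication downstream is
exercised meaningfully. The two-range scenario places a vertical barrier
band (8% of columns) between a west and an east half. Default scenario
sizes (demo configuration: 70×110 cells, 4 layers, 120 occurrences per
range before cleaning, niche sd 0.6 in layer units) were chosen so the
full workflow runs in seconds while leaving each stage comfortably above
its small-sample limits.

Ground-truth oracles: `analytic_overlap` gives the probability that a
draw from niche A lands in B's α-ellipsoid (closed-form normal CDF in
1-D, ≥10⁶-draw Monte Carlo otherwise); `analytic_density_overlap` gives
the Schoener-style density overlap 1 − ½∫|f_A − f_B| by quadrature.

## Occurrence preparation

Deduplication keeps the first record per raster cell. Thinning enforces
a minimum pairwise distance with a randomized greedy heuristic: the
closest conflicting pair is found and its member with more conflicts is
deleted, repeated until clean, with 10 restarts keeping the pass that
retains most records. On small instances this matches the brute-force
optimum (tested by subset enumeration). Distances are Euclidean for
projected coordinates and haversine (R = 6371 km) for geographic ones;
which rule applies is a property of the occurrence set's CRS tag.
Welch's t (Satterthwaite df, two-sided) compares per-layer range
climates; p-values are not multiplicity-adjusted by default (a
Bonferroni column is available) because the comparison is descriptive,
not inferential, in this workflow.

## E-space and occupancy grids

The PCA is calibrated on the pooled background cells of both ranges,
standardized per layer — equivalent to an eigen-decomposition of the
pooled background correlation matrix. Pooling is required for the two
ranges to share one grid frame; a per-region PCA would place the two
occupancy surfaces in incomparable coordinates. Components follow the
convention that each component's largest-magnitude loading is positive.

Occupancy grids use a diagonal-bandwidth Gaussian KDE, by default the
normal-reference (Silverman) rule per axis computed from the occurrence
scores. The grid spans the pooled background envelope plus 5% per axis.
Availability support is the set of cells that actually contain background
points, with single-cell sampling holes closed morphologically; the
corrected occupancy z = (o/e)/max(o/e) is only evaluated there, because
a KDE-tail support lets the ratio explode where no environment exists.
An uncorrected variant (z = o/max o) is available since published
analyses do not always state which was used; the corrected form is the
default and is what the tests calibrate.

## 2-D overlap statistics

Schoener's D uses the normalized occupancies. Both randomization tests
use the +1 p-value correction (p ∈ (0,1], granularity 1/(reps+1), so 100
replicates give a minimum p of ~0.01) and count ties as extreme. The
equivalency null pools and re-splits occurrences at the original sizes.
The similarity null translates one range's occupancy surface toroidally
**within the bounding box of its background support**, rejecting shifts
that move more than half the occupancy mass off the support; restricting
the torus to the background envelope is what makes a niche that fills
its whole background correctly non-significant (any translation maps the
flat surface approximately onto itself).

The dynamics indices (expansion/stability/unfilling) count a cell as
"used" if it carries part of the top 95% of a range's occupancy mass
(`marginal_quantile = 0.05`); without this marginal-tail cut a Gaussian
KDE is positive almost everywhere and expansion degenerates to zero. By
default the indices are restricted to analogue environments (cells in
both supports).

## 3-D overlap

Convex niches are hulls of the occurrence scores in PC1–3; intersection
volumes are computed exactly by stacking both hulls' half-spaces, finding
a Chebyshev-center interior point by linear programming, and running a
half-space intersection; a 10⁶-point Monte-Carlo count stands in if the
exact construction is degenerate. The Bayesian niche region uses the
noninformative normal–inverse-Wishart posterior (Σ ~ IW((n−1)S, n−1);
μ|Σ ~ N(x̄, Σ/n)), 10 000 draws by default. The overlap of A onto B's
α-region is estimated per paired draw from 1000 points of A's normal,
giving a posterior whose mean and equal-tailed 95% credible interval are
reported; at these defaults CI endpoints are stable to about one
percentage point across seeds. Overlap is directional and both
directions are always reported.

## Maximum-entropy SDM

The model is the Gibbs distribution over background cells with features
min-max scaled to [0,1] on the background. Hinge/threshold knots sit at
10 interior quantiles per predictor — far fewer than the canonical
implementation's per-value knots, a deliberate desk-scale default
(configurable). Per-feature penalties are
`λ_j = RM · τ(class, n) · sd_j / √n` with τ interpolating the canonical
per-class constants (linear/quadratic/product from 1.0 at n≤10 to 0.05
at n≥100; hinge 0.5; threshold 2.0→1.0). The objective is convex and is
minimized by FISTA with backtracking (tolerance 1e-7 on the relative
objective change, max 5000 iterations); fits are deterministic, and at
tight tolerances the L1 path is monotone in RM.

Prediction: "raw" output renormalizes the exponential scores over the
prediction region (so it sums to 1 there); **cloglog keeps the
calibration normalization** — 1 − exp(−e^H · exp(βᵀh − log Z_cal)) with
H the calibration entropy — so transferred maps remain comparable
regardless of the target region's size (a prediction-region-normalized
cloglog would deflate suitability on large transfer regions and distort
the spread classification). No-extrapolation transfer masks every cell
with any predictor outside the calibration range; clamping to the range
boundary is available.

## Candidate selection

Candidates are the Cartesian product of RM values (default ladder
0.1–1.0 by 0.1, 2–6 by 1, 8, 10 → 17 values), non-empty feature-class
subsets (31), and predictor sets; one seeded 75/25 split is reused by
every candidate. Omission rate takes the E-quantile of training
suitabilities as threshold. The partial ROC ratio integrates the
(area-fraction, sensitivity) curve over sensitivities ≥ 1−E against the
diagonal on the same x grid, bootstrapping 50% of the test points (500
iterations by default); p is the share of bootstrap ratios ≤ 1. This
canonical construction is asymptotically calibrated but liberal at small
test sizes (the sensitivity staircase biases the kept region upward —
noticeable below ~100 test points, gone by ~400; the calibration tests
use 400). AICc uses the raw per-occurrence probabilities normalized over
the calibration background, all occurrences, and k = count of nonzero
coefficients. ΔAICc is computed against the best candidate that already
passes the significance and omission filters (option to baseline on all).

## Transfer, agreement, spread

Transfer refits on bootstrap resamples of the presence records (30
replicates by default) and summarizes cell-wise by the mean (median
available); a cell masked in any replicate stays masked. Agreement maps
mark cells where both inputs are unmasked and ≥ 0.5. Spread stages
assign the boundary value 0.5 to the "high" side; occurrences on masked
cells are reported as "unscored" rather than silently dropped.

## Pipeline and reproducibility

`run_pipeline` derives one child seed per stage from the master seed via
`numpy.random.SeedSequence(master).spawn`, so stages are independently
reproducible and the whole run is bit-reproducible. Every run directory
carries the config hash, the derived seeds and per-stage record counts.

## Known limitations

- The Gaussian-niche generator cannot express multimodal or truncated
  niches; parameter-recovery results bound estimator behavior only in
  the regimes tested.
- Partial ROC p-values are liberal for test sets under ~100 points (see
  above); with the paper-style 25% splits of a few hundred occurrences
  the significance filter is permissive, and the omission and AICc
  filters do most of the selecting.
- Hull volumes are limited to 3-D (by scope); degenerate point sets are
  rejected rather than repaired.
- Geographic-CRS support covers distance computations (thinning,
  buffers); the synthetic workflow is planar by design.
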